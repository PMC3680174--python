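import pytest

from semview import FixtureSpec, build_gcp_fixture, build_gcp_view

#: node sequences of the worked example's two aggregated branches
PRINTED_PATH_GENO = (
    "study", "genotypingstudy", "dnasamplegenotypingstudy", "dnasample", "germplasm",
)
PRINTED_PATH_PHENO = (
    "study", "phenotypingstudy", "germplasmphenotypingstudy", "germplasm",
)

PRINTED_JOIN_PREDICATES = [
    "vocab:genotypingstudy_id_study",
    "vocab:dnasamplegenotypingstudy_id_genotypingstudy",
    "vocab:dnasamplegenotypingstudy_id_dnasample",
    "vocab:dnasample_id_germplasm",
    "vocab:phenotypingstudy_id_study",
    "vocab:germplasmphenotypingstudy_id_phenotypingstudy",
    "vocab:germplasmphenotypingstudy_id_germplasm",
]


@pytest.fixture()
def gcp(tmp_path):
    """Prepared worked-example view: built, enriched and annotated."""
    doc, fixture = build_gcp_view(FixtureSpec(), str(tmp_path))
    return doc, fixture


@pytest.fixture()
def gcp_fixture(tmp_path):
    return build_gcp_fixture(FixtureSpec(), str(tmp_path))
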