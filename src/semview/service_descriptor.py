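"""SAWSDL-annotated service descriptor emission (no deployment).

A descriptor is a WSDL 1.1 document with one operation (filter pattern in,
result rows out) whose request and response elements each carry exactly
one ``sawsdl:modelReference`` attribute pointing at the input and output
concept URIs.  The synthesized SPARQL query is embedded verbatim as the
service documentation.  Emission is deterministic: identical inputs yield
byte-identical XML.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from lxml import etree

from .errors import AnnotationTargetError, NamingError
from .registry import ConceptTerm
from .sparql_gen import SparqlQuery

WSDL_NS = "http://schemas.xmlsoap.org/wsdl/"
XSD_NS = "http://www.w3.org/2001/XMLSchema"
SAWSDL_NS = "http://www.w3.org/ns/sawsdl"

_NCNAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")


@dataclass
class ServiceDescriptor:
    service_name: str
    input_term: ConceptTerm
    output_term: ConceptTerm
    query: SparqlQuery
    wsdl_text: str


def emit_descriptor(query: SparqlQuery, input_term: ConceptTerm,
                    output_term: ConceptTerm, service_name: str) -> ServiceDescriptor:
    """Fill the WSDL template for one synthesized query (one service per query)."""
    if not _NCNAME_RE.match(service_name or ""):
        raise NamingError(f"service name {service_name!r} is not a valid XML NCName")
    for role, term in (("input", input_term), ("output", output_term)):
        if not getattr(term, "uri", None):
            raise AnnotationTargetError(f"{role} term has no URI")

    tns = f"http://semview.org/services/{service_name}"
    nsmap = {"wsdl": WSDL_NS, "xsd": XSD_NS, "sawsdl": SAWSDL_NS, "tns": tns}
    E = lambda ns, tag: f"{{{ns}}}{tag}"  # noqa: E731

    definitions = etree.Element(
        E(WSDL_NS, "definitions"), nsmap=nsmap,
        attrib={"name": service_name, "targetNamespace": tns},
    )
    doc_el = etree.SubElement(definitions, E(WSDL_NS, "documentation"))
    doc_el.text = "SPARQL query executed by this service:\n" + query.text

    types = etree.SubElement(definitions, E(WSDL_NS, "types"))
    schema = etree.SubElement(types, E(XSD_NS, "schema"),
                              attrib={"targetNamespace": tns, "elementFormDefault": "qualified"})
    request = etree.SubElement(
        schema, E(XSD_NS, "element"),
        attrib={"name": f"{service_name}Request",
                E(SAWSDL_NS, "modelReference"): input_term.uri},
    )
    rtype = etree.SubElement(request, E(XSD_NS, "complexType"))
    rseq = etree.SubElement(rtype, E(XSD_NS, "sequence"))
    etree.SubElement(rseq, E(XSD_NS, "element"),
                     attrib={"name": "pattern", "type": "xsd:string"})
    response = etree.SubElement(
        schema, E(XSD_NS, "element"),
        attrib={"name": f"{service_name}Response",
                E(SAWSDL_NS, "modelReference"): output_term.uri},
    )
    ptype = etree.SubElement(response, E(XSD_NS, "complexType"))
    pseq = etree.SubElement(ptype, E(XSD_NS, "sequence"))
    etree.SubElement(pseq, E(XSD_NS, "element"),
                     attrib={"name": "row", "type": "xsd:string",
                             "minOccurs": "0", "maxOccurs": "unbounded"})

    msg_in = etree.SubElement(definitions, E(WSDL_NS, "message"),
                              attrib={"name": f"{service_name}Input"})
    etree.SubElement(msg_in, E(WSDL_NS, "part"),
                     attrib={"name": "parameters", "element": f"tns:{service_name}Request"})
    msg_out = etree.SubElement(definitions, E(WSDL_NS, "message"),
                               attrib={"name": f"{service_name}Output"})
    etree.SubElement(msg_out, E(WSDL_NS, "part"),
                     attrib={"name": "parameters", "element": f"tns:{service_name}Response"})

    port_type = etree.SubElement(definitions, E(WSDL_NS, "portType"),
                                 attrib={"name": f"{service_name}PortType"})
    operation = etree.SubElement(port_type, E(WSDL_NS, "operation"),
                                 attrib={"name": service_name})
    etree.SubElement(operation, E(WSDL_NS, "input"),
                     attrib={"message": f"tns:{service_name}Input"})
    etree.SubElement(operation, E(WSDL_NS, "output"),
                     attrib={"message": f"tns:{service_name}Output"})

    wsdl_text = etree.tostring(
        definitions, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")
    return ServiceDescriptor(service_name, input_term, output_term, query, wsdl_text)


def validate_descriptor(descriptor: ServiceDescriptor) -> list[tuple[str, str]]:
    """Diagnostics on a descriptor; an empty list means it is valid.

    Checks XML well-formedness, exactly one ``sawsdl:modelReference`` per
    message element with the expected URIs, and that the embedded query
    parses as SPARQL 1.1.
    """
    diags: list[tuple[str, str]] = []
    try:
        root = etree.fromstring(descriptor.wsdl_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        return [("error", f"WSDL is not well-formed XML: {exc}")]

    annotated = root.findall(f".//*[@{{{SAWSDL_NS}}}modelReference]")
    refs = [el.get(f"{{{SAWSDL_NS}}}modelReference") for el in annotated]
    if len(refs) != 2:
        diags.append(("error", f"expected 2 sawsdl:modelReference annotations, found {len(refs)}"))
    else:
        expected = [descriptor.input_term.uri, descriptor.output_term.uri]
        if refs != expected:
            diags.append(("error", f"modelReference URIs {refs} differ from terms {expected}"))
    for el in annotated:
        # one annotation attribute per element by construction; duplicated
        # attributes would already be an XML well-formedness error
        if el.tag != f"{{{XSD_NS}}}element":
            diags.append(("warning", f"modelReference on unexpected element {el.tag}"))

    parts = root.findall(f".//{{{WSDL_NS}}}part")
    if len(parts) != 2:
        diags.append(("error", f"expected 2 message parts, found {len(parts)}"))

    try:
        from rdflib.plugins.sparql import prepareQuery

        prepareQuery(descriptor.query.text)
    except Exception as exc:
        diags.append(("error", f"embedded SPARQL query does not parse: {exc}"))
    return diags
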