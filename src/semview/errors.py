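"""Exception hierarchy shared by all semview stages."""


class SemviewError(Exception):
    """Base class for all semview errors."""


class SchemaError(SemviewError):
    """Invalid relational schema (failed invariants, dangling references)."""


class SchemaParseError(SchemaError):
    """Malformed schema description document."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DatabaseConnectionError(SemviewError):
    """The database behind a ConnectionMeta could not be reached."""


class ViewError(SemviewError):
    """Invalid mapping document."""


class ViewParseError(ViewError):
    """Turtle text could not be parsed into a mapping document."""


class SerializationError(ViewError):
    """Mapping document cannot be rendered (e.g. unresolvable prefix)."""


class ConsistencyError(SemviewError):
    """Mapping document and schema disagree (table sets differ)."""


class AnnotationTargetError(SemviewError):
    """Annotation target column has no property bridge in the view."""


class SelfJoinError(SemviewError):
    """Input and output concept are identical; self joins are unsupported."""


class AnchorError(SemviewError):
    """A concept term is not anchored to any literal column in the view."""


class NoPathError(SemviewError):
    """No join path links the input concept to the output concept."""


class FilterError(SemviewError):
    """Invalid input filter pattern (e.g. empty)."""


class UnsupportedConstructError(SemviewError):
    """SPARQL construct outside the translatable fragment."""

    def __init__(self, construct: str):
        self.construct = construct
        super().__init__(f"unsupported SPARQL construct: {construct}")


class SqlExecutionError(SemviewError):
    """The generated SQL failed at execution time."""


class NamingError(SemviewError):
    """Invalid service name (not an XML NCName)."""
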