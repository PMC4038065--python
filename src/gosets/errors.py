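"""Exception hierarchy shared across the pipeline stages."""


class GosetsError(Exception):
    """Base class for all errors raised by this package."""


class OboParseError(GosetsError):
    """A stanza in the OBO input could not be parsed.

    Carries ``line`` (1-based line number of the offending stanza) when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class OntologyValidationError(GosetsError):
    """The parsed term graph violates a structural requirement (cycle,
    multiple roots in one namespace, cross-namespace part_of edge, orphan)."""


class CacheError(GosetsError):
    """The ontology cache file is unreadable, corrupt, or written by an
    incompatible format version; the caller must re-parse the OBO source."""


class DialectError(GosetsError):
    """An association source does not match its declared dialect
    (e.g. an array annotation file with no GO columns)."""


class ContractViolation(GosetsError):
    """A stage received input that an earlier stage was required to
    normalise first (e.g. propagation over unresolved accessions)."""


class ConfigError(GosetsError):
    """A run configuration is internally inconsistent."""
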