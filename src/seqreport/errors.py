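"""Exception hierarchy for seqreport."""


class SeqReportError(Exception):
    """Base class for all seqreport errors."""


class RegistryError(SeqReportError):
    """The embedded element registry or mapping table is corrupt."""


class NotFoundError(SeqReportError, KeyError):
    """A lookup key (element id, value set, resource id) does not exist."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class UnsupportedTypeError(SeqReportError, ValueError):
    """Resource type outside the supported set."""


class FhirParseError(SeqReportError, ValueError):
    """Malformed FHIR JSON (bad syntax or missing resourceType)."""


class GrammarError(SeqReportError, ValueError):
    """A composite-field grammar (classification, variant notation) did not match."""


class BuildError(SeqReportError):
    """Bundle construction refused; carries the validation issue list."""

    def __init__(self, message, issues=None):
        super().__init__(message)
        self.issues = list(issues or [])


class ExtractionError(SeqReportError):
    """Bundle cannot be interpreted as a sequencing report."""


class ConflictError(SeqReportError):
    """Duplicate client-supplied resource id on create."""


class SearchParameterError(SeqReportError, ValueError):
    """Unsupported search parameter; names the supported keys."""


class AuthorizationError(SeqReportError):
    """Operation denied by the access-token table."""


class VcfError(SeqReportError, ValueError):
    """Malformed VCF input; includes a line number where determinable."""
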