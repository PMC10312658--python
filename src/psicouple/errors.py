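"""Exception hierarchy shared across the package."""


class PsicoupleError(Exception):
    """Base class for package errors."""


class GtfParseError(PsicoupleError):
    """A GTF line could not be parsed; the message names the line number."""


class ValidationError(PsicoupleError):
    """An input violates a structural precondition (e.g. end <= start)."""


class FormatError(PsicoupleError):
    """A file does not conform to its declared format (GCT dims, duplicates)."""


class MissingGeneError(PsicoupleError):
    """No transcript of the requested gene/event is present in the matrix."""


class ConsistencyError(PsicoupleError):
    """Internal data structures disagree (e.g. representative exon missing)."""
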