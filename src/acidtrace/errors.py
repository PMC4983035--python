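"""Exception hierarchy for the acidtrace pipeline.

Every stage raises a subclass of :class:`AcidtraceError` so the pipeline
driver can distinguish validation problems (bad inputs, named offending
records) from programming errors.
"""


class AcidtraceError(Exception):
    """Base class for all acidtrace errors."""


class ParseError(AcidtraceError):
    """Malformed input file (FASTA/Newick/RSA table syntax)."""


class ValidationError(AcidtraceError):
    """Well-formed input that violates a domain invariant."""


class CoordinateError(ValidationError):
    """A 1-based residue interval falls outside the target sequence."""


class LookupError_(AcidtraceError):
    """A referenced id (taxon, sequence, reference row) does not exist."""


class InputError(AcidtraceError):
    """An operation was called with arguments outside its precondition."""
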