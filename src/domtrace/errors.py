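"""Named exceptions raised across the pipeline.

Every contract violation surfaces as one of these so callers (and the CLI)
can report the failing stage without string-matching messages.
"""


class DomtraceError(Exception):
    """Base class for all package errors."""


class ParseError(DomtraceError):
    """Malformed input file; message identifies the offending line."""


class ValidationError(DomtraceError):
    """Invalid configuration or parameter value."""


class InsufficientDataError(DomtraceError):
    """Too few observations/peaks to run the operation."""


class InsufficientRecalibrantsError(DomtraceError):
    """Fewer than the required number of recalibrant pairs / no usable series."""


class ContractViolationError(DomtraceError):
    """Operation applied to inputs outside its stated contract."""


class DegenerateInputError(DomtraceError):
    """Input is degenerate (all-zero spectrum, all-tied ranks, ...)."""


class UnsupportedIonModeError(DomtraceError):
    """Ion mode other than [M-H]- requested."""
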