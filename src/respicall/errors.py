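"""Exception hierarchy for the pipeline."""


class RespicallError(Exception):
    """Base class for all package errors."""


class TraceFormatError(RespicallError):
    """A trace file is missing required columns or is otherwise unreadable."""


class TraceValidationError(RespicallError):
    """A trace violates a structural invariant (time order, ranges, ...)."""


class ScheduleError(RespicallError):
    """The channel-switch schedule is inconsistent (e.g. >3 repetitions)."""


class ReductionDomainError(RespicallError):
    """A physical-domain precondition failed (WVP >= BP, dO2 >= FiO2, ...)."""


class InsufficientDataError(RespicallError):
    """Too few observations/groups for the requested statistical procedure."""
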