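"""Exception hierarchy for dichotrack."""


class DichotrackError(Exception):
    """Base class for all package-specific errors."""


class ContractViolationError(DichotrackError, ValueError):
    """An input violates a documented precondition (e.g. both eyes nonzero
    where monoptic stimulation is required)."""


class FitError(DichotrackError, RuntimeError):
    """An optimizer failed; carries diagnostics in ``args``."""


class FormatError(DichotrackError, ValueError):
    """A delimited-table file violates the trace/trial schema."""


class DegenerateParameterError(DichotrackError, ValueError):
    """A task simulation has no solution for the given observer parameters."""


class UndefinedStatisticError(DichotrackError, ValueError):
    """A requested statistic (correlation, reliability) is undefined on the
    given data, e.g. a constant column or a fully masked trial."""
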