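"""Exception hierarchy shared across the analysis modules."""


class OrgMatrixError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(OrgMatrixError, ValueError):
    """A synthetic-data spec violates one of its invariants."""


class InvalidInputError(OrgMatrixError, ValueError):
    """An input (image, table, curve) does not satisfy a precondition."""


class InvalidThresholdError(OrgMatrixError, ValueError):
    """A threshold box is malformed (min > max or out of channel range)."""


class UndefinedStatisticError(OrgMatrixError, ArithmeticError):
    """A statistic is undefined on this input (e.g. zero variance)."""


class NoContactError(OrgMatrixError, RuntimeError):
    """No probe-sample contact could be located in a force curve."""


class FitFailureError(OrgMatrixError, RuntimeError):
    """A model fit produced a non-physical result."""


class EmptyGroupError(OrgMatrixError, ValueError):
    """A grouping operation received an empty group."""
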