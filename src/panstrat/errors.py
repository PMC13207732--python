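"""Exception types shared across panstrat modules."""


class PanstratError(Exception):
    """Base class for all panstrat errors."""


class ValidationError(PanstratError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(PanstratError, ValueError):
    """A file could not be parsed; the message names the offending cell."""


class GeneLookupError(PanstratError, KeyError):
    """A requested gene, gene set, or data layer is absent."""


class DegenerateStratificationError(PanstratError, ValueError):
    """Quantile thresholds coincide, so high/low groups cannot be formed."""


class UndefinedRangeError(PanstratError, ValueError):
    """Max/min expression ratio undefined (non-positive values present)."""


class SingularDesignError(PanstratError, ValueError):
    """Regression design matrix is singular (perfectly collinear predictors)."""
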