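"""Exception hierarchy shared by all armimu modules."""


class ArmimuError(Exception):
    """Base class for every error raised by this package."""


class InputError(ArmimuError, ValueError):
    """Invalid argument values or mismatched shapes."""


class DegenerateWindowError(ArmimuError, ValueError):
    """A detector window whose mean specific force has (near-)zero norm."""


class DegenerateGeometryError(ArmimuError, ValueError):
    """Coincident circles or otherwise unsolvable geometric configuration."""


class ReachabilityError(ArmimuError, ValueError):
    """Wrist position outside the reachable annulus beyond tolerance."""


class StateError(ArmimuError, ValueError):
    """Filter state violates an invariant (non-unit quaternion, non-PSD covariance)."""


class NumericalError(ArmimuError, ArithmeticError):
    """Singular innovation covariance or other numerical failure."""


class ConstantTemplateError(ArmimuError, ValueError):
    """Template with zero variance: normalized cross-correlation is undefined."""


class ConstantSeriesError(ArmimuError, ValueError):
    """Constant input series: Pearson correlation is undefined."""
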