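"""Exception and warning types shared across the package."""


class DryshrinkError(Exception):
    """Base class for all dryshrink errors."""


class ConfigError(DryshrinkError, ValueError):
    """Invalid configuration (bad population size, threshold, order, ...)."""


class DataError(DryshrinkError, ValueError):
    """Invalid or inconsistent input data (series, images, model files)."""


class LayoutError(DryshrinkError, ValueError):
    """Synthetic scene layout is infeasible (e.g. overlapping disks)."""


class MonotonicityError(DryshrinkError, ValueError):
    """The configured moisture-ratio/shrinkage link is not monotone on its range."""


class DegenerateHistogramWarning(UserWarning):
    """Thresholding saw a constant (single-bin) image."""


class TieBreakWarning(UserWarning):
    """A deterministic tie-break rule was exercised (e.g. equal particle areas)."""


class EmptyForegroundWarning(UserWarning):
    """A binary mask contained no foreground pixels."""


class UnderdeterminedFitWarning(UserWarning):
    """Fewer observations than model parameters."""


class DegenerateInitWarning(UserWarning):
    """Population initialisation range has zero width."""


class PerfectFitWarning(UserWarning):
    """Residual variance is exactly zero; log-likelihood is unbounded."""
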