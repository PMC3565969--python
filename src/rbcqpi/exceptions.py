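"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`RbcQpiError`, so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class RbcQpiError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(RbcQpiError, ValueError):
    """Invalid or inconsistent optical/pipeline configuration."""


class ParameterError(RbcQpiError, ValueError):
    """Invalid numeric parameter (negative concentration, infeasible truncation, ...)."""


class PlacementError(RbcQpiError, ValueError):
    """A phantom cell does not fit on the requested grid."""


class FringeSamplingError(RbcQpiError, ValueError):
    """Carrier frequency violates the 3-pixels-per-fringe sampling rule."""


class NoFringeError(RbcQpiError, ValueError):
    """No first-order spectral lobe found above the noise floor."""


class LobeOverlapError(RbcQpiError, ValueError):
    """Hilbert filter radius would mix the first-order lobe with baseband."""


class GridMismatchError(RbcQpiError, ValueError):
    """Two maps that must share a grid do not."""


class DegenerateCellError(RbcQpiError, ValueError):
    """Empty or too-small cell mask for the requested measurement."""


class InfeasibleShapeError(RbcQpiError, ValueError):
    """Surface area / volume combination has no physical deformation (sphericity > 1)."""


class NoCellsError(RbcQpiError, ValueError):
    """Population statistic requested on an empty record set."""


class InsufficientDataError(RbcQpiError, ValueError):
    """Statistic needs more records than were supplied."""
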