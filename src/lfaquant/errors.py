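"""Exception types raised by the strip-reading pipeline.

Every stage raises a distinct subclass so batch drivers can attribute a
failure to the stage that produced it.
"""


class LFAError(Exception):
    """Base class for all pipeline errors."""


class StripNotFoundError(LFAError):
    """No plausible strip quadrilateral was detected in the photograph."""


class DegeneratePoseError(LFAError, ValueError):
    """Quadrilateral corners are collinear or non-convex."""


class LadderUnusableError(LFAError):
    """Fewer than two usable reference-line points survive outlier removal,
    or the ladder design matrix is rank deficient."""


class CalibrationError(LFAError):
    """Calibration curve is invalid (e.g. non-increasing over its ladder)."""


class ControlSignalError(LFAError):
    """Control-line standardized signal is non-positive; the run is invalid
    (maps to the 'insufficient reaction' QC condition)."""


class ConfigurationError(LFAError, ValueError):
    """Geometry/configuration is inconsistent (e.g. a background flank
    window overlaps another line window)."""
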