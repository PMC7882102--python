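"""Exception hierarchy shared by all fracdose modules."""


class FracdoseError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FracdoseError, ValueError):
    """An argument is outside its documented domain (non-finite, negative, ...)."""


class GeometryError(FracdoseError):
    """A geometric precondition is violated (structure outside grid, source inside volume)."""


class FrameError(FracdoseError):
    """Two grids that must share a coordinate frame do not."""


class CalibrationError(FracdoseError):
    """An HU-to-density curve is malformed (too few points, non-monotone HU)."""


class ConfigurationError(FracdoseError):
    """A required configuration entry is missing or inconsistent."""


class FormatError(FracdoseError):
    """A file does not match any supported dialect."""


class IntegrityError(FracdoseError):
    """A file matches a dialect but its content is internally inconsistent."""


class DegenerateROIError(FracdoseError):
    """An ROI entering a DVH computation is empty."""


class FeasibilityError(FracdoseError):
    """A synthetic plan violates a machine constraint (e.g. leaf speed)."""


class EmptyCourseError(FracdoseError):
    """All fractions of a course are excluded; nothing to accumulate."""


class InsufficientDataError(FracdoseError):
    """A statistical test was requested with too few observations."""
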