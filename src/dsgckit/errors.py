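"""Exception types shared across the pipeline stages."""


class DsgckitError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgumentError(DsgckitError, ValueError):
    """An argument violates a documented precondition."""


class InvalidInputError(DsgckitError, ValueError):
    """Input data violate a structural contract (ragged traces, missing directions...)."""


class UndefinedDirectionError(DsgckitError):
    """A directional statistic is undefined (e.g. vector sum of a symmetric curve)."""


class UndefinedDsiError(DsgckitError):
    """DSI requested with zero total response."""


class InstabilityError(DsgckitError):
    """Forward-Euler integration diverged; message names the required dt bound."""


class DegenerateGeometryError(DsgckitError, ValueError):
    """Fewer than three non-collinear points supplied for a convex hull."""


class CalibrationError(DsgckitError):
    """Camera calibration is impossible (zero inter-camera distance, no paired frames)."""


class UnrecoverableTraceError(DsgckitError):
    """No frame in a marker stream ever had enough high-confidence markers."""


class ConfigError(DsgckitError, ValueError):
    """A run configuration field is missing or out of its documented range."""
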