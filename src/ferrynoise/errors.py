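"""Exception hierarchy for the ferry-noise pipeline."""


class FerryNoiseError(Exception):
    """Base class for all package errors."""


class InvalidEnvironmentError(FerryNoiseError):
    """Environment description violates a physical invariant."""


class NoCutoffError(FerryNoiseError):
    """No modal cutoff exists (seabed not faster than water)."""


class InvalidRangeError(FerryNoiseError):
    """Propagation range below the 1-m reference."""


class InvalidCoordinateError(FerryNoiseError):
    """Latitude/longitude outside valid bounds."""


class InsufficientDataError(FerryNoiseError):
    """Too few samples for the requested operation."""


class NoCPAError(FerryNoiseError):
    """Track has no usable distance samples."""


class SinglePeakError(FerryNoiseError):
    """Speed-change window lacks the double-peak signature."""


class StationaryTrackError(FerryNoiseError):
    """Smoothed STW never exceeds the motion threshold."""


class UnusableTransitError(FerryNoiseError):
    """Transit excluded (AIS gap, failed detection, missing extraction)."""


class MissingValueError(FerryNoiseError):
    """No series block close enough to the requested timestamp."""


class ConfigError(FerryNoiseError):
    """Scenario or run configuration is inconsistent."""
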