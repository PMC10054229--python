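"""Exception hierarchy shared across the analysis stages."""


class PbmWoundError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PbmWoundError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DomainError(PbmWoundError, ValueError):
    """An argument outside the physically meaningful domain of an operation."""


class InsufficientDataError(PbmWoundError, ValueError):
    """Too few points / groups / animals to carry out the requested analysis."""


class UnreachableLevelError(DomainError):
    """A milestone level at or below the fitted plateau is never attained."""


class FitConvergenceError(PbmWoundError, RuntimeError):
    """The nonlinear least-squares optimizer did not converge; carries its status."""


class GeometryError(PbmWoundError, ValueError):
    """Invalid mask / region geometry (empty, fragmented, overlapping, outside)."""


class CalibrationError(PbmWoundError, ValueError):
    """Reference-card calibration impossible (equal/inverted patch intensities)."""


class SaturationError(PbmWoundError, ValueError):
    """Too many saturated pixels inside a measurement region."""


class SchemaError(PbmWoundError, ValueError):
    """A CSV file does not match the expected column schema."""


class DataError(PbmWoundError, ValueError):
    """A structurally valid file contains rows that violate the data contract."""


class DegenerateDataError(PbmWoundError, ValueError):
    """Data degenerate for the requested test (e.g. all paired differences zero)."""
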