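"""Exception hierarchy for calibration and scoring failures."""


class IhccalError(Exception):
    """Base class for all package errors."""


class GridMismatchError(IhccalError):
    """Spectral tables do not share the expected wavelength grid."""


class LayoutError(IhccalError):
    """A chart/bead layout is inconsistent with the image or patch set."""


class EncodingError(IhccalError):
    """An image carries the wrong encoding tag for an operation."""


class CalibrationError(IhccalError):
    """A calibration fit is infeasible or degenerate."""


class MissingLevelError(CalibrationError):
    """A calibrator bead level could not be located in the image."""


class InsufficientDataError(CalibrationError):
    """Too few usable observations for a fit."""


class ConfigError(IhccalError):
    """Pipeline configuration is incomplete or contradictory."""
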