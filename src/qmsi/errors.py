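"""Exception hierarchy for the qmsi pipeline."""


class QmsiError(Exception):
    """Base class for all qmsi errors."""


class GridFormatError(QmsiError):
    """Malformed channel-grid file (duplicates, undeclared channels, bad values)."""


class LayoutError(QmsiError):
    """Invalid mimetic-array layout (overlapping or out-of-bounds wells, bad roles)."""


class ConfigError(QmsiError):
    """Invalid run configuration or simulation parameters."""


class RoiError(QmsiError):
    """Invalid region of interest (empty, out of bounds, zero cell density)."""


class UndefinedRatioError(QmsiError):
    """Analyte/reference ratio undefined because the reference sum is zero."""


class CalibrationError(QmsiError):
    """Calibration could not be built or is invalid (too few levels, slope <= 0)."""


class GeometryError(QmsiError):
    """Array geometry leaves no pixels for a required region (e.g. corridor)."""


class ConcordanceError(QmsiError):
    """MSI and LC-MS sample identifiers cannot be matched."""
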