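"""Exception hierarchy for dectquant."""


class DectQuantError(Exception):
    """Base class for all dectquant errors."""


class GeometryError(DectQuantError):
    """Inconsistent grids, masks outside bodies, overlapping vials."""


class ConfigurationError(DectQuantError):
    """Invalid scenario / pipeline configuration."""


class MeasurementError(DectQuantError):
    """Empty ROI or otherwise unusable measurement region."""


class DegenerateDesignError(DectQuantError):
    """Calibration design cannot identify a slope (e.g. one concentration)."""


class SingularSystemError(DectQuantError):
    """Sensitivity matrix not invertible within the configured condition cap."""


class CalibrationError(DectQuantError):
    """Calibration fit unusable for decomposition."""


class AssayInvalidError(DectQuantError):
    """Haemolysis assay controls do not define a positive denominator."""


class InputError(DectQuantError):
    """Mismatched or malformed user inputs (lengths, organ name sets, ...)."""
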