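"""Exception hierarchy for compcal."""


class CompCalError(Exception):
    """Base class for all compcal errors."""


class FormatError(CompCalError):
    """A file does not conform to the expected layout."""


class ConfigError(CompCalError):
    """The standards configuration is inconsistent."""


class DesignError(CompCalError):
    """The calibration design is unusable."""


class DegenerateDesignError(DesignError):
    """All dilution factors coincide; the slope is unidentifiable."""


class InsufficientPointsError(DesignError):
    """Fewer than three calibration points; the error variance is undefined."""


class NonPositiveSensitivityError(CompCalError):
    """Inverse prediction refused for a channel with non-positive sensitivity."""


class MissingCalibrationError(CompCalError, KeyError):
    """An assay channel has no fitted calibration."""
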