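"""Exception and warning types shared across the package."""


class WoodhaulError(Exception):
    """Base class for package errors."""


class ConfigError(WoodhaulError):
    """A configuration value is outside its designed range."""


class CalibrationError(WoodhaulError):
    """Climate-forcing calibration could not reach its biomass target."""


class HarvestContractError(WoodhaulError):
    """A harvest trip was issued against a patch with no harvestable wood."""


class ExperimentError(WoodhaulError):
    """A simulation run inside an experiment failed."""


class EquilibriumWarning(UserWarning):
    """Spin-up ended before the live-biomass trend criterion was met."""
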