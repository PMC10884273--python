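"""Exception hierarchy for rdsem."""


class RdsemError(Exception):
    """Base class for all rdsem errors."""


class PanelFormatError(RdsemError):
    """A panel file or frame does not have the required layout."""


class PanelIntegrityError(RdsemError):
    """Panel content violates an invariant (duplicates, out-of-range values)."""


class StateError(RdsemError):
    """Operation called on a dataset in the wrong state (e.g. double rescale)."""


class ConfigError(RdsemError):
    """Invalid generating or sampler configuration."""


class CalibrationError(RdsemError):
    """Standardized targets cannot be mapped to a stationary generating process."""


class SpecError(RdsemError):
    """Invalid model specification."""


class EstimationError(RdsemError):
    """Estimation cannot proceed (empty data, degenerate strata, ...)."""


class DegenerateStratumError(EstimationError):
    """A stratified comparison has an empty stratum."""


class StandardizationError(RdsemError):
    """Model-implied variance is zero or undefined during standardization."""
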