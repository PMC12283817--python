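class CasefindError(Exception):
    """Base class for all package errors."""


class ConfigError(CasefindError, ValueError):
    """Invalid generator or parameter configuration; names the offending field."""


class CalibrationError(CasefindError, ValueError):
    """Requested calibration target is unattainable."""


class EstimationError(CasefindError, ValueError):
    """An estimate is undefined for the given data (e.g. empty stratum)."""


class ScenarioError(CasefindError, ValueError):
    """A scenario override path does not resolve to a model parameter."""
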