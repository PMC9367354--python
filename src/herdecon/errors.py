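"""Exception hierarchy."""


class HerdeconError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HerdeconError):
    """A config file is missing a mandatory key or cannot be parsed."""


class ValidationError(HerdeconError, ValueError):
    """A parameter value is outside its valid range."""


class SimulationError(HerdeconError):
    """The herd simulation reached an unrecoverable state."""


class ScenarioError(HerdeconError, ValueError):
    """A scenario perturbation leaves the valid parameter range."""


class RegressionError(HerdeconError, ValueError):
    """The regression design matrix is unusable (rank / size)."""
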