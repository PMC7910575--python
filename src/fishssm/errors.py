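"""Exception types shared across modules."""


class StabilityError(ValueError):
    """Raised when the discrete-time movement update would diverge (k*dt >= 1)."""


class ConfigurationError(ValueError):
    """Raised when required configuration (calibration, covariate tables, ...) is missing."""


class ClippingError(ValueError):
    """Raised when a synthetic signal would exceed 16-bit full scale."""


class InitializationError(RuntimeError):
    """Raised when MCMC cannot find a finite-density starting point."""
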