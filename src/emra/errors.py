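"""Exception types shared across the package."""


class EmraError(Exception):
    """Base class for all package-specific errors."""


class ModelFormatError(EmraError, ValueError):
    """A model file could not be parsed or violates a structural invariant."""


class FluxImbalanceError(EmraError, ValueError):
    """The reference flux does not balance the stoichiometry (S @ vref != 0)."""

    def __init__(self, message, metabolites=None):
        super().__init__(message)
        self.metabolites = list(metabolites or [])


class ConfigurationError(EmraError, ValueError):
    """A user-supplied name, scheme, or option is unknown or inconsistent."""


class NumericalError(EmraError, RuntimeError):
    """A numerical routine produced non-finite values or failed irrecoverably."""


class SamplingError(EmraError, RuntimeError):
    """Ensemble sampling could not reach its quota (acceptance rate too low)."""
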