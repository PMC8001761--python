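"""Exception types shared across the package."""


class NirFatError(ValueError):
    """Base class for domain errors raised by this package."""


class ConfigurationError(NirFatError):
    """An invalid configuration value; the message names the field."""


class DegenerateReferenceError(NirFatError):
    """Light and dark reference scans coincide at an analysis wavelength."""


class CoverageError(NirFatError):
    """The native wavelength grid leaves an analysis bin empty."""


class ModelDomainError(NirFatError):
    """An input lies outside the fitted/defined domain of a model."""


class SelectionError(NirFatError):
    """Feature selection could not produce a usable model."""
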