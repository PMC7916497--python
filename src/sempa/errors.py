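"""Exception and warning types used across the package."""


class SempaError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SempaError, ValueError):
    """A scalar parameter is outside its physical domain."""


class InvalidSpectrumError(SempaError, ValueError):
    """A spectrum violates an invariant of its declared kind."""


class GridMismatchError(SempaError, ValueError):
    """Two spectra that must share a wavelength grid do not."""


class RangeError(SempaError, ValueError):
    """Requested wavelengths fall outside a model's validity range."""


class ConfigurationError(SempaError, ValueError):
    """Required configuration (tables, metadata) is missing or inconsistent."""


class SaturationError(SempaError, ValueError):
    """Transmittance reached zero: extinction cannot be recovered."""


class QCFailureError(SempaError, RuntimeError):
    """No measurement in a dilution series passed quality control."""


class DegenerateInputError(SempaError, ValueError):
    """Input is identically zero or otherwise carries no information."""


class ModelInconsistencyError(SempaError, ValueError):
    """A closed-form solver produced a physically impossible (negative) value."""


class KKPaddingWarning(UserWarning):
    """Kramers-Kronig input grid extends less than the recommended margin
    beyond the output window; truncation error may be non-negligible."""
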