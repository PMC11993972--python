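"""Exception types shared across the package."""


class MedflySitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MedflySitError, ValueError):
    """An operation was called with an out-of-range or inconsistent argument."""


class ConfigError(MedflySitError, ValueError):
    """A configuration file or parameter set failed validation."""


class CalibrationError(MedflySitError, RuntimeError):
    """Equilibrium calibration failed to produce a stationary population."""
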