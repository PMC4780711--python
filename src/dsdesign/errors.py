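"""Exception hierarchy shared across the package."""


class DsdesignError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DsdesignError, ValueError):
    """A detection-function parameter vector violates its domain."""


class CalibrationError(DsdesignError, RuntimeError):
    """Scale calibration to a target mean detection rate failed."""


class NumericError(DsdesignError, RuntimeError):
    """Quadrature, matrix inversion or another numeric step failed."""


class ConfigError(DsdesignError, ValueError):
    """A configuration file or CLI argument combination is invalid."""
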