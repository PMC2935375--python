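"""Exception hierarchy shared across the package."""


class ReplicadeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ReplicadeError):
    """Invalid configuration or input data; message names the offending field."""


class ConfoundingError(ReplicadeError):
    """Design matrix is rank deficient, e.g. a batch aliased with rat line."""


class SchemaError(ReplicadeError):
    """A table is missing required columns or carries malformed values."""


class CalibrationError(ReplicadeError):
    """A qPCR standard curve could not be fitted or is physically invalid."""
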