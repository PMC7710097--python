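"""Exception hierarchy used across the package."""


class ValidationError(ValueError):
    """Input data violates a documented precondition."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns or has bad values."""


class DimensionalityError(ValidationError):
    """A volume does not have the expected number of axes."""


class GeometryError(ValidationError):
    """A geometric construction is degenerate (e.g. collinear landmarks)."""


class ConfigurationError(ValueError):
    """Required configuration (weights, thresholds) was not supplied."""
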