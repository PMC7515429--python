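"""Exception hierarchy: thin ValueError subclasses so callers can catch broadly."""


class RLDAMPError(ValueError):
    """Base class for all package-specific errors."""


class ParameterError(RLDAMPError):
    """A scalar parameter is outside its admissible range."""


class DimensionError(RLDAMPError):
    """Array shapes or lengths are inconsistent."""


class ConfigurationError(RLDAMPError):
    """Unknown plug-in name or invalid configuration block."""


class DataError(RLDAMPError):
    """Non-finite or otherwise unusable input data."""


class AggregationError(RLDAMPError):
    """Patch aggregation found a pixel covered by no patch."""


class DivergenceError(RLDAMPError):
    """The solver iterates became non-finite; carries the iteration index."""

    def __init__(self, message: str, iteration: int):
        super().__init__(message)
        self.iteration = iteration
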