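class LtrscapeError(Exception):
    """Base class for all ltrscape errors."""


class ParameterError(LtrscapeError, ValueError):
    """Invalid parameter value or range."""


class PlanningError(LtrscapeError):
    """Insertion plans conflict (overlapping or out-of-bounds sites)."""

    def __init__(self, message, collisions=None):
        super().__init__(message)
        self.collisions = list(collisions or [])


class ConfigurationError(LtrscapeError):
    """Inconsistent run configuration or family model."""
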