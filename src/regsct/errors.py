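"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value violates a documented precondition."""


class ShapeError(ValueError):
    """Array shapes are incompatible with the requested operation."""


class CheckpointError(RuntimeError):
    """A checkpoint file is missing, corrupt, or version-incompatible."""
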