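"""Exception types shared across the library."""


class DcopError(Exception):
    """Base class for library errors."""


class EmptyMask(DcopError):
    """A mask with (near-)zero foreground where foreground is required."""


class DegeneratePrototype(DcopError):
    """A prototype with (near-)zero norm cannot be cosine-scored."""


class ShapeMismatch(DcopError):
    """Spatial or channel extents of two inputs are inconsistent."""


class EmptyPrediction(DcopError):
    """A predicted mask is too empty to pool a prototype from."""


class UnknownStrategy(DcopError):
    """A prototype-refinement strategy name is not registered."""


class ConfigError(DcopError):
    """An invalid or inconsistent configuration was supplied."""


class CheckpointError(DcopError):
    """A checkpoint file is unreadable or incompatible."""
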