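class InvalidConfigError(ValueError):
    """Raised when a model or pipeline configuration violates its invariants."""


class ShapeError(ValueError):
    """Raised when an input shape is incompatible with an architecture."""
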