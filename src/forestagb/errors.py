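"""Exception types shared across the package."""


class ConfigError(ValueError):
    """An invalid configuration value (non-positive extent, bad ratio, ...)."""


class SchemaError(ValueError):
    """A table is missing required columns or carries unexpected ones."""


class EmptyPlotError(ValueError):
    """A plot footprint contains no usable LiDAR returns."""
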