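"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A config value violates an invariant (e.g. image size not divisible by patch size)."""


class ShapeError(ValueError):
    """An array does not have the shape an operation requires."""


class IncompatibilityError(ValueError):
    """Two weight sets (or a state file and a model) do not share keys/shapes."""


class EmptyDataError(ValueError):
    """An operation that needs at least one sample received none."""


class DivergenceError(RuntimeError):
    """Local optimization produced a non-finite loss."""


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. single-class labels for AUC)."""


class LayoutError(OSError):
    """An on-disk dataset does not follow the expected split/class folder layout."""
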