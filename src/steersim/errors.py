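"""Exception types shared across the pipeline."""


class InvalidParameterError(ValueError):
    """A parameter is outside its valid domain."""


class PlacementError(RuntimeError):
    """A lesion cannot be placed at the requested position."""


class AlignmentError(ValueError):
    """Two arrays that must share a grid do not."""


class ConfigurationError(ValueError):
    """A configuration object is inconsistent or incomplete."""


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. a class is absent)."""
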