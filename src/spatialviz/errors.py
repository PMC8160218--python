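"""Exception hierarchy shared across the toolkit."""


class SpatialVizError(Exception):
    """Base class for all toolkit errors."""


class DimensionMismatchError(SpatialVizError):
    """Images, masks or stacks do not share the same 2-D shape."""


class FormatError(SpatialVizError):
    """A file's content violates the expected format (duplicate markers,
    non-integer label values, ...)."""


class SchemaError(SpatialVizError):
    """A tabular file is missing required columns."""


class ConfigError(SpatialVizError):
    """Invalid or incomplete analysis configuration."""


class EmptyInputError(SpatialVizError):
    """An operation received an empty point set, sample or cluster."""


class DegenerateInputError(SpatialVizError):
    """Input is formally valid but the statistic is undefined on it
    (zero variance, no positive cells, ...)."""


class GenerationError(SpatialVizError):
    """Synthetic phantom generation failed (e.g. cell packing limit)."""


class DependencyError(SpatialVizError):
    """A pipeline stage was requested without its upstream artifacts."""
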