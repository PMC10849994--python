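"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PipelineError` so callers (CLI,
cross-validation loops) can distinguish data problems from programming
errors.
"""


class PipelineError(ValueError):
    """Base class for all pipeline-level errors."""


class MatrixFormatError(PipelineError):
    """Malformed expression matrix or annotation file."""


class AlignmentError(PipelineError):
    """Matrix and annotation share no samples."""


class NormalizationError(PipelineError):
    """A sample column cannot be normalized (e.g. constant values)."""


class DecompositionError(PipelineError):
    """PCA preconditions violated (unnormalized input, degenerate shape)."""


class EmptySelectionError(PipelineError):
    """A selection step produced an empty set and no override was given."""


class DiscriminationError(PipelineError):
    """Classifier fitting or evaluation cannot proceed."""
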