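"""Exception hierarchy shared across the package."""


class BucketEvalError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(BucketEvalError, ValueError):
    """An argument is outside its documented domain."""


class EmptyInputError(BucketEvalError, ValueError):
    """An operation received no usable data."""


class ShapeError(BucketEvalError, ValueError):
    """Dimensions of an input do not match what the operation requires."""


class IncompatibleSchemeError(BucketEvalError, ValueError):
    """Two bucket assignments do not share the same scheme or gene set."""


class NormalizationError(BucketEvalError, ValueError):
    """A similarity matrix cannot be rescaled (non-positive maximum)."""


class UntestableError(BucketEvalError, ValueError):
    """A statistical comparison has an empty group and cannot be run."""


class FormatError(BucketEvalError, ValueError):
    """A file does not conform to the expected tabular dialect."""
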