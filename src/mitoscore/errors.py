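"""Exception and warning types shared across the package."""


class MitoscoreError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(MitoscoreError):
    """Input array does not have the expected dimensionality or shape."""


class EmptyRegionError(MitoscoreError):
    """A polygon region is degenerate (zero area) or covers no pixels."""


class PackingError(MitoscoreError):
    """Synthetic object placement failed after bounded retries."""


class AnnotationParseError(MitoscoreError):
    """Annotation file is not valid JSON; message carries line context."""


class AnnotationValidationError(MitoscoreError):
    """A polygon annotation is malformed (too few vertices, self-intersecting)."""


class DegenerateHistogramWarning(UserWarning):
    """Otsu thresholding received a constant-intensity input; mask returned unchanged."""
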