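"""Exception hierarchy for the segmentation pipeline."""


class AdipoQuantError(Exception):
    """Base class for all pipeline errors."""


class GeometryError(AdipoQuantError):
    """Inconsistent or invalid image geometry (spacing, shape, slice mismatch)."""


class NoBodyDetected(AdipoQuantError):
    """Adaptive thresholding found no foreground body region."""


class ContourCollapsed(AdipoQuantError):
    """The evolving contour's enclosed area shrank to zero."""


class ContainmentLost(AdipoQuantError):
    """The evolving contour reached the image border."""


class ValidationError(AdipoQuantError, ValueError):
    """Invalid parameter or input value."""
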