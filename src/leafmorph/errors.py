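"""Exception hierarchy."""


class LeafmorphError(Exception):
    """Base class for all leafmorph errors."""


class InvalidInputError(LeafmorphError, ValueError):
    """Input image or parameter violates a precondition."""


class EmptySegmentationError(LeafmorphError):
    """Segmentation produced no foreground."""


class DegenerateShapeError(LeafmorphError):
    """Region too small/degenerate for the requested descriptor."""
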