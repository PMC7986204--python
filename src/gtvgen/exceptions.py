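"""Exception hierarchy for gtvgen.

All package errors derive from :class:`GtvGenError` so callers can catch one
base type at pipeline level while tests discriminate precise failure modes.
"""


class GtvGenError(Exception):
    """Base class for all gtvgen errors."""


class FormatError(GtvGenError):
    """A file could not be read in a supported volume/contour format."""


class ShapeError(GtvGenError):
    """An image payload does not have the expected dimensionality/shape."""


class GridMismatchError(GtvGenError):
    """Two objects that must share a grid geometry do not."""


class EmptyMaskError(GtvGenError):
    """An operation received an empty mask where a non-empty one is required."""


class ContourPlacementError(GtvGenError):
    """A contour slice does not lie on (or near) a slice plane of the grid."""


class ParameterError(GtvGenError):
    """An operation received an invalid parameter value."""


class BoundsError(GtvGenError):
    """A synthetic shape or trajectory does not fit inside the grid."""


class DegenerateMaskError(GtvGenError):
    """A perturbation or shift emptied the mask entirely."""


class UndefinedCostError(GtvGenError):
    """The correlation-ratio cost is undefined (no intensity variance)."""


class RegistrationFailure(GtvGenError):
    """A phase registration could not produce a valid translation/cost."""


class NoValidRegistrationError(GtvGenError):
    """All VOI-method registration outcomes failed; nothing to select."""


class GenerationFailure(GtvGenError):
    """The envelope intersection is empty: complete generation failure."""
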