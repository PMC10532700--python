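"""Exception hierarchy shared by all pipeline stages.

Each stage failure maps to one subclass so that callers (and the CLI exit
codes) can tell a malformed request apart from degenerate data.
"""


class PostopError(Exception):
    """Base class for all postop3d errors."""


class FormatError(PostopError):
    """File could not be read or written in a supported volume format."""


class DimensionalityError(FormatError):
    """Image on disk is not a 3D scalar volume."""


class MisuseError(PostopError):
    """API contract violation (wrong shapes, invalid parameters, ...)."""


class DegenerateInputError(PostopError):
    """Input is valid in form but carries no usable information
    (constant intensities, collinear points, rank-deficient fits)."""


class EmptyCropError(PostopError):
    """Requested crop box does not intersect the volume."""


class EmptyFragmentError(PostopError):
    """Fragment mask construction selected no voxels."""


class PhantomGenerationError(PostopError):
    """Random plane draws failed to isolate a closed fragment."""


class DetectionFailure(PostopError):
    """A per-structure detection (plane, landmark) could not be computed."""
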