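"""Exception hierarchy."""


class PmctseqError(Exception):
    """Base class for all package errors."""


class CollapseError(PmctseqError):
    """The requested ventricle volume is non-positive at some time point.

    Signals the regime where the ventricle has narrowed past the point of
    measurability; callers that want to keep the degenerate time points
    (to exercise downstream QC) should generate with ``on_collapse="clamp"``.
    """


class GridTooSmallError(PmctseqError):
    """The requested structure cannot be voxelized on the given grid."""


class EmptyMaskError(PmctseqError):
    """An operation requiring a nonempty mask received an empty one."""


class GridMismatchError(PmctseqError):
    """Arrays that must share a voxel grid do not."""


class RegistrationDivergenceError(PmctseqError):
    """The registration objective increased instead of decreasing."""


class ZeroSlopeError(PmctseqError):
    """A fitted trend with zero slope cannot be inverted for the PMI."""
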