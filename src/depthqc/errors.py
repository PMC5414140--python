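"""Exceptions and warnings used across depthqc."""


class DepthQCError(Exception):
    """Base class for all depthqc errors."""


class InvalidInputError(DepthQCError, ValueError):
    """Malformed or inconsistent user input (dimension mismatch, bad labels...)."""


class InvalidParameterError(DepthQCError, ValueError):
    """A parameter outside its allowed range (e.g. fence factor < 1)."""


class DegenerateInputError(DepthQCError, ValueError):
    """Input with no usable variation (constant matrix, empty region...)."""


class DegenerateGridError(DepthQCError, ValueError):
    """A depth grid on which no node attains depth >= 1."""


class EmptyRegionError(DepthQCError, ValueError):
    """Requested depth level exceeds the maximal depth on the grid."""


class GroupTooSmallError(DepthQCError, ValueError):
    """Group below the minimum size for bag construction; use the boxplot path."""


class DataError(DepthQCError, ValueError):
    """File-level parse or validation problem."""


class DepthQCWarning(UserWarning):
    """Base class for depthqc warnings."""


class DegenerateCloudWarning(DepthQCWarning):
    """Point cloud is rank-deficient; depth computed in its affine span."""


class DegenerateRegionWarning(DepthQCWarning):
    """A hull degenerated to fewer than p+1 affinely independent points."""


class KStarFallbackWarning(DepthQCWarning):
    """No depth level satisfied the bag rule; fell back to the maximal depth."""


class GroupSkippedWarning(DepthQCWarning):
    """An experimental group was skipped by a detection method."""
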