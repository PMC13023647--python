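"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`MaskError` and its subclasses map
to exit code 2 (input/validation problems), :class:`GeometryError` and its
subclasses to exit code 3 (a landmark could not be constructed).
"""


class FourCVError(Exception):
    """Base class for all package errors."""


class MaskError(FourCVError):
    """Problems with mask files or mask-set validity."""


class MaskLoadError(MaskError):
    """A structure file is missing or unreadable."""


class MaskFormatError(MaskError):
    """Rasters disagree in shape or are otherwise malformed."""


class SpecError(MaskError):
    """An infeasible phantom specification."""


class GeometryError(FourCVError):
    """A geometric construction failed."""


class EmptyRegionError(GeometryError):
    """An operation that requires foreground got an empty raster."""


class DegenerateFitError(GeometryError):
    """Too few pixels, or an isotropic region, for a principal-axis fit."""


class NoHollowError(GeometryError):
    """The convex envelope of the thorax leaves no residual (no spine hollow)."""


class BisectFailureError(GeometryError):
    """No line orientation balances the half-plane areas acceptably."""


class ParallelLinesError(GeometryError):
    """Two lines that should intersect are parallel."""


class DegenerateAngleError(GeometryError):
    """An angle was requested with a zero-length arm."""


class IndeterminateSideError(GeometryError):
    """A point lies on the reference line, so its side is undefined."""


class NoIntersectionError(GeometryError):
    """A required line/contour intersection does not exist."""


class DegenerateChordError(GeometryError):
    """A normalization chord has (near-)zero length."""


class AggregationError(FourCVError):
    """Empty or inconsistent input to an aggregation step."""


class PairingError(FourCVError):
    """Paired sequences disagree in length."""


class DegenerateLabelsError(FourCVError):
    """ROC analysis needs at least one positive and one negative label."""
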