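"""Raster and planar geometry primitives behind the landmark construction.

Everything here is pure computation on binary rasters and points in the
image coordinate convention of :mod:`fourcv.mask_io` (x right, y down,
pixel centers at integer coordinates).  Angles are reported in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point as ShapelyPoint
from skimage import measure, morphology

from .exceptions import (
    BisectFailureError,
    DegenerateAngleError,
    DegenerateFitError,
    EmptyRegionError,
    NoHollowError,
    ParallelLinesError,
)

#: 8-connectivity structuring element for component labeling.
_EIGHT = np.ones((3, 3), dtype=bool)


class PlanarPoint(NamedTuple):
    """A point in continuous pixel coordinates."""

    x: float
    y: float


@dataclass(frozen=True)
class OrientedLine:
    """An infinite line given by an anchor point and a unit direction."""

    anchor: PlanarPoint
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        dx, dy = self.direction
        norm = float(np.hypot(dx, dy))
        if abs(norm - 1.0) > 1e-9:
            if norm == 0.0:
                raise ValueError("zero-length direction")
            object.__setattr__(self, "direction", (dx / norm, dy / norm))

    def point_at(self, t: float) -> PlanarPoint:
        return PlanarPoint(
            self.anchor.x + t * self.direction[0],
            self.anchor.y + t * self.direction[1],
        )

    def project(self, point: PlanarPoint) -> float:
        """Signed parameter of ``point`` along the line direction."""
        return (point.x - self.anchor.x) * self.direction[0] + (
            point.y - self.anchor.y
        ) * self.direction[1]

    def signed_offset(self, point: PlanarPoint) -> float:
        """Signed perpendicular distance (cross product with direction)."""
        return self.direction[0] * (point.y - self.anchor.y) - self.direction[
            1
        ] * (point.x - self.anchor.x)


@dataclass
class ContourPolyline:
    """An ordered boundary polyline; ``vertices`` is an (N, 2) xy array."""

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.closed and len(self.vertices) < 3:
            raise ValueError("closed contour needs at least 3 vertices")

    def length(self) -> float:
        ring = self.vertices
        if self.closed:
            ring = np.vstack([ring, ring[:1]])
        return float(np.sum(np.hypot(*np.diff(ring, axis=0).T)))

    def enclosed_area(self) -> float:
        """Shoelace area of the closed polyline."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)

    def as_linestring(self) -> LineString:
        ring = self.vertices
        if self.closed:
            ring = np.vstack([ring, ring[:1]])
        return LineString(ring)


def _foreground_coords(raster: np.ndarray) -> np.ndarray:
    """(N, 2) array of xy pixel-center coordinates of the foreground."""
    rows, cols = np.nonzero(np.asarray(raster))
    return np.column_stack([cols, rows]).astype(float)


def _canonical_direction(dx: float, dy: float) -> tuple[float, float]:
    """Fix the sign so dy > 0, or dx > 0 when dy == 0."""
    if dy < 0 or (dy == 0 and dx < 0):
        dx, dy = -dx, -dy
    return dx, dy


def region_centroid(binary_raster: np.ndarray) -> PlanarPoint:
    """Arithmetic mean of foreground pixel centers."""
    coords = _foreground_coords(binary_raster)
    if len(coords) == 0:
        raise EmptyRegionError("centroid of empty region")
    cx, cy = coords.mean(axis=0)
    return PlanarPoint(float(cx), float(cy))


def largest_component(binary_raster: np.ndarray) -> np.ndarray:
    """Boolean mask of the largest 8-connected foreground component."""
    raster = np.asarray(binary_raster).astype(bool)
    labels, n = ndimage.label(raster, structure=_EIGHT)
    if n == 0:
        raise EmptyRegionError("no foreground component")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))

def extract_outer_contour(binary_raster: np.ndarray) -> ContourPolyline:
    """Sub-pixel outer boundary of the largest 8-connected component.

    Marching-squares tracing at the 0.5 level of the lightly smoothed
    (σ = 1 px) indicator of the zero-padded component: the smoothing keeps
    the 0.5-level set on the true straight-edge boundary while removing
    the staircase bias that binary marching squares puts on curved-edge
    lengths.  The longest closed ring wins.
    """
    component = largest_component(binary_raster)
    padded = np.pad(component, 3).astype(float)
    smoothed = ndimage.gaussian_filter(padded, sigma=1.0)
    rings = measure.find_contours(smoothed, 0.5)
    if not rings:  # a structure too thin to survive smoothing
        rings = measure.find_contours(padded, 0.5)
    if not rings:
        raise EmptyRegionError("no contour found")
    ring = max(rings, key=len)
    # (row, col) in padded frame -> (x, y) in image frame.
    xy = np.column_stack([ring[:, 1] - 3.0, ring[:, 0] - 3.0])
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    # Drop repeated consecutive vertices.
    keep = np.ones(len(xy), dtype=bool)
    keep[1:] = np.any(np.abs(np.diff(xy, axis=0)) > 1e-12, axis=1)
    return ContourPolyline(xy[keep], closed=True)


def principal_axis_line(binary_raster: np.ndarray) -> OrientedLine:
    """Orthogonal-least-squares (principal) long axis of a region.

    The line is anchored at the region centroid and directed along the
    leading eigenvector of the pixel-coordinate covariance.  Orthogonal
    least squares rather than a regression of y on x: the ventricular
    septum may be near-vertical, where ordinary regression is ill-posed,
    and the principal axis is rotationally invariant.
    """
    coords = _foreground_coords(binary_raster)
    if len(coords) == 0:
        raise EmptyRegionError("principal axis of empty region")
    centered = coords - coords.mean(axis=0)
    if len(np.unique(coords, axis=0)) < 2:
        raise DegenerateFitError("fewer than 2 distinct pixels")
    cov = centered.T @ centered / len(centered)
    eigvals, eigvecs = np.linalg.eigh(cov)
    # eigh returns ascending eigenvalues; the long axis is the last column.
    gap = eigvals[1] - eigvals[0]
    if gap <= 1e-6 * max(eigvals[1], 1.0):
        raise DegenerateFitError("isotropic region: long axis undefined")
    dx, dy = _canonical_direction(float(eigvecs[0, 1]), float(eigvecs[1, 1]))
    cx, cy = coords.mean(axis=0)
    return OrientedLine(PlanarPoint(float(cx), float(cy)), (dx, dy))


def convex_hollow_centroid(thorax_raster: np.ndarray) -> PlanarPoint:
    """Centroid of the spine hollow: fill the thorax's convex envelope,
    subtract the thorax, keep the largest residual component.

    The largest-component rule discards the thin slivers that rasterized
    convexity leaves along a curved boundary; a genuine spine hollow
    dominates them by orders of magnitude.
    """
    raster = np.asarray(thorax_raster).astype(bool)
    if not raster.any():
        raise EmptyRegionError("empty thorax raster")
    hull = morphology.convex_hull_image(raster)
    residual = hull & ~raster
    if not residual.any():
        raise NoHollowError("no hollow: thorax is convex")
    labels, n = ndimage.label(residual, structure=_EIGHT)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(np.argmax(counts))
    component = labels == best
    # Rasterized convexity leaves 1-px slivers along curved boundaries; a
    # genuine spine hollow has interior thickness.
    if float(ndimage.distance_transform_edt(component).max()) < 1.5:
        raise NoHollowError("residual too thin to be a spine hollow")
    return region_centroid(component)


def _halfplane_imbalance(
    rel_coords: np.ndarray, theta_deg: np.ndarray | float
) -> np.ndarray | float:
    """Signed (left - right) foreground fraction for line tilt(s) theta.

    ``theta_deg`` is the tilt of the line direction from image-vertical;
    direction u = (sin θ, -cos θ).  A pixel's side is the sign of
    cross(u, p - anchor); pixels exactly on the line count for neither.
    """
    theta = np.deg2rad(np.atleast_1d(np.asarray(theta_deg, dtype=float)))
    ux, uy = np.sin(theta), -np.cos(theta)
    # cross = ux * rel_y - uy * rel_x ; broadcast over angles.  Pixels on
    # the line (within float dust) count for neither side, so a line that
    # aligns exactly with a pixel row or column stays balanced.
    cross = np.outer(ux, rel_coords[:, 1]) - np.outer(uy, rel_coords[:, 0])
    n = rel_coords.shape[0]
    imbalance = (np.sum(cross > 1e-7, axis=1) - np.sum(cross < -1e-7, axis=1)) / n
    return imbalance if np.ndim(theta_deg) else float(imbalance[0])


def area_bisecting_line(
    whole_thorax_raster: np.ndarray,
    anchor: PlanarPoint,
    success_tolerance: float = 0.005,
    failure_tolerance: float = 0.05,
) -> OrientedLine:
    """Line through ``anchor`` splitting the foreground area in half.

    A 1° coarse sweep of the tilt from image-vertical locates a sign change
    of the signed half-plane imbalance, which bisection then refines; the
    candidate minimizing |imbalance| wins, ties broken by the smallest tilt
    from vertical.  Success requires the imbalance to be at most
    ``success_tolerance`` of the total area; if no orientation gets within
    ``failure_tolerance`` a :class:`BisectFailureError` is raised.
    """
    coords = _foreground_coords(whole_thorax_raster)
    if len(coords) == 0:
        raise EmptyRegionError("empty whole-thorax raster")
    if not (np.isfinite(anchor.x) and np.isfinite(anchor.y)):
        raise ValueError("anchor must be finite")
    rel = coords - np.array([anchor.x, anchor.y])

    thetas = np.arange(-90.0, 90.0, 1.0)
    imb = np.asarray(_halfplane_imbalance(rel, thetas))

    candidates: list[tuple[float, float]] = []  # (|imbalance|, theta)
    # Refine every sign change by bisection; f(θ+180) = -f(θ) closes the wrap.
    wrapped = np.append(imb, -imb[0])
    for i in range(len(thetas)):
        lo, hi = thetas[i], thetas[i] + 1.0
        f_lo, f_hi = wrapped[i], wrapped[i + 1]
        if f_lo == 0.0:
            candidates.append((0.0, lo))
            continue
        if f_lo * f_hi > 0:
            continue
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            f_mid = _halfplane_imbalance(rel, mid)
            if f_mid == 0.0 or (hi - lo) < 1e-9:
                lo = hi = mid
                break
            if f_lo * f_mid < 0:
                hi = mid
            else:
                lo, f_lo = mid, f_mid
        mid = 0.5 * (lo + hi)
        candidates.append((abs(float(_halfplane_imbalance(rel, mid))), mid))
    # Always keep the best coarse angle as a fallback candidate.
    best_coarse = int(np.argmin(np.abs(imb)))
    candidates.append((abs(float(imb[best_coarse])), float(thetas[best_coarse])))

    # Smallest imbalance first; ties -> smallest tilt from vertical.
    candidates.sort(key=lambda c: (c[0], abs(c[1])))
    best_err, best_theta = candidates[0]
    if best_err > failure_tolerance:
        raise BisectFailureError(
            f"half-plane imbalance {best_err:.3f} exceeds {failure_tolerance}"
        )
    if best_err > success_tolerance:
        raise BisectFailureError(
            f"half-plane imbalance {best_err:.4f} exceeds "
            f"tolerance {success_tolerance}"
        )
    theta = np.deg2rad(best_theta)
    dx, dy = _canonical_direction(float(np.sin(theta)), float(-np.cos(theta)))
    return OrientedLine(anchor, (dx, dy))


def line_contour_intersections(
    line: OrientedLine,
    contour: ContourPolyline,
    dedup_radius: float = 0.5,
) -> list[PlanarPoint]:
    """All intersections of the infinite line with the contour's segments.

    Points closer than ``dedup_radius`` are merged, and the result is
    ordered along the line direction.
    """
    verts = contour.vertices
    span = float(np.max(np.ptp(verts, axis=0))) + np.hypot(
        line.anchor.x - verts[:, 0].mean(), line.anchor.y - verts[:, 1].mean()
    )
    reach = 4.0 * (span + 1.0)
    p0 = line.point_at(-reach)
    p1 = line.point_at(reach)
    segment = LineString([p0, p1])
    hit = segment.intersection(contour.as_linestring())
    points: list[tuple[float, float]] = []
    if hit.is_empty:
        return []
    geoms = getattr(hit, "geoms", [hit])
    for geom in geoms:
        if isinstance(geom, ShapelyPoint):
            points.append((geom.x, geom.y))
        else:  # collinear overlap: keep its endpoints
            coords = list(geom.coords)
            points.append(coords[0])
            points.append(coords[-1])
    pts = [PlanarPoint(float(x), float(y)) for x, y in points]
    pts.sort(key=line.project)
    deduped: list[PlanarPoint] = []
    for p in pts:
        if deduped and np.hypot(p.x - deduped[-1].x, p.y - deduped[-1].y) < dedup_radius:
            continue
        deduped.append(p)
    return deduped


def line_line_intersection(l1: OrientedLine, l2: OrientedLine) -> PlanarPoint:
    """Unique intersection point of two non-parallel lines."""
    d1x, d1y = l1.direction
    d2x, d2y = l2.direction
    cross = d1x * d2y - d1y * d2x
    if abs(cross) <= 1e-9:
        raise ParallelLinesError("lines are parallel")
    ax = l2.anchor.x - l1.anchor.x
    ay = l2.anchor.y - l1.anchor.y
    t = (ax * d2y - ay * d2x) / cross
    return l1.point_at(t)


def angle_at_vertex(
    vertex: PlanarPoint, p1: PlanarPoint, p2: PlanarPoint
) -> float:
    """Angle (degrees, in [0, 180]) at ``vertex`` between rays to p1 and p2."""
    v1 = np.array([p1.x - vertex.x, p1.y - vertex.y])
    v2 = np.array([p2.x - vertex.x, p2.y - vertex.y])
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateAngleError("zero-length arm at vertex")
    cosine = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))
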