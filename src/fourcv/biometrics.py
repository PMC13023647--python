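"""Four-chamber-view biometric parameters from a structure mask set.

The measurement chain mirrors how a sonographer works on the 4CV:

1. The spine is located as the centroid of the hollow left in the thorax
   mask (convex envelope minus thorax), point S.
2. The anteroposterior reference is the line through S that bisects the
   whole-thorax area; its far contour intersection is point R.
3. The ventricular septum's principal axis gives the septal line; its
   intersection with line RS is point I, and its thoracic-contour crossing
   nearer the septum is point V (apex substitute).
4. The cardiac axis is the angle ∠RIV; the apex side (sign of V against
   line RS) infers the fetal presentation; the descending aorta's side
   against RS relative to V gives situs (solitus/inversus).
5. The cardiac position, point P, is the septal-line crossing of the heart
   contour opposite the apex, expressed in a thorax-centered, tilt-corrected
   frame normalized by the thoracic chords (divided into eight parts), with
   the lateral coordinate folded onto the apex side.

Normal guideline ranges (CTAR < 35%, axis 45 ± 20°, position box
0 ≤ gx ≤ 2, −1 ≤ gy ≤ 1) are applied by :mod:`fourcv.screening`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import geometry as geo
from .exceptions import (
    DegenerateAngleError,
    DegenerateChordError,
    EmptyRegionError,
    IndeterminateSideError,
    NoIntersectionError,
)
from .geometry import ContourPolyline, OrientedLine, PlanarPoint
from .mask_io import StructureMaskSet

#: Half-width (px) of the "on the line" band for side classifications.
ON_LINE_TOLERANCE = 0.5

#: Degrees of slack in the angle-identity situs test (∠VSA vs ∠RSV + ∠RSA).
LATERALITY_ANGLE_EPSILON = 1.0

#: Number of equal parts the thoracic chords are divided into for point P.
DEFAULT_POINTP_DIVISIONS = 8


@dataclass
class AnatomicalLandmarks:
    """The constructed points and axes for one image.

    ``A`` is ``None`` when the descending aorta is absent (laterality is
    then indeterminate).  ``theta`` is the signed tilt (degrees) of line RS
    from image-vertical; ``B1/B2`` and ``A1/A2`` are the thoracic-contour
    crossings of the lateral (x′) and anteroposterior (y′) axes through the
    whole-thorax centroid O′.
    """

    S: PlanarPoint
    R: PlanarPoint
    I: PlanarPoint
    V: PlanarPoint
    A: PlanarPoint | None
    O_prime: PlanarPoint
    theta: float
    B1: PlanarPoint
    B2: PlanarPoint
    A1: PlanarPoint
    A2: PlanarPoint
    rs_line: OrientedLine
    septal_line: OrientedLine
    thorax_contour: ContourPolyline

    def to_dict(self) -> dict[str, Any]:
        def pt(p: PlanarPoint | None) -> list[float] | None:
            return None if p is None else [p.x, p.y]

        return {
            "S": pt(self.S),
            "R": pt(self.R),
            "I": pt(self.I),
            "V": pt(self.V),
            "A": pt(self.A),
            "O_prime": pt(self.O_prime),
            "theta_deg": self.theta,
            "B1": pt(self.B1),
            "B2": pt(self.B2),
            "A1": pt(self.A1),
            "A2": pt(self.A2),
        }


@dataclass
class BiometricRecord:
    """All screening parameters measured on one image."""

    ctar: float
    cardiac_axis: float
    apex_side: str  # left_of_RS | right_of_RS
    inferred_presentation: str  # cephalic | breech
    laterality: str  # solitus | inversus | indeterminate
    point_p: tuple[float, float] | None
    source_id: str = ""
    landmarks: AnatomicalLandmarks | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "ctar": self.ctar,
            "cardiac_axis_deg": self.cardiac_axis,
            "apex_side": self.apex_side,
            "inferred_presentation": self.inferred_presentation,
            "laterality": self.laterality,
            "point_p": None
            if self.point_p is None
            else {"gx": self.point_p[0], "gy": self.point_p[1]},
            "landmarks": None if self.landmarks is None else self.landmarks.to_dict(),
            "source_id": self.source_id,
        }


def compute_ctar(mask_set: StructureMaskSet) -> float:
    """Cardiothoracic area ratio: heart pixels over whole-thorax pixels.

    Pixel counting on the contour-based masks, not an elliptical
    approximation, so the ratio reflects the segmented shapes directly.
    """
    n_thorax = int(mask_set["whole_thorax"].sum())
    if n_thorax == 0:
        raise EmptyRegionError("empty whole_thorax")
    return int(mask_set["heart"].sum()) / n_thorax


def _signed_tilt_from_vertical(direction: tuple[float, float]) -> float:
    """Signed angle (degrees) from image-vertical 'up' to ``direction``."""
    dx, dy = direction
    return float(np.degrees(np.arctan2(dx, -dy)))


def _chord_through(
    point: PlanarPoint,
    direction: tuple[float, float],
    contour: ContourPolyline,
) -> tuple[PlanarPoint, PlanarPoint]:
    line = OrientedLine(point, direction)
    hits = geo.line_contour_intersections(line, contour)
    if len(hits) < 2:
        raise DegenerateChordError("axis does not span the thoracic contour")
    return hits[0], hits[-1]


def locate_landmarks(mask_set: StructureMaskSet) -> AnatomicalLandmarks:
    """Construct all landmarks for one image.

    Geometry errors (no spine hollow, bisect failure, degenerate septum
    fit) propagate; a missing descending aorta yields ``A = None`` and an
    indeterminate laterality downstream.
    """
    S = geo.convex_hollow_centroid(mask_set["thorax"])
    rs_line = geo.area_bisecting_line(mask_set["whole_thorax"], S)
    contour = geo.extract_outer_contour(mask_set["whole_thorax"])

    rs_hits = geo.line_contour_intersections(rs_line, contour)
    if not rs_hits:
        raise NoIntersectionError("bisecting line misses the thoracic contour")
    R = max(rs_hits, key=lambda p: np.hypot(p.x - S.x, p.y - S.y))
    # Orient the RS direction from S toward R (posterior -> anterior).
    u = rs_line.direction
    if (R.x - S.x) * u[0] + (R.y - S.y) * u[1] < 0:
        u = (-u[0], -u[1])
    rs_line = OrientedLine(S, u)

    septal_line = geo.principal_axis_line(mask_set["ventricular_septum"])
    I = geo.line_line_intersection(rs_line, septal_line)

    septum_centroid = geo.region_centroid(mask_set["ventricular_septum"])
    sept_hits = geo.line_contour_intersections(septal_line, contour)
    if not sept_hits:
        raise NoIntersectionError("septal line misses the thoracic contour")
    V = min(
        sept_hits,
        key=lambda p: np.hypot(p.x - septum_centroid.x, p.y - septum_centroid.y),
    )

    A: PlanarPoint | None = None
    if mask_set["descending_aorta"].any():
        aorta_centroid = geo.region_centroid(mask_set["descending_aorta"])
        da = np.array([aorta_centroid.x - S.x, aorta_centroid.y - S.y])
        norm = float(np.linalg.norm(da))
        if norm > 1e-9:
            ray = OrientedLine(S, (da[0] / norm, da[1] / norm))
            hits = geo.line_contour_intersections(ray, contour)
            # Beyond the aorta: smallest parameter past the aorta centroid.
            beyond = [p for p in hits if ray.project(p) > norm]
            if beyond:
                A = beyond[0]
            elif hits:
                A = hits[-1]

    O_prime = geo.region_centroid(mask_set["whole_thorax"])
    theta = _signed_tilt_from_vertical(rs_line.direction)
    u_ap = rs_line.direction  # anteroposterior (toward R)
    u_lat = (-u_ap[1], u_ap[0])  # perpendicular; sign irrelevant for chords
    B1, B2 = _chord_through(O_prime, u_lat, contour)
    A1, A2 = _chord_through(O_prime, u_ap, contour)

    return AnatomicalLandmarks(
        S=S, R=R, I=I, V=V, A=A, O_prime=O_prime, theta=theta,
        B1=B1, B2=B2, A1=A1, A2=A2,
        rs_line=rs_line, septal_line=septal_line, thorax_contour=contour,
    )


def compute_cardiac_axis(landmarks: AnatomicalLandmarks) -> float:
    """Cardiac axis ∠RIV in degrees, apex side notwithstanding."""
    return geo.angle_at_vertex(landmarks.I, landmarks.R, landmarks.V)


def classify_apex_presentation(
    landmarks: AnatomicalLandmarks,
) -> tuple[str, str]:
    """Apex side against line RS, and the fetal presentation it implies.

    The sign of cross(R−S, V−S) decides the side: negative (image-left of
    the S→R direction) means the apex sits in the left thoracic cavity,
    the normal cephalic configuration; positive means breech.
    """
    S, R, V = landmarks.S, landmarks.R, landmarks.V
    if abs(landmarks.rs_line.signed_offset(V)) <= ON_LINE_TOLERANCE:
        raise IndeterminateSideError("V lies on line RS")
    cross = (R.x - S.x) * (V.y - S.y) - (R.y - S.y) * (V.x - S.x)
    if cross < 0:
        return "left_of_RS", "cephalic"
    return "right_of_RS", "breech"


def laterality_angles(landmarks: AnatomicalLandmarks) -> tuple[float, float]:
    """(∠VSA, ∠RSV + ∠RSA) — the angle identity behind the situs rule."""
    if landmarks.A is None:
        raise DegenerateAngleError("no aorta point A")
    S, R, V, A = landmarks.S, landmarks.R, landmarks.V, landmarks.A
    vsa = geo.angle_at_vertex(S, V, A)
    rsv = geo.angle_at_vertex(S, R, V)
    rsa = geo.angle_at_vertex(S, R, A)
    return vsa, rsv + rsa


def classify_laterality(landmarks: AnatomicalLandmarks) -> str:
    """Situs solitus vs inversus from the heart/aorta side relation.

    Normal anatomy has apex (V) and descending aorta (A) in the same
    thoracic cavity: V then lies on the arc between A and R and
    ∠VSA < ∠RSV + ∠RSA; when they occupy opposite cavities (e.g. a
    right-sided aortic arch) the sum identity ∠VSA = ∠RSV + ∠RSA holds.
    The authoritative test is the side of each point against line RS; the
    angle identity is exposed via :func:`laterality_angles` and asserted
    as a consistency property in the test suite.
    """
    if landmarks.A is None:
        return "indeterminate"
    off_v = landmarks.rs_line.signed_offset(landmarks.V)
    off_a = landmarks.rs_line.signed_offset(landmarks.A)
    if abs(off_v) <= ON_LINE_TOLERANCE or abs(off_a) <= ON_LINE_TOLERANCE:
        return "indeterminate"
    return "solitus" if off_v * off_a > 0 else "inversus"


def compute_point_p(
    mask_set: StructureMaskSet,
    landmarks: AnatomicalLandmarks,
    divisions: int = DEFAULT_POINTP_DIVISIONS,
) -> tuple[float, float]:
    """Cardiac position (gx, gy) in thorax-relative units.

    Point P is the septal-line crossing of the cardiac circumference on the
    side opposite the septum/apex (the base-ward crossing).  It is then
    mapped into the thorax frame: translate by −O′, rotate by −θ so the
    anteroposterior axis is vertical, flip the vertical sign (anterior
    positive), and scale by the chord-derived unit lengths
    dx = |B1B2|/divisions, dy = |A1A2|/divisions.  The lateral coordinate
    is folded, gx = |px′|, so the apex side is non-negative and mirrored
    images agree; gy keeps its sign.
    """
    heart_contour = geo.extract_outer_contour(mask_set["heart"])
    line_iv = landmarks.septal_line
    hits = geo.line_contour_intersections(line_iv, heart_contour)
    if not hits:
        raise NoIntersectionError("septal line misses the cardiac contour")
    t_i = line_iv.project(landmarks.I)
    t_v = line_iv.project(landmarks.V)
    side_v = np.sign(t_v - t_i)
    opposite = [p for p in hits if np.sign(line_iv.project(p) - t_i) == -side_v]
    if opposite:
        # Base-ward crossing: nearest to I on the far side from V.
        P = min(opposite, key=lambda p: abs(line_iv.project(p) - t_i))
    else:
        # Heart entirely on V's side of I: farthest crossing from V.
        P = max(hits, key=lambda p: abs(line_iv.project(p) - t_v))

    d_x = float(np.hypot(landmarks.B1.x - landmarks.B2.x,
                         landmarks.B1.y - landmarks.B2.y)) / divisions
    d_y = float(np.hypot(landmarks.A1.x - landmarks.A2.x,
                         landmarks.A1.y - landmarks.A2.y)) / divisions
    if d_x <= 1e-9 or d_y <= 1e-9:
        raise DegenerateChordError("degenerate thoracic chord")

    rel = np.array([P.x - landmarks.O_prime.x, P.y - landmarks.O_prime.y])
    u_ap = np.array(landmarks.rs_line.direction)  # toward R (anterior)
    u_lat = np.array([-u_ap[1], u_ap[0]])  # sign immaterial: gx is folded
    gx = abs(float(rel @ u_lat)) / d_x
    gy = float(rel @ u_ap) / d_y
    return gx, gy


def compute_biometrics(
    mask_set: StructureMaskSet,
    pointp_divisions: int = DEFAULT_POINTP_DIVISIONS,
) -> BiometricRecord:
    """Full measurement of one image: CTAR, axis, orientation, situs, P."""
    landmarks = locate_landmarks(mask_set)
    ctar = compute_ctar(mask_set)
    axis = compute_cardiac_axis(landmarks)
    apex_side, presentation = classify_apex_presentation(landmarks)
    laterality = classify_laterality(landmarks)
    point_p = compute_point_p(mask_set, landmarks, divisions=pointp_divisions)
    return BiometricRecord(
        ctar=ctar,
        cardiac_axis=axis,
        apex_side=apex_side,
        inferred_presentation=presentation,
        laterality=laterality,
        point_p=point_p,
        source_id=mask_set.source_id,
        landmarks=landmarks,
    )
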