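"""Guideline classification and image → video → patient screening calls.

Each biometric parameter is compared against its guideline normal range
(CTAR < 35%, cardiac axis 45 ± 20°, cardiac-position box 0 ≤ gx ≤ 2,
−1 ≤ gy ≤ 1).  Two images per video are averaged before classification;
patients whose video yielded no extractable 4CV are screened positive.
The ordinal screening score — the count of abnormal parameters among a
chosen subset — feeds the ROC analysis in :mod:`fourcv.evaluation`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .biometrics import BiometricRecord
from .exceptions import AggregationError

#: Parameters that count toward the ordinal screening score by default.
#: Orientation mismatch and laterality are auxiliary flags: they still make
#: the overall call positive, but are not part of the score used for ROC.
DEFAULT_INCLUDED = ("ctar", "axis", "pointp")

_FLAG_BY_PARAMETER = {
    "ctar": "ctar_abnormal",
    "axis": "axis_abnormal",
    "pointp": "pointp_abnormal",
}


@dataclass(frozen=True)
class NormalRanges:
    """Guideline normal ranges for the three screening parameters."""

    ctar_max: float = 0.35
    axis_center: float = 45.0
    axis_halfwidth: float = 20.0
    pointp_box: tuple[float, float, float, float] = (0.0, 2.0, -1.0, 1.0)
    # (gx_min, gx_max, gy_min, gy_max)

    def __post_init__(self) -> None:
        lo = self.axis_center - self.axis_halfwidth
        hi = self.axis_center + self.axis_halfwidth
        if not (0.0 <= lo and hi <= 180.0):
            raise ValueError("axis interval must lie within [0, 180]")
        gx_min, gx_max, gy_min, gy_max = self.pointp_box
        if gx_min > gx_max or gy_min > gy_max:
            raise ValueError("point-P box bounds out of order")


@dataclass
class ScreeningResult:
    """Per-parameter abnormality flags and the aggregated call."""

    flags: dict[str, bool]
    score: int
    overall: str  # positive | negative
    level: str  # image | video | patient
    non_extractable: bool = False
    notes: list[str] = field(default_factory=list)


def _overall(flags: dict[str, bool], non_extractable: bool = False) -> str:
    return "positive" if (non_extractable or any(flags.values())) else "negative"


def classify_parameters(
    record: BiometricRecord,
    ranges: NormalRanges = NormalRanges(),
    declared_presentation: str = "unknown",
) -> ScreeningResult:
    """Classify one image's parameters against the normal ranges.

    CTAR exactly at the threshold counts as abnormal ("< 35%" is the
    normal range, so the abnormal boundary is closed).  An indeterminate
    laterality does not flag — it is noted instead — and the orientation
    flag fires only when the examiner declared a presentation and the
    image disagrees with it.
    """
    flags = {
        "ctar_abnormal": record.ctar >= ranges.ctar_max,
        "axis_abnormal": abs(record.cardiac_axis - ranges.axis_center)
        > ranges.axis_halfwidth,
        "pointp_abnormal": False,
        "orientation_mismatch": False,
        "laterality_abnormal": record.laterality == "inversus",
    }
    notes: list[str] = []
    if record.point_p is None:
        notes.append("point P unavailable; flag left false")
    else:
        gx, gy = record.point_p
        gx_min, gx_max, gy_min, gy_max = ranges.pointp_box
        flags["pointp_abnormal"] = not (
            gx_min <= gx <= gx_max and gy_min <= gy <= gy_max
        )
    if declared_presentation in ("cephalic", "breech"):
        flags["orientation_mismatch"] = (
            record.inferred_presentation != declared_presentation
        )
    if record.laterality == "indeterminate":
        notes.append("laterality indeterminate; flag left false")
    score = sum(flags[_FLAG_BY_PARAMETER[p]] for p in DEFAULT_INCLUDED)
    return ScreeningResult(
        flags=flags,
        score=score,
        overall=_overall(flags),
        level="image",
        notes=notes,
    )


def _majority(values: Sequence[str], tie_value: str) -> tuple[str, bool]:
    """Majority vote; returns (winner, tied)."""
    counts = Counter(values)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return tie_value, True
    return top[0][0], False


def aggregate_video(
    records: Sequence[BiometricRecord],
    ranges: NormalRanges = NormalRanges(),
    declared_presentation: str = "unknown",
) -> tuple[BiometricRecord, ScreeningResult]:
    """Average image records into one per-video record and classify it.

    Continuous parameters (CTAR, axis, point P) are averaged; categorical
    outcomes go by majority with ties treated as abnormal — screening
    favors sensitivity, since a positive call only triggers a secondary
    examination.
    """
    if not records:
        raise AggregationError("no image records to aggregate")
    n = len(records)
    ctar = sum(r.ctar for r in records) / n
    axis = sum(r.cardiac_axis for r in records) / n
    ps = [r.point_p for r in records if r.point_p is not None]
    point_p = (
        (sum(p[0] for p in ps) / len(ps), sum(p[1] for p in ps) / len(ps))
        if ps
        else None
    )
    apex_side, _ = _majority([r.apex_side for r in records], "right_of_RS")
    presentation, pres_tied = _majority(
        [r.inferred_presentation for r in records],
        "breech" if declared_presentation == "cephalic" else "cephalic",
    )
    known_lat = [r.laterality for r in records if r.laterality != "indeterminate"]
    if known_lat:
        laterality, lat_tied = _majority(known_lat, "inversus")
    else:
        laterality, lat_tied = "indeterminate", False

    aggregate = BiometricRecord(
        ctar=ctar,
        cardiac_axis=axis,
        apex_side=apex_side,
        inferred_presentation=presentation,
        laterality=laterality,
        point_p=point_p,
        source_id=records[0].source_id,
        landmarks=None,
    )
    result = classify_parameters(aggregate, ranges, declared_presentation)
    result.level = "video"
    if pres_tied and declared_presentation in ("cephalic", "breech"):
        result.flags["orientation_mismatch"] = True
        result.notes.append("presentation tie treated as abnormal")
    if lat_tied:
        result.flags["laterality_abnormal"] = True
        result.notes.append("laterality tie treated as abnormal")
    result.score = sum(
        result.flags[_FLAG_BY_PARAMETER[p]] for p in DEFAULT_INCLUDED
    )
    result.overall = _overall(result.flags)
    return aggregate, result


def screen_patient(
    video_result: ScreeningResult | None,
    extractable: bool,
) -> ScreeningResult:
    """Patient-level call: non-extractable videos are screened positive.

    A video from which no 4CV could be extracted already failed the most
    basic morphological check, so the patient is referred regardless of
    parameter values.
    """
    if not extractable:
        return ScreeningResult(
            flags={flag: False for flag in _FLAG_BY_PARAMETER.values()}
            | {"orientation_mismatch": False, "laterality_abnormal": False},
            score=len(DEFAULT_INCLUDED),
            overall="positive",
            level="patient",
            non_extractable=True,
            notes=["no extractable 4CV; screened positive"],
        )
    if video_result is None:
        raise AggregationError("extractable patient without a video result")
    return ScreeningResult(
        flags=dict(video_result.flags),
        score=video_result.score,
        overall=video_result.overall,
        level="patient",
        non_extractable=False,
        notes=list(video_result.notes),
    )


def screening_score(
    result: ScreeningResult,
    included: Sequence[str] = DEFAULT_INCLUDED,
) -> int:
    """Ordinal score: abnormal count among ``included`` parameters.

    Non-extractable patients receive the maximum score, ``len(included)``,
    so they rank above every parameter-based positive in the ROC sweep.
    """
    if not included:
        raise ValueError("included parameter set must be non-empty")
    unknown = set(included) - set(_FLAG_BY_PARAMETER)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    if result.non_extractable:
        return len(included)
    return sum(result.flags[_FLAG_BY_PARAMETER[p]] for p in included)


# ---------------------------------------------------------------------------
# Worked example: per-patient sensitivity over a CHD cohort from counts
# ---------------------------------------------------------------------------

def _synthetic_record(abnormal: bool, source_id: str) -> BiometricRecord:
    """A minimal image record, clearly inside or outside the CTAR range."""
    return BiometricRecord(
        ctar=0.45 if abnormal else 0.27,
        cardiac_axis=44.0,
        apex_side="left_of_RS",
        inferred_presentation="cephalic",
        laterality="solitus",
        point_p=(0.6, -0.3),
        source_id=source_id,
    )


def cohort_sensitivity_from_counts(
    n_patients: int,
    n_non_extractable: int,
    n_abnormal_images: int,
    n_flagged_patients: int,
    images_per_video: int = 2,
    ranges: NormalRanges = NormalRanges(),
) -> float:
    """Per-patient sensitivity of an all-affected cohort built from counts.

    Constructs an affected cohort in which ``n_non_extractable`` patients
    have no extractable 4CV, and the remaining patients carry
    ``images_per_video`` image records of which ``n_abnormal_images`` in
    total are parameter-abnormal, concentrated so that exactly
    ``n_flagged_patients`` patients hold at least one abnormal image.  The
    full image → video → patient machinery then produces the calls; the
    return value is (positive patients) / ``n_patients``.
    """
    n_extractable = n_patients - n_non_extractable
    if n_extractable < n_flagged_patients:
        raise ValueError("more flagged patients than extractable patients")
    if not (
        n_flagged_patients
        <= n_abnormal_images
        <= n_flagged_patients * images_per_video
    ):
        raise ValueError(
            "abnormal image count incompatible with flagged patient count"
        )
    # Distribute abnormal images: fill flagged patients to capacity, then
    # strip one from the tail until the total matches.
    per_patient = [0] * n_extractable
    remaining = n_abnormal_images
    for i in range(n_flagged_patients):
        take = min(images_per_video, remaining - (n_flagged_patients - i - 1))
        per_patient[i] = take
        remaining -= take

    positives = n_non_extractable  # non-extractable rule
    for i in range(n_extractable):
        records = [
            _synthetic_record(j < per_patient[i], f"patient{i:02d}_img{j}")
            for j in range(images_per_video)
        ]
        _, video_result = aggregate_video(records, ranges)
        patient_result = screen_patient(video_result, extractable=True)
        if patient_result.overall == "positive":
            positives += 1
    return positives / n_patients
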