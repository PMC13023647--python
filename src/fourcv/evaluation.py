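"""Segmentation and screening metrics: Dice, MAE, ROC/AUC, Youden point.

The Dice coefficient is the standard 2·TP / (2·TP + FP + FN) pixel-overlap
form.  ROC curves sweep the distinct values of the ordinal screening score;
the AUC equals the Mann–Whitney pair statistic (ties counted one half),
which the test suite asserts against exhaustive pair counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn import metrics as _skm

from .exceptions import DegenerateLabelsError, PairingError


@dataclass
class ConfusionCounts:
    """Pixelwise (or case-wise) confusion counts."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion(pred_raster: np.ndarray, truth_raster: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred_raster).astype(bool)
    truth = np.asarray(truth_raster).astype(bool)
    if pred.shape != truth.shape:
        raise PairingError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    return ConfusionCounts(tp, fp, fn, tn)


def dice(pred_raster: np.ndarray, truth_raster: np.ndarray) -> float:
    """Dice coefficient 2·TP / (2·TP + FP + FN); both-empty counts as 1.0.

    The perfect-agreement convention for two empty masks keeps legitimately
    absent structures from poisoning per-structure means.
    """
    c = confusion(pred_raster, truth_raster)
    denominator = 2 * c.TP + c.FP + c.FN
    if denominator == 0:
        return 1.0
    return 2 * c.TP / denominator


@dataclass
class MeanDiceResult:
    """Mean Dice over included pairs, with the exclusions reported."""

    value: float
    n_used: int
    n_excluded: int
    excluded_indices: list[int] = field(default_factory=list)


def mean_dice(
    pred_sets: Sequence,
    truth_sets: Sequence,
    structure: str,
) -> MeanDiceResult:
    """Mean per-image Dice for one structure over paired mask sets.

    Pairs where the prediction is empty but the reference is not (the
    structure could not be segmented) are excluded from the mean and
    reported, never silently dropped.
    """
    if len(pred_sets) != len(truth_sets):
        raise PairingError("pred/truth set counts differ")
    if len(pred_sets) == 0:
        raise PairingError("empty pairing")
    values: list[float] = []
    excluded: list[int] = []
    for i, (pred, truth) in enumerate(zip(pred_sets, truth_sets)):
        p, t = pred[structure], truth[structure]
        if not p.any() and t.any():
            excluded.append(i)
            continue
        values.append(dice(p, t))
    if not values:
        raise PairingError("all pairs excluded")
    return MeanDiceResult(
        value=float(np.mean(values)),
        n_used=len(values),
        n_excluded=len(excluded),
        excluded_indices=excluded,
    )


def mae(estimates: Sequence[float], truths: Sequence[float]) -> float:
    """Mean absolute error in the parameter's native units."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise PairingError("estimate/truth length mismatch")
    return float(np.mean(np.abs(est - tru)))


@dataclass
class RocCurve:
    """Operating points (FPR, TPR) with thresholds, and the trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve over the distinct score values; AUC by the trapezoid rule."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise PairingError("score/label length mismatch")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("need at least one positive and one negative")
    fpr, tpr, thresholds = _skm.roc_curve(y, s, drop_intermediate=False)
    return RocCurve(
        fpr=fpr, tpr=tpr, thresholds=thresholds, auc=float(_skm.auc(fpr, tpr))
    )


def youden_point(curve: RocCurve) -> tuple[float, float, float]:
    """(FPR, TPR, threshold) maximizing TPR − FPR; ties go to lower FPR."""
    j = curve.tpr - curve.fpr
    order = np.lexsort((curve.fpr, -j))  # best J first, then lowest FPR
    best = order[0]
    return (
        float(curve.fpr[best]),
        float(curve.tpr[best]),
        float(curve.thresholds[best]),
    )


def bootstrap_auc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded case-resampling percentile CI for the AUC (optional extra)."""
    rng = np.random.default_rng(seed)
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(s)
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if len(np.unique(y[idx])) < 2:
            continue
        aucs.append(roc_curve(s[idx], y[idx]).auc)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
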