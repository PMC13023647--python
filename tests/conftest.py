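"""Shared fixtures: simple rasters, phantoms, and reference oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from fourcv import biometrics, phantom
from fourcv.mask_io import STRUCTURES, StructureMaskSet

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_disk(shape: tuple[int, int], cx: float, cy: float, r: float) -> np.ndarray:
    y, x = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (x - cx) ** 2 + (y - cy) ** 2 <= r**2


def make_ellipse(
    shape: tuple[int, int], cx: float, cy: float, a: float, b: float
) -> np.ndarray:
    y, x = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


def mask_set_from(masks: dict[str, np.ndarray], **kwargs) -> StructureMaskSet:
    """Build a mask set, filling any unspecified structure with background."""
    shape = next(iter(masks.values())).shape
    full = {name: masks.get(name, np.zeros(shape, dtype=bool)) for name in STRUCTURES}
    return StructureMaskSet(width=shape[1], height=shape[0], masks=full, **kwargs)


def mirror_mask_set(mask_set: StructureMaskSet) -> StructureMaskSet:
    return StructureMaskSet(
        width=mask_set.width,
        height=mask_set.height,
        masks={k: v[:, ::-1].copy() for k, v in mask_set.masks.items()},
        source_id=mask_set.source_id + "_mirror",
    )


def sweep_bisect_angle(
    raster: np.ndarray, anchor: tuple[float, float], step: float = 0.05
) -> float:
    """Exhaustive-sweep oracle: line tilt (deg from vertical, in [-90, 90))
    through ``anchor`` minimizing the absolute half-plane pixel imbalance."""
    rows, cols = np.nonzero(raster)
    rel = np.column_stack([cols - anchor[0], rows - anchor[1]]).astype(float)
    thetas = np.arange(-90.0, 90.0, step)
    best_angle, best_err = 0.0, np.inf
    for start in range(0, len(thetas), 400):  # chunked to bound memory
        chunk = np.deg2rad(thetas[start : start + 400])
        ux, uy = np.sin(chunk), -np.cos(chunk)
        cross = np.outer(ux, rel[:, 1]) - np.outer(uy, rel[:, 0])
        imb = np.abs(
            (np.sum(cross > 1e-7, axis=1) - np.sum(cross < -1e-7, axis=1))
        ) / len(rel)
        i = int(np.argmin(imb))
        if imb[i] < best_err:
            best_err, best_angle = float(imb[i]), float(thetas[start + i])
    return best_angle


def auc_by_pair_counting(scores, labels) -> float:
    """Mann-Whitney oracle: fraction of (positive, negative) pairs ranked
    correctly, ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def normal_phantom():
    return phantom.generate_phantom(phantom.PhantomSpec())


@pytest.fixture(scope="session")
def normal_record(normal_phantom):
    mask_set, _ = normal_phantom
    return biometrics.compute_biometrics(mask_set)
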