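"""Reading, writing and validating structure mask sets.

A four-chamber-view (4CV) measurement starts from five co-registered binary
masks, one per anatomical structure: the heart, the ventricular septum, the
whole thorax (thoracic region with the spine hollow filled), the thorax
(whole thorax minus the spine region) and the descending aorta.  This module
fixes the on-disk format — one single-channel PNG per structure plus a JSON
manifest — and the validity rules every measurement assumes.

Coordinate convention (inherited by every geometry module): 0-based pixel
indices, x increases rightward (columns), y increases downward (rows); a
pixel's location is its center.  Any nonzero sample is foreground, so 0/1
and 0/255 mask dialects load identically; masks are written as 0/255.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import MaskFormatError, MaskLoadError

#: Canonical structure names, in manifest order.
STRUCTURES = (
    "heart",
    "ventricular_septum",
    "whole_thorax",
    "thorax",
    "descending_aorta",
)

#: Containment pairs checked by :func:`validate_mask_set` (child, parent).
_CONTAINMENT = (("heart", "whole_thorax"), ("ventricular_septum", "heart"))

#: Default tolerated fraction of a child's foreground outside its parent.
DEFAULT_CONTAINMENT_TOLERANCE = 0.02

MANIFEST_NAME = "manifest.json"


@dataclass
class MaskManifest:
    """Sidecar metadata carried with a mask set.

    ``presentation`` is the examiner-declared fetal presentation
    (``cephalic``/``breech``/``unknown``); ``extractable`` records whether a
    4CV could be obtained for the source video at all (non-extractable videos
    are screened positive downstream).
    """

    structures: dict[str, str]
    source_id: str = ""
    presentation: str = "unknown"
    extractable: bool = True
    pixel_spacing: float | None = None


@dataclass
class StructureMaskSet:
    """Five co-registered binary rasters, one per labeled structure.

    ``masks`` maps each name in :data:`STRUCTURES` to a boolean array of
    shape ``(height, width)``.  ``pixel_spacing`` is an optional isotropic
    length per pixel; all ratios and angles computed downstream are
    spacing-invariant, so it is carried only for provenance.
    """

    width: int
    height: int
    masks: dict[str, np.ndarray]
    pixel_spacing: float | None = None
    source_id: str = ""
    presentation: str = "unknown"
    extractable: bool = True

    def __post_init__(self) -> None:
        for name in STRUCTURES:
            if name not in self.masks:
                raise MaskFormatError(f"missing structure raster: {name}")
        clean: dict[str, np.ndarray] = {}
        for name, raster in self.masks.items():
            arr = np.asarray(raster)
            if arr.ndim != 2:
                raise MaskFormatError(f"{name}: raster must be 2-D")
            if arr.shape != (self.height, self.width):
                raise MaskFormatError(
                    f"{name}: shape {arr.shape} != ({self.height}, {self.width})"
                )
            clean[name] = arr.astype(bool)
        self.masks = clean

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


@dataclass
class Violation:
    """One validation failure: the structure involved and the broken rule."""

    structure: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.structure}: {self.rule}"


def read_mask_set(directory_path: str | Path) -> StructureMaskSet:
    """Load a mask set (five PNGs + manifest) from ``directory_path``.

    Any pixel value above zero is treated as foreground.  Raises
    :class:`MaskLoadError` naming the structure whose file is missing and
    :class:`MaskFormatError` on dimension mismatches.
    """
    directory = Path(directory_path)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.is_file():
        raise MaskLoadError(f"no manifest at {manifest_path}")
    payload = json.loads(manifest_path.read_text())
    structures = payload.get("structures", {})
    masks: dict[str, np.ndarray] = {}
    shape: tuple[int, int] | None = None
    for name in STRUCTURES:
        if name not in structures:
            raise MaskLoadError(f"manifest missing structure entry: {name}")
        file_path = directory / structures[name]
        if not file_path.is_file():
            raise MaskLoadError(f"missing mask file for {name}: {file_path}")
        arr = np.asarray(Image.open(file_path).convert("L"))
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise MaskFormatError(
                f"{name}: shape {arr.shape} differs from {shape}"
            )
        masks[name] = arr > 0
    assert shape is not None
    return StructureMaskSet(
        width=shape[1],
        height=shape[0],
        masks=masks,
        pixel_spacing=payload.get("pixel_spacing"),
        source_id=payload.get("source_id", ""),
        presentation=payload.get("presentation", "unknown"),
        extractable=bool(payload.get("extractable", True)),
    )


def write_mask_set(mask_set: StructureMaskSet, directory_path: str | Path) -> None:
    """Write one 0/255 PNG per structure plus the JSON manifest.

    ``read_mask_set(write_mask_set(x))`` reproduces every raster bit-exactly.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    structures = {name: f"{name}.png" for name in STRUCTURES}
    for name, filename in structures.items():
        img = Image.fromarray(
            np.where(mask_set[name], 255, 0).astype(np.uint8), mode="L"
        )
        img.save(directory / filename)
    manifest = {
        "structures": structures,
        "source_id": mask_set.source_id,
        "presentation": mask_set.presentation,
        "extractable": mask_set.extractable,
        "pixel_spacing": mask_set.pixel_spacing,
    }
    (directory / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))


def validate_mask_set(
    mask_set: StructureMaskSet,
    containment_tolerance: float = DEFAULT_CONTAINMENT_TOLERANCE,
) -> list[Violation]:
    """Check mask-set invariants; return a (possibly empty) violation list.

    Rules: the whole thorax must be non-empty, and heart ⊆ whole_thorax and
    ventricular_septum ⊆ heart must hold up to ``containment_tolerance``
    (fraction of the child's foreground allowed to stray outside the parent
    — real segmentations leak a little at boundaries).  Validation never
    raises; it reports.
    """
    violations: list[Violation] = []
    if not mask_set["whole_thorax"].any():
        violations.append(Violation("whole_thorax", "whole_thorax empty"))
    for child, parent in _CONTAINMENT:
        child_mask = mask_set[child]
        n_child = int(child_mask.sum())
        if n_child == 0:
            continue
        stray = int((child_mask & ~mask_set[parent]).sum())
        if stray > containment_tolerance * n_child:
            violations.append(
                Violation(
                    child,
                    f"containment: {child} ⊄ {parent} "
                    f"({stray}/{n_child} stray pixels)",
                )
            )
    return violations
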