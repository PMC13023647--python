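"""Run configuration: normal-range overrides and pipeline knobs.

Config files are flat key-value YAML (or JSON, a YAML subset).  Recognized
keys: ``ctar_max``, ``axis_center``, ``axis_halfwidth``, ``pointp_box``
(four numbers: gx_min, gx_max, gy_min, gy_max), ``pointp_divisions``,
``seed``, ``log_level``.  Defaults reproduce the guideline ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .biometrics import DEFAULT_POINTP_DIVISIONS
from .screening import NormalRanges


@dataclass
class RunConfig:
    ranges: NormalRanges = field(default_factory=NormalRanges)
    pointp_divisions: int = DEFAULT_POINTP_DIVISIONS
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: str | Path | None) -> RunConfig:
    """Load a :class:`RunConfig`; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    payload = yaml.safe_load(Path(path).read_text()) or {}
    range_kwargs = {}
    for key in ("ctar_max", "axis_center", "axis_halfwidth"):
        if key in payload:
            range_kwargs[key] = float(payload[key])
    if "pointp_box" in payload:
        range_kwargs["pointp_box"] = tuple(float(v) for v in payload["pointp_box"])
    return RunConfig(
        ranges=NormalRanges(**range_kwargs),
        pointp_divisions=int(payload.get("pointp_divisions", DEFAULT_POINTP_DIVISIONS)),
        seed=int(payload.get("seed", 0)),
        log_level=str(payload.get("log_level", "INFO")),
    )
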