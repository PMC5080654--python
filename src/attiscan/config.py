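"""Structured pipeline configuration (YAML-backed).

One config object carries every module's parameters and the seeds for
every random operation, so a run is reproducible end to end.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .scenes import CATEGORIES, ScanConfig
from .normals import ScaleConfig
from .stats import DEFAULT_BANDS, BinningConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    scan: ScanConfig = field(default_factory=ScanConfig)
    scale: ScaleConfig = field(default_factory=ScaleConfig)
    binning: BinningConfig = field(default_factory=BinningConfig)
    bands: tuple = DEFAULT_BANDS
    categories: tuple = CATEGORIES
    scenes_per_category: int = 2
    contrast_kind: str = "normalized"
    weighting: str = "solid_angle"
    calibration_distances_m: tuple = (3.0, 10.0, 30.0)
    #: cap on per-scene query points for normal estimation (0 = all)
    max_query_points: int = 20000
    n_movers: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.weighting not in ("solid_angle", "none"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.contrast_kind not in ("normalized", "log"):
            raise ValueError(f"unknown contrast kind {self.contrast_kind!r}")
        for cat in self.categories:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
        self.bands = tuple(tuple(b) for b in self.bands)
        los = [b[0] for b in self.bands]
        if los != sorted(los):
            raise ValueError("elevation bands must be ordered")
        for (lo, hi) in self.bands:
            if not lo < hi:
                raise ValueError("elevation band must have lo < hi")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for name, sub in (("scan", ScanConfig), ("scale", ScaleConfig), ("binning", BinningConfig)):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        if "bands" in kwargs:
            kwargs["bands"] = tuple(tuple(b) for b in kwargs["bands"])
        for key in ("categories", "calibration_distances_m"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
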