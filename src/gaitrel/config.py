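"""Run configuration: one object bundling every convention the pipeline
uses, serializable to/from YAML so any output is reproducible from
(inputs, config)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .indices import IndexConfig
from .preprocess import FilterConfig
from .reliability import ReliabilityConfig
from .segmentation import SegmentationConfig
from .types import SensorSite


@dataclass
class RunConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    index: IndexConfig = field(default_factory=IndexConfig)
    reliability: ReliabilityConfig = field(default_factory=ReliabilityConfig)
    static_window_s: tuple[float, float] = (0.0, 3.0)
    drop_incomplete: bool = True
    strict: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segmentation"]["anchor_leg"] = self.segmentation.anchor_leg.value
        d["index"]["parity"] = {k.value: v for k, v in self.index.parity.items()}
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "filter" in raw:
            cfg.filter = FilterConfig(**raw["filter"])
        if "segmentation" in raw:
            seg = dict(raw["segmentation"])
            if "anchor_leg" in seg:
                seg["anchor_leg"] = SensorSite(seg["anchor_leg"])
            if "stride_band_s" in seg:
                seg["stride_band_s"] = tuple(seg["stride_band_s"])
            cfg.segmentation = SegmentationConfig(**seg)
        if "index" in raw:
            idx = dict(raw["index"])
            if "parity" in idx:
                from .types import Axis

                idx["parity"] = {Axis(k): v for k, v in idx["parity"].items()}
            cfg.index = IndexConfig(**idx)
        if "reliability" in raw:
            cfg.reliability = ReliabilityConfig(**raw["reliability"])
        if "static_window_s" in raw:
            cfg.static_window_s = tuple(raw["static_window_s"])
        for key in ("drop_incomplete", "strict"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return Path(path)
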