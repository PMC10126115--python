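"""Pipeline configuration: every tunable in one dataclass, loadable from
JSON or YAML."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .adaptive import FilterRules, IterationGrid
from .contaminants import ContaminantModel


@dataclass
class PipelineConfig:
    dc_mode: str = "background"        # "background" | "mean"
    depth_px: int = 1024               # depth pixels kept after the transform
    roi_margin_alines: int = 10        # extra A-lines around the annotation
    qc_n_sd: float = 2.0
    qc_min_keep: int = 3
    fa_ssf: float = 0.06
    fa_window_dz_um: float = 29.0
    contaminants: ContaminantModel = field(default_factory=ContaminantModel)
    grid: IterationGrid = field(default_factory=IterationGrid)
    rules: FilterRules = field(default_factory=FilterRules)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kw = dict(data)
        if "contaminants" in kw and isinstance(kw["contaminants"], dict):
            kw["contaminants"] = ContaminantModel(**kw["contaminants"])
        if "grid" in kw and isinstance(kw["grid"], dict):
            kw["grid"] = IterationGrid(**{k: tuple(v) for k, v in kw["grid"].items()})
        if "rules" in kw and isinstance(kw["rules"], dict):
            kw["rules"] = FilterRules(**kw["rules"])
        return cls(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
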