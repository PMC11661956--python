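"""Pipeline configuration: one dataclass bundling every stage's parameters."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cluster_states import ClusterParams
from .dynamic_fnc import GlassoParams, WindowParams
from .meta_states import MetaParams
from .preprocess import PreprocessParams

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """All stage parameters plus paths and the master seed.

    Per-stage randomness is derived from ``seed`` with fixed offsets so that
    any stage can be re-run in isolation and reproduce the full-run output.
    """

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    window: WindowParams = field(default_factory=WindowParams)
    glasso: GlassoParams = field(default_factory=GlassoParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    meta: MetaParams = field(default_factory=MetaParams)
    alpha: float = 0.05
    variance_kept: float = 0.95
    seed: int = 0
    data_dir: str = "data"
    out_dir: str = "results"

    def stage_seed(self, stage: str) -> int:
        offsets = {"simulate": 0, "dfnc": 1, "states": 2, "metastates": 3, "stats": 4}
        return (self.seed * 1000 + offsets[stage]) % (2**31 - 1)


def _to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["glasso"]["penalty_grid"] = [float(a) for a in d["glasso"]["penalty_grid"]]
    return d


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = (
        json.dumps(_to_dict(cfg), indent=2)
        if path.suffix == ".json"
        else yaml.safe_dump(_to_dict(cfg))
    )
    path.write_text(text)
    return path


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    raw = path.read_text()
    d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    d = d or {}
    kwargs = {}
    sections = {
        "preprocess": PreprocessParams,
        "window": WindowParams,
        "glasso": GlassoParams,
        "cluster": ClusterParams,
        "meta": MetaParams,
    }
    for key, cls in sections.items():
        if key in d:
            sub = dict(d[key])
            if key == "glasso" and "penalty_grid" in sub:
                sub["penalty_grid"] = tuple(sub["penalty_grid"])
            kwargs[key] = cls(**sub)
    for key in ("alpha", "variance_kept", "seed", "data_dir", "out_dir"):
        if key in d:
            kwargs[key] = d[key]
    return PipelineConfig(**kwargs)
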