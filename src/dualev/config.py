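"""Run configuration: YAML in, dataclasses out, seed fan-out.

One top-level seed is fanned out to the stochastic stages through fixed
offsets so that a run is reproducible end to end from a single integer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from dualev.classical import SegmentationParams
from dualev.scene import SceneSpec
from dualev.segnet import SegNetConfig
from dualev.vae import VAEConfig

__all__ = ["RunConfig", "load_config", "stage_seed"]

# fixed per-stage seed offsets
_STAGE_OFFSETS = {
    "scene_ab": 101,
    "scene_igg": 202,
    "vae": 303,
    "vae_sample": 404,
    "cnn": 505,
    "assemble": 606,
}


def stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    return (seed * 1009 + _STAGE_OFFSETS[stage] + index) % (2**31 - 1)


@dataclass
class RunConfig:
    mode: str = "classical"  # or "cnn"
    seed: int = 0
    n_pairs: int = 8
    bound_fraction_ab: float = 0.32
    bound_fraction_igg: float = 0.05
    out_dir: str = "runs/demo"
    model_path: str | None = None  # required for mode="cnn"
    scene: SceneSpec = field(default_factory=SceneSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    vae: VAEConfig = field(default_factory=VAEConfig)
    cnn: SegNetConfig = field(default_factory=SegNetConfig)

    def validate(self) -> None:
        if self.mode not in ("classical", "cnn"):
            raise ValueError("mode must be 'classical' or 'cnn'")
        if self.mode == "cnn" and not self.model_path:
            raise ValueError("mode='cnn' requires model_path")
        self.scene.validate()


def _build(cls, block: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for k, v in block.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(
        **{k: v for k, v in raw.items() if k not in ("scene", "segmentation", "vae", "cnn")}
    )
    if "scene" in raw:
        cfg.scene = _build(SceneSpec, raw["scene"])
    if "segmentation" in raw:
        cfg.segmentation = _build(SegmentationParams, raw["segmentation"])
    if "vae" in raw:
        cfg.vae = _build(VAEConfig, raw["vae"])
    if "cnn" in raw:
        cfg.cnn = _build(SegNetConfig, raw["cnn"])
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    def to_dict(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    Path(path).write_text(yaml.safe_dump(to_dict(cfg), sort_keys=False))
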