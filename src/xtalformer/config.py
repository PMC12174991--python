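"""Schema-validated run configuration for the command-line interface.

Defaults reproduce the production training recipe: BERT-base encoder shape
(12 layers, hidden 768, 12 heads), 50 pre-training epochs at batch 512,
AdamW (lr 1e-4, weight decay 1e-2) with 5% warm-up then linear decay,
ε = 1.1 SEP weighting, 50×50 persistence images (spread 0.15, patch 5),
15% masking with 80/10/10 corruption, 200 atom pairs per crystal, and
50 fine-tuning epochs at batch 32 with an 80/10/10 split.

Unknown keys are rejected; validation errors carry field paths.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["RunConfig", "FeaturizationConfig", "EncoderConfig",
           "PretrainConfig", "FinetuneConfig", "PathsConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FeaturizationConfig(_Strict):
    resolution: int = 50
    spread: float = 0.15
    patch: int = 5
    min_extent: float = 20.0
    sigma: float = 0.05          # positional perturbation, Å
    k: int = 8                   # nearest neighbours for positional features

    @field_validator("resolution")
    @classmethod
    def _pos(cls, v):
        if v < 1:
            raise ValueError("resolution must be >= 1")
        return v


class EncoderConfig(_Strict):
    layers: int = 12
    hidden: int = 768
    heads: int = 12
    max_atoms: int = 512
    use_images: bool = True
    positional_mode: str = "relative"
    graph_width: int = 256
    graph_layers: int = 2
    ff_mult: int = 4

    @field_validator("positional_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("relative", "absolute"):
            raise ValueError("positional_mode must be 'relative' or 'absolute'")
        return v


class PretrainConfig(_Strict):
    epochs: int = 50
    batch_size: int = 512
    lr: float = 1e-4
    weight_decay: float = 1e-2
    warmup_fraction: float = 0.05
    mask_rate: float = 0.15
    corruption_split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_pairs: int = 200
    epsilon: float = 1.1
    enabled: bool = True         # False → fine-tune from random init


class FinetuneConfig(_Strict):
    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-4
    weight_decay: float = 1e-2
    warmup_fraction: float = 0.05
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    top_n: int = 10
    direction: str = "lowest"


class PathsConfig(_Strict):
    run_dir: str = "runs"
    cache_dir: str = "feature_cache"


class RunConfig(_Strict):
    featurization: FeaturizationConfig = Field(default_factory=FeaturizationConfig)
    model: EncoderConfig = Field(default_factory=EncoderConfig)
    pretrain: PretrainConfig = Field(default_factory=PretrainConfig)
    finetune: FinetuneConfig = Field(default_factory=FinetuneConfig)
    paths: PathsConfig = Field(default_factory=PathsConfig)
    seed: int = 0

    def model_config_obj(self):
        from .model import ModelConfig
        m = self.model
        f = self.featurization
        return ModelConfig(layers=m.layers, hidden=m.hidden, heads=m.heads,
                           max_atoms=m.max_atoms, patch=f.patch,
                           resolution=f.resolution, use_images=m.use_images,
                           positional_mode=m.positional_mode,
                           graph_width=m.graph_width,
                           graph_layers=m.graph_layers,
                           knn_k=f.k, perturb_sigma=f.sigma,
                           ff_mult=m.ff_mult)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load YAML/JSON config; missing path → defaults. ``overrides`` is a
    nested dict merged on top."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text)) or {}
    for key, value in (overrides or {}).items():
        section, _, field = key.partition(".")
        if field:
            data.setdefault(section, {})[field] = value
        else:
            data[section] = value
    return RunConfig(**data)
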