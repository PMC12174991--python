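"""Desk-scale study conditions shared by the test suite and the
acceptance script.

One fixed recipe — a 240-crystal fixture corpus (200 train / 40 held out;
diatomic and bent-triatomic templates over space groups {1, 2, 4, 19},
four element types), a reduced encoder (2 layers, hidden 64, 4 heads) and
50 pre-training epochs — so every end-to-end number reported anywhere in
this repository comes from the same, reproducible computation. Featurization
is correspondingly desk-sized: 30×30 persistence images (5×5 patches) on a
12 Å supercell extent and a 2× feed-forward width.

Sampling-scheme constants (15% masking, 80/10/10 corruption, 200 pairs,
ε = 1.1, 5% warm-up, AdamW weight decay 1e-2) are the production values; the
optimisation scale is desk-sized to the corpus (batch 8, peak lr 2e-3 —
at 200 structures the production lr of 1e-4 would leave a small model far
from convergence within the 50-epoch budget).
"""

from __future__ import annotations

import numpy as np

from .featurize import ElementVocab
from .fixtures import make_dataset
from .model import ModelConfig
from .training import (StructureFeatures, evaluate_pretrain, prepare_features,
                       pretrain, PretrainResult)

__all__ = [
    "toy_model_config", "build_toy_corpus", "run_toy_pretraining",
    "TOY_MIN_EXTENT", "TOY_N_TRAIN", "TOY_N_EVAL",
]

TOY_MIN_EXTENT = 12.0
TOY_N_TRAIN = 200
TOY_N_EVAL = 40
TOY_TEMPLATES = ("N2", "Cl2", "water")


def toy_model_config(**overrides) -> ModelConfig:
    base = dict(layers=2, hidden=64, heads=4, graph_width=64, graph_layers=2,
                resolution=30, patch=5, ff_mult=2)
    base.update(overrides)
    return ModelConfig(**base)


def build_toy_corpus(seed: int = 0, n_train: int = TOY_N_TRAIN,
                     n_eval: int = TOY_N_EVAL):
    """(train, eval) lists of (structure, record) fixture pairs."""
    data = make_dataset(n_train + n_eval, seed=seed, templates=TOY_TEMPLATES)
    return data[:n_train], data[n_train:]


def run_toy_pretraining(seed: int = 0, epochs: int = 50, batch_size: int = 8,
                        lr: float = 2e-3,
                        n_train: int = TOY_N_TRAIN, n_eval: int = TOY_N_EVAL,
                        **config_overrides):
    """Full reduced-scale pre-training run.

    Returns a dict with the PretrainResult, held-out task metrics, the
    prepared train/eval features and the vocabulary — enough to reuse the
    corpus for fine-tuning and attribution without recomputation.
    """
    train, evald = build_toy_corpus(seed=seed, n_train=n_train, n_eval=n_eval)
    cfg = toy_model_config(**config_overrides)
    vocab = ElementVocab(sorted({el for s, _ in train + evald for el in s.elements}))
    feats = prepare_features(train, vocab, cfg, min_extent=TOY_MIN_EXTENT)
    eval_feats = prepare_features(evald, vocab, cfg, min_extent=TOY_MIN_EXTENT)
    result: PretrainResult = pretrain(
        feats, cfg, seed=seed, epochs=epochs, batch_size=batch_size, lr=lr,
        eval_features=eval_feats)
    return {
        "config": cfg,
        "vocab": vocab,
        "train": train,
        "eval": evald,
        "train_features": feats,
        "eval_features": eval_feats,
        "result": result,
        "metrics": result.metrics,
    }


def finetune_comparison(run: dict, seeds=(0, 1, 2, 3, 4), n_records: int = 100,
                        epochs: int = 12, batch_size: int = 32):
    """Pre-trained vs random-init fine-tuning on a synthetic density target.

    Reuses the toy corpus features; for each seed both initialisations are
    fine-tuned on the same split and evaluated on the same test records.
    Returns {"pretrained": [...], "scratch": [...]} test MAEs per seed.
    """
    import pandas as pd

    from .finetune import PropertyDataset, finetune
    from .model import CrystalTransformer

    cfg = run["config"]
    feats = run["train_features"][:n_records]
    structures = run["train"][:n_records]
    ids = [s.structure_id for s, _ in structures]
    labels = [rec["density"] for _, rec in structures]
    features_by_id = dict(zip(ids, feats))
    table = pd.DataFrame({"structure_id": ids, "label": labels})
    source = run["result"].model

    out = {"pretrained": [], "scratch": []}
    for seed in seeds:
        ds = PropertyDataset(table.copy(), seed=seed)
        warm = CrystalTransformer(cfg, source.vocab, seed=seed)
        warm.load_state_arrays([a.copy() for a in source.state_arrays()])
        _, rep_warm = finetune(warm, features_by_id, ds, seed=seed,
                               epochs=epochs, batch_size=batch_size, lr=1e-3)
        cold = CrystalTransformer(cfg, source.vocab, seed=seed)
        _, rep_cold = finetune(cold, features_by_id, ds, seed=seed,
                               epochs=epochs, batch_size=batch_size, lr=1e-3)
        out["pretrained"].append(rep_warm.mae)
        out["scratch"].append(rep_cold.mae)
    return out


def ablation_smoke(seed: int = 0, epochs: int = 3, n: int = 40):
    """The two architecture ablations — image-free encoder and absolute
    positional embeddings — must pre-train end-to-end from config switches
    alone. Returns the held-out metric dicts per ablation."""
    out = {}
    for name, overrides in (("no_images", {"use_images": False}),
                            ("absolute_positional",
                             {"positional_mode": "absolute"})):
        res = run_toy_pretraining(seed=seed, epochs=epochs, n_train=n,
                                  n_eval=10, **overrides)
        out[name] = res["metrics"]
    return out
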