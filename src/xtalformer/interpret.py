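"""Attention-rollout attribution of predictions to atoms and image patches.

Transformers mix token information layer by layer, so raw last-layer
attention misattributes importance. Attention rollout composes the
layer-wise attention maps: heads are averaged, a residual identity is mixed
in (A' = α·I + (1−α)·A, rows renormalised, α = 0.5 by default) and the
modified matrices are multiplied across layers. The [CLS] row of the
product scores every input token's cumulative contribution to the
whole-crystal representation.

Scores are normalised over non-special tokens (atoms, patches, [SCL]) so
atom and image shares are directly comparable; a display floor (default
0.005) clips negligible atoms in exported overlays.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .crystal_io import write_xyz
from .model import CrystalTransformer
from .training import StructureFeatures, epoch_positional

__all__ = ["AttributionResult", "attention_rollout", "attribute", "export_attribution"]


@dataclasses.dataclass
class AttributionResult:
    """Rolled-out [CLS] attention mapped back to inputs; scores over
    non-special tokens sum to 1 (before clipping)."""

    atom_scores: np.ndarray
    patch_scores_1d: np.ndarray
    patch_scores_2d: np.ndarray
    scl_scores: np.ndarray
    clip_threshold: float = 0.005

    def clipped_atom_scores(self) -> np.ndarray:
        out = self.atom_scores.copy()
        out[out < self.clip_threshold] = 0.0
        return out

    def top_patches(self, which: str = "1d", k: int = 10) -> list[int]:
        scores = self.patch_scores_1d if which == "1d" else self.patch_scores_2d
        k = min(k, len(scores))
        return list(np.argsort(-scores, kind="stable")[:k])


def attention_rollout(attentions: list[np.ndarray], residual_alpha: float = 0.5,
                      cls_position: int = 0) -> np.ndarray:
    """Roll attention across layers and return the [CLS] row.

    ``attentions``: per-layer arrays of shape (heads, T, T) or (T, T), rows
    summing to 1. Per layer, heads are averaged, residual-mixed with α·I
    and renormalised; the rollout is the ordered product A'_L ··· A'_1.
    """
    if not attentions:
        raise ValueError("need at least one attention layer")
    rolled = None
    for layer in attentions:
        A = np.asarray(layer, dtype=float)
        if A.ndim == 3:
            A = A.mean(axis=0)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("attention must be (T, T) or (heads, T, T)")
        if np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-3):
            raise ValueError("attention rows must sum to 1")
        A = residual_alpha * np.eye(A.shape[0]) + (1.0 - residual_alpha) * A
        A = A / A.sum(axis=1, keepdims=True)
        rolled = A if rolled is None else A @ rolled
    return rolled[cls_position]


def attribute(model: CrystalTransformer, feat: StructureFeatures,
              residual_alpha: float = 0.5, clip_threshold: float = 0.005,
              seed: int = 0) -> AttributionResult:
    """Run the model on one structure and attribute the [CLS] output over
    atoms, patches and [SCL] tokens."""
    cfg = model.cfg
    with nn.set_grad_enabled(False):
        inputs = [epoch_positional(feat, cfg, seed=seed)]
        reps, layouts, attns = model.forward(inputs, collect_attention=True)
    layout = layouts[0]
    T = layout.length
    per_layer = [a[0, :, :T, :T] for a in attns]
    cls_row = attention_rollout(per_layer, residual_alpha)

    atom_pos = layout.positions("ATOM")
    p1_pos = layout.positions("PATCH1D")
    p2_pos = layout.positions("PATCH2D")
    scl_pos = layout.positions("SCL")
    keep = atom_pos + p1_pos + p2_pos + scl_pos
    norm = cls_row[keep].sum()
    if norm <= 0:
        raise ValueError("degenerate rollout: no mass on non-special tokens")
    scaled = cls_row / norm
    return AttributionResult(
        atom_scores=scaled[atom_pos],
        patch_scores_1d=scaled[p1_pos],
        patch_scores_2d=scaled[p2_pos],
        scl_scores=scaled[scl_pos],
        clip_threshold=clip_threshold,
    )


def export_attribution(result: AttributionResult, structure, path_prefix: str | Path,
                       resolution: int | None = None, patch: int = 5) -> dict[str, Path]:
    """Write attribution artefacts:

    * ``<prefix>.xyz`` — extended XYZ with a per-atom score column
      (clipped at the display floor),
    * ``<prefix>.patches.npz`` — patch-score overlay grids per image,
    * ``<prefix>.json`` — summary with top-10 patches and [SCL] scores.
    """
    prefix = Path(path_prefix)
    paths = {}
    xyz = prefix.with_suffix(".xyz")
    write_xyz(structure, xyz,
              extra_columns={"attention": result.clipped_atom_scores()})
    paths["xyz"] = xyz

    def overlay(scores):
        k = int(round(np.sqrt(len(scores))))
        return scores.reshape(k, k)

    npz = prefix.parent / (prefix.name + ".patches.npz")
    np.savez(npz, patch_scores_1d=overlay(result.patch_scores_1d),
             patch_scores_2d=overlay(result.patch_scores_2d))
    paths["patches"] = npz

    js = prefix.with_suffix(".json")
    js.write_text(json.dumps({
        "top10_patches_1d": [int(i) for i in result.top_patches("1d")],
        "top10_patches_2d": [int(i) for i in result.top_patches("2d")],
        "scl_scores": [float(x) for x in result.scl_scores],
        "clip_threshold": result.clip_threshold,
        "atom_score_sum": float(result.atom_scores.sum()),
        "patch_score_sum": float(result.patch_scores_1d.sum()
                                 + result.patch_scores_2d.sum()),
    }, indent=1))
    paths["summary"] = js
    return paths
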