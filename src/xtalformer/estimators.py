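"""scikit-learn style estimators — the package's primary public API.

Three estimators compose with sklearn pipelines and model selection:

* :class:`PersistenceImageFeaturizer` — stateless transformer from crystal
  structures to flattened persistence-image patch features (+ scale
  scalars), usable with any downstream sklearn regressor.
* :class:`CrystalTransformerPretrainer` — self-supervised fit of the
  multi-modal transformer on unlabeled crystals (four pre-training tasks).
* :class:`CrystalPropertyRegressor` — supervised fit/predict on scalar
  crystal properties, optionally warm-started from a pre-trained model.

Inputs ``X`` are lists of :class:`~xtalformer.crystal_io.CrystalStructure`
in P1 with molecule labels assigned (see ``crystal_io.to_p1`` /
``assign_molecules``).
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .crystal_io import density
from .featurize import ElementVocab
from .model import CrystalTransformer, ModelConfig
from .topology import featurize_structure, patchify
from .training import evaluate_pretrain, prepare_features, pretrain
from .finetune import PropertyDataset, finetune, predict as _predict

__all__ = [
    "PersistenceImageFeaturizer",
    "CrystalTransformerPretrainer",
    "CrystalPropertyRegressor",
]


def _check_structures(X):
    X = list(X)
    if not X:
        raise ValueError("X must contain at least one structure")
    for s in X:
        if not hasattr(s, "frac_coords"):
            raise TypeError("X must be a list of CrystalStructure objects")
    return X


class PersistenceImageFeaturizer(TransformerMixin, BaseEstimator):
    """Persistent-homology image features of periodic crystals.

    ``transform`` returns, per structure, the concatenation of the 1D and
    2D persistence-image patch vectors plus the four scale scalars
    (max persistence / max birth per image), i.e. a flat matrix of width
    ``2·resolution² + 4``.
    """

    def __init__(self, resolution: int = 50, spread: float = 0.15,
                 min_extent: float = 20.0, patch: int = 5):
        self.resolution = resolution
        self.spread = spread
        self.min_extent = min_extent
        self.patch = patch

    def fit(self, X, y=None):
        _check_structures(X)
        if self.resolution % self.patch:
            raise ValueError("patch must divide resolution")
        self.n_features_out_ = 2 * self.resolution ** 2 + 4
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_out_")
        X = _check_structures(X)
        rows = []
        for s in X:
            images, _, _ = featurize_structure(
                s, resolution=self.resolution, spread=self.spread,
                min_extent=self.min_extent)
            rows.append(np.concatenate([
                patchify(images.image_1d, self.patch).ravel(),
                patchify(images.image_2d, self.patch).ravel(),
                [images.max_persistence_1d, images.max_birth_1d,
                 images.max_persistence_2d, images.max_birth_2d]]))
        return np.asarray(rows)


class CrystalTransformerPretrainer(BaseEstimator):
    """Self-supervised pre-training on unlabeled molecular crystals.

    ``fit(X, y=None)``: X is a list of P1 structures with molecules
    assigned. ``y`` may be a list of dicts carrying ``sep_bits`` (7-bit
    symmetry-element labels) and optionally ``density``; densities are
    otherwise computed from the structures, and the SEP task is skipped
    when no labels are given.

    Fitted attributes: ``model_``, ``history_``, ``density_scaler_``,
    ``sep_weights_``, ``metrics_`` (when ``eval_structures`` given).
    """

    def __init__(self, layers: int = 12, hidden: int = 768, heads: int = 12,
                 graph_width: int = 256, graph_layers: int = 2,
                 resolution: int = 50, patch: int = 5, use_images: bool = True,
                 positional_mode: str = "relative", ff_mult: int = 4,
                 min_extent: float = 20.0, epochs: int = 50,
                 batch_size: int = 512, lr: float = 1e-4,
                 weight_decay: float = 1e-2, warmup_fraction: float = 0.05,
                 mask_rate: float = 0.15, n_pairs: int = 200,
                 epsilon: float = 1.1, random_state: int = 0):
        self.layers = layers
        self.hidden = hidden
        self.heads = heads
        self.graph_width = graph_width
        self.graph_layers = graph_layers
        self.resolution = resolution
        self.patch = patch
        self.use_images = use_images
        self.positional_mode = positional_mode
        self.ff_mult = ff_mult
        self.min_extent = min_extent
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.warmup_fraction = warmup_fraction
        self.mask_rate = mask_rate
        self.n_pairs = n_pairs
        self.epsilon = epsilon
        self.random_state = random_state

    def _config(self) -> ModelConfig:
        return ModelConfig(layers=self.layers, hidden=self.hidden,
                           heads=self.heads, graph_width=self.graph_width,
                           graph_layers=self.graph_layers,
                           resolution=self.resolution, patch=self.patch,
                           use_images=self.use_images,
                           positional_mode=self.positional_mode,
                           ff_mult=self.ff_mult)

    @staticmethod
    def _records(X, y):
        recs = []
        for i, s in enumerate(X):
            rec = dict(y[i]) if y is not None else {}
            rec.setdefault("density", density(s))
            rec.setdefault("sep_bits", None)
            recs.append(rec)
        return recs

    def fit(self, X, y=None, eval_structures=None, eval_y=None):
        X = _check_structures(X)
        cfg = self._config()
        vocab = ElementVocab(sorted({el for s in X for el in s.elements}))
        feats = prepare_features(list(zip(X, self._records(X, y))), vocab, cfg,
                                 min_extent=self.min_extent)
        eval_feats = None
        if eval_structures is not None:
            eval_feats = prepare_features(
                list(zip(eval_structures, self._records(eval_structures, eval_y))),
                vocab, cfg, min_extent=self.min_extent)
        result = pretrain(feats, cfg, seed=self.random_state,
                          epochs=self.epochs, batch_size=self.batch_size,
                          lr=self.lr, weight_decay=self.weight_decay,
                          warmup_fraction=self.warmup_fraction,
                          mask_rate=self.mask_rate, n_pairs=self.n_pairs,
                          epsilon=self.epsilon, eval_features=eval_feats)
        self.model_ = result.model
        self.history_ = result.history
        self.density_scaler_ = result.density_scaler
        self.sep_weights_ = result.sep_weights
        self.metrics_ = result.metrics
        self.features_ = feats
        return self

    def score_tasks(self, X, y=None, seed: int = 0) -> dict:
        """Held-out metrics of the four pre-training tasks."""
        check_is_fitted(self, "model_")
        feats = prepare_features(list(zip(X, self._records(X, y))),
                                 self.model_.vocab, self.model_.cfg,
                                 min_extent=self.min_extent)
        return evaluate_pretrain(self.model_, feats, self.model_.cfg,
                                 self.density_scaler_, seed=seed)


class CrystalPropertyRegressor(RegressorMixin, BaseEstimator):
    """Scalar crystal-property regression with the multi-modal transformer.

    ``pretrained`` may be a fitted :class:`CrystalTransformerPretrainer`
    or a :class:`~xtalformer.model.CrystalTransformer`; if None the model
    trains from random initialisation (the no-pre-training ablation).

    ``fit(X, y)`` carves a 90/10 train/validation split internally and
    keeps the best-validation epoch. Fitted attributes: ``model_``,
    ``report_`` (validation report of the selected epoch).
    """

    def __init__(self, pretrained=None, layers: int = 12, hidden: int = 768,
                 heads: int = 12, graph_width: int = 256, graph_layers: int = 2,
                 resolution: int = 50, patch: int = 5, use_images: bool = True,
                 positional_mode: str = "relative", ff_mult: int = 4,
                 min_extent: float = 20.0, epochs: int = 50,
                 batch_size: int = 32, lr: float = 1e-4,
                 weight_decay: float = 1e-2, warmup_fraction: float = 0.05,
                 random_state: int = 0):
        self.pretrained = pretrained
        self.layers = layers
        self.hidden = hidden
        self.heads = heads
        self.graph_width = graph_width
        self.graph_layers = graph_layers
        self.resolution = resolution
        self.patch = patch
        self.use_images = use_images
        self.positional_mode = positional_mode
        self.ff_mult = ff_mult
        self.min_extent = min_extent
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.warmup_fraction = warmup_fraction
        self.random_state = random_state

    def _base_model(self, X) -> CrystalTransformer:
        import copy
        if self.pretrained is None:
            cfg = ModelConfig(layers=self.layers, hidden=self.hidden,
                              heads=self.heads, graph_width=self.graph_width,
                              graph_layers=self.graph_layers,
                              resolution=self.resolution, patch=self.patch,
                              use_images=self.use_images,
                              positional_mode=self.positional_mode,
                              ff_mult=self.ff_mult)
            vocab = ElementVocab(sorted({el for s in X for el in s.elements}))
            return CrystalTransformer(cfg, vocab, seed=self.random_state)
        source = getattr(self.pretrained, "model_", self.pretrained)
        clone = CrystalTransformer(source.cfg, source.vocab,
                                   seed=self.random_state)
        clone.load_state_arrays([a.copy() for a in source.state_arrays()])
        return clone

    def fit(self, X, y):
        import pandas as pd
        X = _check_structures(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if len(X) < 3:
            raise ValueError("need at least 3 records for a train/val split")
        model = self._base_model(X)
        ids = [f"rec{i:06d}" for i in range(len(X))]
        records = [{"density": density(s), "sep_bits": None} for s in X]
        feats = prepare_features(list(zip(X, records)), model.vocab, model.cfg,
                                 min_extent=self.min_extent)
        features_by_id = dict(zip(ids, feats))
        table = pd.DataFrame({"structure_id": ids, "label": y})
        ds = PropertyDataset(table, seed=self.random_state,
                             proportions=(0.9, 0.1, 0.0))
        # formal one-record test split so the shared loop applies unchanged
        t = ds.table
        pool = t.index[t["split"] == "val"]
        if len(pool) == 0:
            t.loc[t.index[:1], "split"] = "val"
            pool = t.index[t["split"] == "val"]
        t.loc[pool[-1:], "split"] = "test"
        if (t["split"] == "val").sum() == 0:
            t.loc[t.index[t["split"] == "train"][-1:], "split"] = "val"
        self.model_, self.report_ = finetune(
            model, features_by_id, ds, seed=self.random_state,
            epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
            weight_decay=self.weight_decay,
            warmup_fraction=self.warmup_fraction)
        self._min_extent_used = self.min_extent
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = _check_structures(X)
        records = [{"density": density(s), "sep_bits": None} for s in X]
        feats = prepare_features(list(zip(X, records)), self.model_.vocab,
                                 self.model_.cfg, min_extent=self.min_extent)
        return _predict(self.model_, feats, seed=self.random_state)
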