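"""Fine-tuning on property tables: splits, metrics and the few-shot
protocol.

A pre-trained checkpoint is extended with a fresh single dense head on the
[CLS] token and all weights are fine-tuned (AdamW lr 1e-4 / wd 1e-2, 5%
warm-up then linear decay, default 50 epochs, batch 32). Datasets are
property tables (structure_id → scalar label, optional family tag) split
80/10/10 at random with a stored seed; the epoch with the best validation
MAE is evaluated on the test split.

Metrics: MAE, R² = 1 − SS_res/SS_tot, and top-n overlap — the size of the
intersection between the n best true and n best predicted records (lowest
for energies, highest for capacities), the quantity a screening campaign
actually cares about.

The few-shot protocol holds out one molecular family entirely: stage 1
fine-tunes on every other family (90/10 train/val); stage 2 further
fine-tunes on k sampled holdout records (k = 0 is zero-shot) and always
evaluates on the untouched holdout remainder.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .model import CrystalTransformer
from .training import StructureFeatures, epoch_positional

__all__ = [
    "PropertyDataset", "EvalReport", "r2", "top_n_overlap",
    "finetune", "predict", "few_shot_protocol",
]


@dataclasses.dataclass
class PropertyDataset:
    """Property table with a reproducible 80/10/10 split.

    Split assignment is by uniform random draw per record over the
    records sorted by structure_id, so it is invariant to input order.
    """

    table: pd.DataFrame  # columns: structure_id, label[, family]
    seed: int = 0
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self):
        required = {"structure_id", "label"}
        if not required.issubset(self.table.columns):
            raise ValueError("table needs structure_id and label columns")
        df = self.table.copy().sort_values("structure_id").reset_index(drop=True)
        rng = np.random.default_rng(self.seed)
        u = rng.random(len(df))
        p_train, p_val, _ = self.proportions
        split = np.where(u < p_train, "train",
                         np.where(u < p_train + p_val, "val", "test"))
        df["split"] = split
        self.table = df

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = 0, **kw) -> "PropertyDataset":
        return cls(pd.read_csv(path), seed=seed, **kw)

    def ids(self, split: str) -> list[str]:
        return list(self.table.loc[self.table["split"] == split, "structure_id"])

    def labels(self, split: str) -> np.ndarray:
        return self.table.loc[self.table["split"] == split, "label"].to_numpy(float)


@dataclasses.dataclass
class EvalReport:
    mae: float
    r2: float
    top_n_overlap: int
    n: int
    predictions: pd.DataFrame  # structure_id, y_true, y_pred

    def __post_init__(self):
        if self.r2 > 1 + 1e-9:
            raise ValueError("r2 cannot exceed 1")
        if not 0 <= self.top_n_overlap <= self.n:
            raise ValueError("top-n overlap out of bounds")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"mae": self.mae, "r2": self.r2,
             "top_n_overlap": self.top_n_overlap, "n": self.n}, indent=1))

    def to_csv(self, path: str | Path) -> None:
        self.predictions.to_csv(path, index=False)


def r2(pred, true) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot."""
    pred = np.asarray(pred, float)
    true = np.asarray(true, float)
    if len(true) < 2:
        raise ValueError("need at least two records")
    ss_tot = float(((true - true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("true values have zero variance")
    return 1.0 - float(((true - pred) ** 2).sum()) / ss_tot


def top_n_overlap(pred, true, n: int = 10, direction: str = "lowest") -> int:
    """|top-n(pred) ∩ top-n(true)|, ties broken by stable record order."""
    pred = np.asarray(pred, float)
    true = np.asarray(true, float)
    if n > len(pred):
        raise ValueError("n exceeds the number of records")
    sign = 1.0 if direction == "lowest" else -1.0
    top_pred = set(np.argsort(sign * pred, kind="stable")[:n])
    top_true = set(np.argsort(sign * true, kind="stable")[:n])
    return len(top_pred & top_true)


def _evaluate(model, feats: list[StructureFeatures], y: np.ndarray, cfg,
              seed: int, ids, n_top: int = 10,
              direction: str = "lowest", batch_size: int = 64):
    mu, sd = model.reg_scaler
    preds = []
    with nn.set_grad_enabled(False):
        for start in range(0, len(feats), batch_size):
            chunk = feats[start:start + batch_size]
            inputs = [epoch_positional(f, cfg, seed=seed + start + i)
                      for i, f in enumerate(chunk)]
            reps, _, _ = model.forward(inputs)
            cls = reps[np.arange(len(chunk)), np.zeros(len(chunk), dtype=int)]
            preds.extend(model.reg_head(cls).data.reshape(-1) * sd + mu)
    preds = np.array(preds)
    n_top = min(n_top, len(y))
    try:
        r2_val = r2(preds, y)
    except ValueError:  # degenerate split: < 2 records or constant labels
        r2_val = float("nan")
    return EvalReport(
        mae=float(np.mean(np.abs(preds - y))),
        r2=r2_val,
        top_n_overlap=top_n_overlap(preds, y, n_top, direction),
        n=n_top,
        predictions=pd.DataFrame(
            {"structure_id": ids, "y_true": y, "y_pred": preds}),
    )


def finetune(model: CrystalTransformer, features_by_id: dict[str, StructureFeatures],
             dataset: PropertyDataset, seed: int = 0, epochs: int = 50,
             batch_size: int = 32, lr: float = 1e-4, weight_decay: float = 1e-2,
             warmup_fraction: float = 0.05, n_top: int = 10,
             direction: str = "lowest", reinit_head: bool = True,
             log=None) -> tuple[CrystalTransformer, EvalReport]:
    """Fine-tune all model weights plus a fresh dense head; the epoch with
    the best validation MAE is evaluated on the test split."""
    cfg = model.cfg
    for split in ("train", "val", "test"):
        if not dataset.ids(split):
            raise ValueError(f"empty {split} split")
    rng = np.random.default_rng(seed)
    if reinit_head:
        model.reg_head = nn.Linear(cfg.hidden, 1, rng)

    train_ids = dataset.ids("train")
    y_train = dataset.labels("train")
    model.reg_scaler = (float(y_train.mean()), float(y_train.std() + 1e-8))
    mu, sd = model.reg_scaler

    opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)
    steps_per_epoch = max(1, (len(train_ids) + batch_size - 1) // batch_size)
    total_steps = epochs * steps_per_epoch
    best_val = np.inf
    best_state = [a.copy() for a in model.state_arrays()]
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(len(train_ids))
        for start in range(0, len(train_ids), batch_size):
            idx = order[start:start + batch_size]
            feats = [features_by_id[train_ids[i]] for i in idx]
            inputs = [epoch_positional(f, cfg, seed=int(rng.integers(2 ** 31)))
                      for f in feats]
            reps, _, _ = model.forward(inputs)
            cls = reps[np.arange(len(feats)), np.zeros(len(feats), dtype=int)]
            pred = model.reg_head(cls).reshape(-1)
            target = (y_train[idx] - mu) / sd
            loss = ((pred - target) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step(lr=nn.warmup_linear_schedule(step, total_steps, lr,
                                                  warmup_fraction))
            step += 1
        val_ids = dataset.ids("val")
        val = _evaluate(model, [features_by_id[i] for i in val_ids],
                        dataset.labels("val"), cfg,
                        seed=seed + 7000 + epoch, ids=val_ids,
                        n_top=n_top, direction=direction)
        if log:
            log({"epoch": epoch, "val_mae": val.mae})
        if val.mae < best_val:
            best_val = val.mae
            best_state = [a.copy() for a in model.state_arrays()]
    model.load_state_arrays(best_state)
    test_ids = dataset.ids("test")
    report = _evaluate(model, [features_by_id[i] for i in test_ids],
                       dataset.labels("test"), cfg,
                       seed=seed + 9000, ids=test_ids,
                       n_top=n_top, direction=direction)
    return model, report


def predict(model: CrystalTransformer, features: list[StructureFeatures],
            seed: int = 0) -> np.ndarray:
    """Predictions of the current regression head (original label units)."""
    cfg = model.cfg
    mu, sd = model.reg_scaler
    preds = []
    with nn.set_grad_enabled(False):
        for i, f in enumerate(features):
            reps, _, _ = model.forward([epoch_positional(f, cfg, seed=seed + i)])
            preds.append(model.reg_head(reps[0, 0]).item() * sd + mu)
    return np.array(preds)


def few_shot_protocol(model_factory, features_by_id: dict[str, StructureFeatures],
                      table: pd.DataFrame, holdout_family: str,
                      k_list=(0, 100, 200), seed: int = 0,
                      stage1_epochs: int = 50, stage2_epochs: int = 50,
                      batch_size: int = 32, n_top: int = 10,
                      direction: str = "lowest") -> dict[int, EvalReport]:
    """Family-holdout few-shot evaluation.

    ``model_factory()`` must return a fresh copy of the starting model
    (e.g. re-loaded from a checkpoint). Stage 1 fine-tunes on all
    non-holdout families with a 90/10 train/val split; stage 2, for each k,
    further fine-tunes on k sampled holdout records (10% carved out for
    validation when k ≥ 20) and evaluates on the remaining holdout records.
    k = 0 reports the stage-1 model directly.
    """
    if "family" not in table.columns:
        raise ValueError("few-shot protocol needs a family column")
    holdout = table[table["family"] == holdout_family].sort_values("structure_id")
    rest = table[table["family"] != holdout_family]
    if holdout.empty or rest.empty:
        raise ValueError("holdout family must be a proper subset of the data")
    for k in k_list:
        if k >= len(holdout):
            raise ValueError(f"k={k} is not smaller than the holdout size {len(holdout)}")

    stage1_ds = PropertyDataset(rest.copy(), seed=seed, proportions=(0.9, 0.1, 0.0))
    # PropertyDataset requires a test split for finetune(); give it one
    # validation record as a formal test so stage 1 reuses the same loop.
    t = stage1_ds.table
    if (t["split"] == "test").sum() == 0:
        val_idx = t.index[t["split"] == "val"]
        t.loc[val_idx[-1:], "split"] = "test"

    stage1_model, _ = finetune(model_factory(), features_by_id, stage1_ds,
                               seed=seed, epochs=stage1_epochs,
                               batch_size=batch_size, n_top=n_top,
                               direction=direction)
    stage1_state = [a.copy() for a in stage1_model.state_arrays()]

    rng = np.random.default_rng(seed + 1)
    reports: dict[int, EvalReport] = {}
    y_hold = holdout["label"].to_numpy(float)
    ids_hold = list(holdout["structure_id"])
    stage1_scaler = stage1_model.reg_scaler
    for k in k_list:
        model = model_factory()
        model.reg_head = stage1_model.reg_head  # keep the trained head
        model.reg_scaler = stage1_scaler
        model.load_state_arrays([a.copy() for a in stage1_state])
        if k == 0:
            test_idx = np.arange(len(holdout))
        else:
            sampled = rng.choice(len(holdout), size=k, replace=False)
            test_idx = np.setdiff1d(np.arange(len(holdout)), sampled)
            sub = holdout.iloc[sampled].copy()
            if k >= 20:
                ds_k = PropertyDataset(sub, seed=seed + k, proportions=(0.9, 0.1, 0.0))
                t = ds_k.table
                val_idx = t.index[t["split"] == "val"]
                if len(val_idx) == 0:
                    t.loc[t.index[-1:], "split"] = "val"
                    val_idx = t.index[t["split"] == "val"]
                t.loc[val_idx[-1:], "split"] = "test"
            else:
                ds_k = PropertyDataset(sub, seed=seed + k, proportions=(1.0, 0.0, 0.0))
                t = ds_k.table
                t.loc[t.index[-2:-1], "split"] = "val"
                t.loc[t.index[-1:], "split"] = "test"
            model, _ = finetune(model, features_by_id, ds_k, seed=seed + k,
                                epochs=stage2_epochs, batch_size=batch_size,
                                n_top=n_top, direction=direction,
                                reinit_head=False)
        feats = [features_by_id[ids_hold[i]] for i in test_idx]
        reports[k] = _evaluate(model, feats, y_hold[test_idx], model.cfg,
                               seed=seed + 5000 + k,
                               ids=[ids_hold[i] for i in test_idx],
                               n_top=min(n_top, len(test_idx)),
                               direction=direction)
    return reports
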