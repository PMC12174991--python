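"""Multi-modal crystal transformer: token sequence, encoder and heads.

Token layout (images on)::

    [CLS] ATOM×n [SEP] PATCH1D×100 SCL SCL [SEP] PATCH2D×100 SCL SCL

so the sequence length is n + 207 with a 50×50 image cut into 5×5 patches.
With ``use_images`` off the sequence ends after the first [SEP] (a pure
atom-graph transformer — the image-free ablation). The [CLS] token carries
whole-crystal state for the global heads; the two [SCL] tokens after each
image carry that image's maximum persistence and maximum birth, which the
per-image scaling of the persistence images would otherwise discard.

Pre-training heads (all fed from the encoder output):

* MAP — masked atom prediction: softmax over the element vocabulary at the
  15% of atom tokens selected for corruption (80% → [MASK] identity,
  10% → random other element, 10% left unchanged).
* APC — atom pair classification: order-symmetric same-molecule logit
  g([h_i;h_j]) + g([h_j;h_i]) on 200 sampled pairs, half intra- half
  inter-molecular.
* CDP — crystal density regression from [CLS] through one dense layer.
* SEP — 7-dim symmetry-element multi-hot from [CLS], inverse-frequency
  weighted binary cross-entropy.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from . import nn
from .featurize import AtomGraph, ElementVocab, GraphEmbedder
from .symmetry import ELEMENT_NAMES

__all__ = [
    "ModelConfig", "TokenSequence", "token_layout", "CrystalTransformer",
    "mask_atoms", "sample_pairs", "APC_DISABLED",
    "cross_entropy", "bce_with_logits", "weighted_sep_loss", "pretrain_loss",
    "save_checkpoint", "load_checkpoint",
]

TOKEN_TYPES = ("CLS", "ATOM", "SEP", "PATCH1D", "PATCH2D", "SCL")
APC_DISABLED = "apc-disabled"  # sentinel for single-molecule cells


@dataclasses.dataclass
class ModelConfig:
    """Encoder and featurization geometry.

    Defaults are the BERT-base-shaped production values; tests use a
    reduced model (layers=2, hidden=64, heads=4).
    """

    layers: int = 12
    hidden: int = 768
    heads: int = 12
    max_atoms: int = 512
    patch: int = 5
    resolution: int = 50
    use_images: bool = True
    positional_mode: str = "relative"  # or "absolute"
    graph_width: int = 256
    graph_layers: int = 2
    knn_k: int = 8
    n_anchors: int = 8
    perturb_sigma: float = 0.05
    position_bins: int = 100
    ff_mult: int = 4

    def __post_init__(self):
        if self.hidden % self.heads:
            raise ValueError("hidden width must be divisible by head count")
        if self.resolution % self.patch:
            raise ValueError("patch must divide resolution")
        if self.positional_mode not in ("relative", "absolute"):
            raise ValueError("positional_mode must be 'relative' or 'absolute'")

    @property
    def n_patches(self) -> int:
        return (self.resolution // self.patch) ** 2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class TokenSequence:
    """Declarative layout of one structure's token sequence."""

    token_types: list[str]
    atom_index_map: dict[int, int]   # token position -> atom index
    scl_values: tuple[float, float, float, float] | None

    @property
    def length(self) -> int:
        return len(self.token_types)

    def positions(self, token_type: str) -> list[int]:
        return [p for p, t in enumerate(self.token_types) if t == token_type]


def token_layout(n_atoms: int, cfg: ModelConfig,
                 scl_values=None) -> TokenSequence:
    """The single source of truth for token ordering."""
    if n_atoms > cfg.max_atoms:
        raise ValueError(f"structure has {n_atoms} atoms, exceeding max_atoms={cfg.max_atoms}")
    types = ["CLS"] + ["ATOM"] * n_atoms + ["SEP"]
    if cfg.use_images:
        types += ["PATCH1D"] * cfg.n_patches + ["SCL", "SCL", "SEP"]
        types += ["PATCH2D"] * cfg.n_patches + ["SCL", "SCL"]
    atom_map = {1 + i: i for i in range(n_atoms)}
    return TokenSequence(types, atom_map, tuple(scl_values) if scl_values is not None else None)


# -- corruption / sampling schemes ----------------------------------------


def mask_atoms(element_ids: np.ndarray, vocab: ElementVocab, rate: float = 0.15,
               seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Select ``max(1, round(rate·n))`` atoms (round half up) uniformly
    without replacement and corrupt them: 80% → MASK identity, 10% → a
    random *other* element, 10% unchanged (drawn i.i.d. per atom).

    Returns (corrupted_ids, mask_flags, selected_positions, true_ids);
    mask_flags marks MASK-identity atoms so the graph embedder hides them.
    """
    element_ids = np.asarray(element_ids)
    n = len(element_ids)
    if n < 1:
        raise ValueError("need at least one atom")
    rng = np.random.default_rng(seed)
    m = max(1, int(math.floor(rate * n + 0.5)))
    selected = np.sort(rng.choice(n, size=m, replace=False))
    corrupted = element_ids.copy()
    n_elements = len(vocab.symbols)
    for pos in selected:
        u = rng.random()
        if u < 0.8:
            corrupted[pos] = vocab.mask_id
        elif u < 0.9 and n_elements > 1:
            others = [e for e in range(n_elements) if e != element_ids[pos]]
            corrupted[pos] = others[rng.integers(len(others))]
        # else: left unchanged
    mask_flags = corrupted == vocab.mask_id
    return corrupted, mask_flags, selected, element_ids[selected]


def sample_pairs(molecule_ids: np.ndarray, n_pairs: int = 200, seed: int = 0):
    """Sample ``n_pairs/2`` intra-molecule and ``n_pairs/2`` inter-molecule
    atom pairs uniformly with replacement (i ≠ j within a pair).

    Returns (pairs (n_pairs, 2), flags (n_pairs,)) or the APC_DISABLED
    sentinel when the cell has a single molecule (or no multi-atom
    molecule), in which case the APC loss contributes zero.
    """
    mol = np.asarray(molecule_ids)
    if len(mol) < 2:
        raise ValueError("need at least two atoms")
    rng = np.random.default_rng(seed)
    groups: dict[int, np.ndarray] = {m: np.nonzero(mol == m)[0] for m in np.unique(mol)}
    multi = [g for g in groups.values() if len(g) >= 2]
    if len(groups) < 2 or not multi:
        return APC_DISABLED
    half = n_pairs // 2
    intra = np.empty((half, 2), dtype=int)
    for row in range(half):
        g = multi[rng.integers(len(multi))]
        i, j = rng.choice(len(g), size=2, replace=False)
        intra[row] = g[i], g[j]
    inter = np.empty((half, 2), dtype=int)
    mols = list(groups.keys())
    for row in range(half):
        a, b = rng.choice(len(mols), size=2, replace=False)
        inter[row] = (groups[mols[a]][rng.integers(len(groups[mols[a]]))],
                      groups[mols[b]][rng.integers(len(groups[mols[b]]))])
    pairs = np.concatenate([intra, inter])
    flags = np.concatenate([np.ones(half), np.zeros(half)])
    return pairs, flags


# -- transformer encoder ----------------------------------------------------


class TransformerLayer(nn.Module):
    """Pre-norm multi-head self-attention + feed-forward block."""

    def __init__(self, hidden: int, heads: int, ff_mult: int, rng):
        self.hidden = hidden
        self.heads = heads
        self.dk = hidden // heads
        self.qkv = nn.Linear(hidden, 3 * hidden, rng)
        self.out = nn.Linear(hidden, hidden, rng)
        self.ff1 = nn.Linear(hidden, ff_mult * hidden, rng)
        self.ff2 = nn.Linear(ff_mult * hidden, hidden, rng)
        self.ln1 = nn.LayerNorm(hidden)
        self.ln2 = nn.LayerNorm(hidden)

    def __call__(self, x: nn.Tensor, additive_mask: np.ndarray | None,
                 collect: list | None = None) -> nn.Tensor:
        B, T, H = x.shape
        qkv = self.qkv(self.ln1(x))                         # (B, T, 3H)
        qkv = qkv.reshape(B, T, 3, self.heads, self.dk).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]                    # (B, A, T, dk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dk))
        attn = nn.softmax(scores, axis=-1, additive_mask=additive_mask)
        if collect is not None:
            collect.append(attn.data.copy())
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, H)
        x = x + self.out(ctx)
        x = x + self.ff2(nn.gelu(self.ff1(self.ln2(x))))
        return x


class CrystalTransformer(nn.Module):
    """The full multi-modal model: graph embedder, token projections,
    encoder stack and all prediction heads."""

    def __init__(self, cfg: ModelConfig, vocab: ElementVocab, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.vocab = vocab
        H, gw = cfg.hidden, cfg.graph_width
        self.embedder = GraphEmbedder(vocab, gw, cfg.graph_layers, rng)
        if cfg.positional_mode == "relative":
            self.pos_proj = nn.Linear((cfg.knn_k + 4 * cfg.n_anchors) * 16, gw, rng)
        else:
            self.pos_tables = [nn.Embedding(cfg.position_bins, gw, rng) for _ in range(3)]
        self.atom_proj = nn.Linear(2 * gw, H, rng)
        self.patch_proj = nn.Linear(cfg.patch ** 2, H, rng)
        # where a patch sits in the image encodes its (birth, persistence)
        # coordinates — without this the encoder sees an unordered bag
        self.patch_pos_embed = nn.Embedding(cfg.n_patches, H, rng)
        self.scl_proj = nn.Linear(1, H, rng)
        self.cls_vec = nn.Parameter(rng.normal(0, 0.02, size=H))
        self.sep_vec = nn.Parameter(rng.normal(0, 0.02, size=H))
        self.type_embed = nn.Embedding(len(TOKEN_TYPES), H, rng)
        self.layers = [TransformerLayer(H, cfg.heads, cfg.ff_mult, rng)
                       for _ in range(cfg.layers)]
        self.final_norm = nn.LayerNorm(H)
        self.map_head = nn.Linear(H, len(vocab.symbols), rng)
        self.apc_g1 = nn.Linear(2 * H, H, rng)
        self.apc_g2 = nn.Linear(H, 1, rng)
        self.cdp_head = nn.Linear(H, 1, rng)
        self.sep_head = nn.Linear(H, 7, rng)
        self.reg_head = nn.Linear(H, 1, rng)  # fine-tuning head (reinitialised per task)

    # -- token assembly ----------------------------------------------------

    def _positional(self, feats: list[dict]) -> nn.Tensor:
        if self.cfg.positional_mode == "relative":
            raw = np.concatenate([f["pos_feats"] for f in feats])
            return self.pos_proj(nn.Tensor(raw))
        bins = np.concatenate([f["pos_bins"] for f in feats])
        out = self.pos_tables[0](bins[:, 0])
        for axis in (1, 2):
            out = out + self.pos_tables[axis](bins[:, axis])
        return out

    def build_batch(self, feats: list[dict]):
        """Assemble padded token tensors for a batch of structure feature
        dicts (keys: element_ids, graph, pos_feats|pos_bins, patches_1d,
        patches_2d, scl)."""
        cfg = self.cfg
        B = len(feats)
        n_atoms = [len(f["element_ids"]) for f in feats]
        layouts = [token_layout(n, cfg, f.get("scl")) for n, f in zip(n_atoms, feats)]
        T = max(l.length for l in layouts)

        ids = np.concatenate([f["element_ids"] for f in feats])
        graphs = [f["graph"] for f in feats]
        h_atoms = self.embedder(ids, graphs)
        # concatenate the two per-atom blocks so neither modality is
        # attenuated by summation before the shared projection
        h_atoms = self.atom_proj(nn.concat([h_atoms, self._positional(feats)],
                                           axis=1))

        bi_atom = np.concatenate([np.full(n, b) for b, n in enumerate(n_atoms)])
        ti_atom = np.concatenate([1 + np.arange(n) for n in n_atoms])
        x = nn.scatter_rows(h_atoms, (bi_atom, ti_atom), (B, T, cfg.hidden))

        type_ids = np.zeros((B, T), dtype=int)
        pad_mask = np.full((B, 1, 1, T), -1e9, dtype=np.float32)
        cls_rows, sep_rows = [], []
        patch_payload, patch_rows = [], []
        scl_payload, scl_rows = [], []
        for b, (layout, f) in enumerate(zip(layouts, feats)):
            pad_mask[b, :, :, :layout.length] = 0.0
            for p, t in enumerate(layout.token_types):
                type_ids[b, p] = TOKEN_TYPES.index(t)
            cls_rows.append((b, 0))
            for p in layout.positions("SEP"):
                sep_rows.append((b, p))
            if cfg.use_images:
                for p, patch in zip(layout.positions("PATCH1D"), f["patches_1d"]):
                    patch_rows.append((b, p))
                    patch_payload.append(patch)
                for p, patch in zip(layout.positions("PATCH2D"), f["patches_2d"]):
                    patch_rows.append((b, p))
                    patch_payload.append(patch)
                for p, val in zip(layout.positions("SCL"), f["scl"]):
                    scl_rows.append((b, p))
                    scl_payload.append([val])

        def place(rows, payload: nn.Tensor):
            bi = np.array([r[0] for r in rows])
            ti = np.array([r[1] for r in rows])
            return nn.scatter_rows(payload, (bi, ti), (B, T, cfg.hidden))

        cls_tile = nn.stack([self.cls_vec] * B, axis=0)
        x = x + place(cls_rows, cls_tile)
        x = x + place(sep_rows, nn.stack([self.sep_vec] * len(sep_rows), axis=0))
        if cfg.use_images and patch_rows:
            # unit-mass rasterization leaves pixel values ~1/resolution²;
            # rescale so patch tokens enter at the same order of magnitude
            # as atom tokens instead of being drowned by type embeddings
            payload = np.array(patch_payload) * float(cfg.resolution)
            # patch index within its own image (both images share tables;
            # the token-type embedding separates the 1D and 2D channels)
            per_struct = 2 * cfg.n_patches
            patch_pos = np.array([i % per_struct % cfg.n_patches
                                  for i in range(len(patch_rows))])
            patch_tok = self.patch_proj(nn.Tensor(payload)) + \
                self.patch_pos_embed(patch_pos)
            x = x + place(patch_rows, patch_tok)
            x = x + place(scl_rows, self.scl_proj(nn.Tensor(np.array(scl_payload))))
        x = x + self.type_embed(type_ids)
        return x, type_ids, pad_mask, layouts

    def encode(self, x: nn.Tensor, pad_mask: np.ndarray,
               collect_attention: bool = False):
        """Run the encoder stack; optionally retain per-layer attention
        tensors (list of (B, A, T, T) arrays)."""
        attns: list[np.ndarray] | None = [] if collect_attention else None
        for layer in self.layers:
            x = layer(x, pad_mask, collect=attns)
        return self.final_norm(x), attns

    def forward(self, feats: list[dict], collect_attention: bool = False):
        x, type_ids, pad_mask, layouts = self.build_batch(feats)
        reps, attns = self.encode(x, pad_mask, collect_attention)
        return reps, layouts, attns

    # -- heads -------------------------------------------------------------

    def apc_logit(self, h_i: nn.Tensor, h_j: nn.Tensor) -> nn.Tensor:
        """Order-symmetric same-molecule logit:
        g([h_i;h_j]) + g([h_j;h_i]) with one shared two-layer head g."""
        def g(a, b):
            return self.apc_g2(nn.gelu(self.apc_g1(nn.concat([a, b], axis=-1))))
        return g(h_i, h_j) + g(h_j, h_i)


# -- losses ----------------------------------------------------------------


def cross_entropy(logits: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    """Mean softmax cross-entropy (logits (M, V), integer labels (M,))."""
    labels = np.asarray(labels)
    shift = logits.data.max(axis=1, keepdims=True)
    z = logits - shift
    lse = z.exp().sum(axis=1).log()
    picked = z[np.arange(len(labels)), labels]
    return (lse - picked).mean()


def bce_with_logits(logits: nn.Tensor, targets: np.ndarray,
                    weights: np.ndarray | None = None) -> nn.Tensor:
    """Mean binary cross-entropy on logits, with optional per-component
    multiplicative weights."""
    p = nn.sigmoid(logits)
    t = np.asarray(targets, dtype=np.float32)
    eps = 1e-7
    terms = -(t * (p + eps).log() + (1.0 - t) * (1.0 - p + eps).log())
    if weights is not None:
        terms = terms * np.asarray(weights, dtype=np.float32)
    return terms.mean()


def weighted_sep_loss(logits: nn.Tensor, bits: np.ndarray,
                      weights: np.ndarray) -> nn.Tensor:
    """SEP loss: per-element BCE, element i's term scaled by w_i."""
    weights = np.asarray(weights, dtype=np.float32)
    if weights.shape[-1] != 7:
        raise ValueError("SEP weight vector must have length 7")
    return bce_with_logits(logits, bits, weights)


def pretrain_loss(task_losses: dict[str, nn.Tensor | None],
                  task_weights: dict[str, float] | None = None) -> nn.Tensor:
    """Total pre-training loss: unit-weighted sum of the four task losses;
    a disabled task (None) contributes zero."""
    task_weights = task_weights or {}
    total = None
    for name in ("map", "apc", "cdp", "sep"):
        loss = task_losses.get(name)
        if loss is None:
            continue
        w = task_weights.get(name, 1.0)
        term = loss * w
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no task losses provided")
    return total


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(model: CrystalTransformer, path: str | Path,
                    featurization_hash: str, extra: dict | None = None) -> None:
    """Single-file checkpoint: weights + config + vocabulary + symmetry bit
    order + featurization hash (refused on mismatch at load)."""
    meta = {
        "config": model.cfg.to_dict(),
        "vocab": model.vocab.symbols,
        "symmetry_bit_order": list(ELEMENT_NAMES),
        "featurization_hash": featurization_hash,
        "extra": extra or {},
    }
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(Path(path), meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path,
                    expected_hash: str | None = None) -> tuple[CrystalTransformer, dict]:
    z = np.load(Path(path))
    meta = json.loads(bytes(z["meta"]).decode())
    if list(meta["symmetry_bit_order"]) != list(ELEMENT_NAMES):
        raise ValueError("checkpoint symmetry bit order does not match this build")
    if expected_hash is not None and meta["featurization_hash"] != expected_hash:
        raise ValueError(
            f"featurization hash mismatch: checkpoint {meta['featurization_hash']}, "
            f"expected {expected_hash}")
    cfg = ModelConfig(**meta["config"])
    vocab = ElementVocab(meta["vocab"])
    model = CrystalTransformer(cfg, vocab, seed=0)
    arrays = [z[f"p{i}"] for i in range(len([k for k in z.files if k.startswith("p")]))]
    model.load_state_arrays(arrays)
    return model, meta
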