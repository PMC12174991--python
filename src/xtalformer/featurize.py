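"""Per-atom features: periodic graph embeddings and positional embeddings.

The local modality of the model. Each atom enters the transformer as the
concatenation (projected to the encoder width) of (a) a learned graph
embedding produced by edge-gated message passing on the periodic
interatomic graph interleaved with line-graph (bond-angle) updates, and
(b) a positional embedding.

Two positional schemes are provided:

* relative (default): the structure is randomly perturbed (std ``sigma`` Å,
  fresh seed each epoch), then each atom's sorted periodic distances to its
  k nearest neighbours, plus its distances to a few randomly drawn shared
  anchor atoms, are expanded in a fixed radial basis. Everything is built
  from interatomic distances, so the embedding is invariant under rigid
  rotation and translation; the perturbation and per-epoch anchors
  regularise training and break the exact degeneracy between
  symmetry-equivalent atoms (without which molecule-membership questions
  would be unanswerable in Z′=1 cells).
* absolute (ablation): each fractional coordinate is discretised into bins
  and looked up in a per-axis embedding table, summed over axes. This
  deliberately violates translational invariance — it exists to quantify
  how much that costs.

Masking contract: an atom whose element is hidden for the masked-atom task
enters the graph with a reserved MASK identity, so its element cannot leak
into any message it sends.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .data import COVALENT_RADII

__all__ = [
    "AtomGraph",
    "build_graph",
    "GraphEmbedder",
    "ElementVocab",
    "relative_positional",
    "radial_basis",
    "absolute_position_bins",
    "atom_graph_embed",
]

MASK_TOKEN = "[MASK]"


class ElementVocab:
    """Element-symbol vocabulary with a reserved MASK identity."""

    def __init__(self, elements: list[str]):
        self.symbols = sorted(set(elements))
        self.index = {el: i for i, el in enumerate(self.symbols)}
        self.mask_id = len(self.symbols)

    def __len__(self):  # embeddings allocate one extra row for MASK
        return len(self.symbols) + 1

    def encode(self, elements: list[str]) -> np.ndarray:
        try:
            return np.array([self.index[e] for e in elements], dtype=int)
        except KeyError as exc:
            raise ValueError(f"element {exc.args[0]!r} not in training vocabulary") from exc

    def decode(self, ids) -> list[str]:
        return [self.symbols[i] for i in ids]


@dataclasses.dataclass
class AtomGraph:
    """Periodic interatomic graph of one structure.

    edges are directed (src → dst); ``distances`` in Å. Triplets pair the
    ``line_k`` shortest incident edges of each atom and carry the cosine of
    the angle between the two bond vectors at the shared atom.
    """

    n_atoms: int
    edge_src: np.ndarray
    edge_dst: np.ndarray
    distances: np.ndarray
    triplet_e1: np.ndarray
    triplet_e2: np.ndarray
    cos_angles: np.ndarray


def _periodic_vectors(s, max_shift: np.ndarray):
    """All image vectors r_j + L·n − r_i for |n_i| ≤ max_shift_i."""
    shifts = np.array([[i, j, k]
                       for i in range(-max_shift[0], max_shift[0] + 1)
                       for j in range(-max_shift[1], max_shift[1] + 1)
                       for k in range(-max_shift[2], max_shift[2] + 1)], dtype=float)
    return shifts


def build_graph(s, k_neighbors: int = 8, cutoff: float = 8.0,
                radius_scale: float = 1.2, line_k: int = 6) -> AtomGraph:
    """Periodic interatomic graph: union of the covalent bond graph
    (minimum-image distance ≤ radius_scale × covalent-radius sum) and each
    atom's ``k_neighbors`` nearest periodic neighbours within ``cutoff`` Å.

    Periodic images are enumerated far enough that no neighbour within
    ``cutoff`` is missed even for small cells; an atom can bond to several
    images of the same partner.
    """
    from .topology import perpendicular_widths

    n = s.n_atoms
    widths = perpendicular_widths(s.lattice)
    max_shift = np.maximum(1, np.ceil(cutoff / widths).astype(int))
    shifts = _periodic_vectors(s, max_shift)
    cart_shifts = shifts @ s.lattice                      # (S, 3)
    cart = s.cart_coords
    radii = np.array([COVALENT_RADII[el] for el in s.elements])

    src, dst, vecs = [], [], []
    for i in range(n):
        delta = cart[None, :, :] + cart_shifts[:, None, :] - cart[i]  # (S, n, 3)
        d2 = np.einsum("snj,snj->sn", delta, delta)
        flat = d2.ravel()
        self_mask = flat < 1e-12
        flat_idx = np.argsort(flat)
        chosen: list[int] = []
        bond_cut2 = (radius_scale * (radii[i] + radii)) ** 2
        # covalent bonds (any image)
        bond_sel = np.nonzero((d2 <= bond_cut2[None, :]) & (d2 > 1e-12))
        bond_flat = set(bond_sel[0] * n + bond_sel[1])
        for fi in flat_idx:
            if self_mask[fi]:
                continue
            if flat[fi] > cutoff ** 2 and fi not in bond_flat:
                break
            if len(chosen) >= k_neighbors and fi not in bond_flat:
                continue
            chosen.append(fi)
        for fi in sorted(set(chosen)):
            s_i, j = divmod(fi, n)
            src.append(i)
            dst.append(j)
            vecs.append(delta.reshape(-1, 3)[fi])
    src = np.array(src, dtype=int)
    dst = np.array(dst, dtype=int)
    vecs = np.array(vecs, dtype=float).reshape(-1, 3)
    dists = np.linalg.norm(vecs, axis=1)

    # line-graph triplets: pair the line_k shortest incident edges per atom
    t1, t2, cosines = [], [], []
    for i in range(n):
        incident = np.nonzero(src == i)[0]
        incident = incident[np.argsort(dists[incident])][:line_k]
        for a in range(len(incident)):
            for b in range(len(incident)):
                if a == b:
                    continue
                e1, e2 = incident[a], incident[b]
                c = np.dot(vecs[e1], vecs[e2]) / (dists[e1] * dists[e2])
                t1.append(e1)
                t2.append(e2)
                cosines.append(np.clip(c, -1.0, 1.0))
    return AtomGraph(n, src, dst, dists,
                     np.array(t1, dtype=int), np.array(t2, dtype=int),
                     np.array(cosines, dtype=float))


def radial_basis(values: np.ndarray, n_basis: int = 16,
                 low: float = 0.0, high: float = 8.0) -> np.ndarray:
    """Gaussian radial basis expansion with fixed, evenly spaced centers."""
    centers = np.linspace(low, high, n_basis)
    width = (high - low) / (n_basis - 1)
    return np.exp(-((np.asarray(values)[..., None] - centers) ** 2) / (2 * width ** 2))


class GraphEmbedder(nn.Module):
    """Edge-gated message passing on the periodic interatomic graph with
    line-graph angle updates; returns one vector per atom.

    Batched: atoms/edges/triplets of several structures are concatenated
    with index offsets before the call.
    """

    N_RBF = 16
    N_ANGLE = 16

    def __init__(self, vocab: ElementVocab, width: int = 256, layers: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.vocab = vocab
        self.width = width
        self.n_layers = layers
        self.element_embed = nn.Embedding(len(vocab), width, rng)
        self.edge_init = nn.Linear(self.N_RBF, width, rng)
        self.angle_mlp = [nn.Linear(2 * width + self.N_ANGLE, width, rng) for _ in range(layers)]
        self.edge_mlp = [nn.Linear(2 * width, width, rng) for _ in range(layers)]
        self.gate_mlp = [nn.Linear(3 * width, width, rng) for _ in range(layers)]
        self.msg_mlp = [nn.Linear(3 * width, width, rng) for _ in range(layers)]
        self.node_mlp = [nn.Linear(2 * width, width, rng) for _ in range(layers)]
        self.node_norm = [nn.LayerNorm(width) for _ in range(layers)]
        self.edge_norm = [nn.LayerNorm(width) for _ in range(layers)]

    def __call__(self, element_ids: np.ndarray, graphs: list[AtomGraph]) -> nn.Tensor:
        """element_ids: concatenated per-atom vocabulary ids (MASK already
        applied where hidden); graphs: matching AtomGraph per structure."""
        n_total = len(element_ids)
        src_l, dst_l, dist_l, t1_l, t2_l, cos_l = [], [], [], [], [], []
        a_off = e_off = 0
        for g in graphs:
            src_l.append(g.edge_src + a_off)
            dst_l.append(g.edge_dst + a_off)
            dist_l.append(g.distances)
            t1_l.append(g.triplet_e1 + e_off)
            t2_l.append(g.triplet_e2 + e_off)
            cos_l.append(g.cos_angles)
            a_off += g.n_atoms
            e_off += len(g.edge_src)
        src = np.concatenate(src_l)
        dst = np.concatenate(dst_l)
        dists = np.concatenate(dist_l)
        t1 = np.concatenate(t1_l)
        t2 = np.concatenate(t2_l)
        cosines = np.concatenate(cos_l)
        n_edges = len(src)

        h = self.element_embed(element_ids)
        e = self.edge_init(nn.Tensor(radial_basis(dists, self.N_RBF)))
        angle_feat = radial_basis(cosines, self.N_ANGLE, low=-1.0, high=1.0)

        for layer in range(self.n_layers):
            if len(t1):
                tin = nn.concat([nn.gather_rows(e, t1), nn.gather_rows(e, t2),
                                 nn.Tensor(angle_feat)], axis=1)
                tmsg = nn.gelu(self.angle_mlp[layer](tin))
                agg_t = nn.segment_sum(tmsg, t1, n_edges)
            else:
                agg_t = nn.Tensor(np.zeros((n_edges, self.width)))
            e = self.edge_norm[layer](e + self.edge_mlp[layer](nn.concat([e, agg_t], axis=1)))

            hi = nn.gather_rows(h, src)
            hj = nn.gather_rows(h, dst)
            ein = nn.concat([hi, hj, e], axis=1)
            msg = nn.sigmoid(self.gate_mlp[layer](ein)) * nn.gelu(self.msg_mlp[layer](ein))
            agg = nn.segment_sum(msg, src, n_total)
            h = self.node_norm[layer](h + self.node_mlp[layer](nn.concat([h, agg], axis=1)))
        return h


def relative_positional(s, sigma: float = 0.05, k: int = 8,
                        seed: int = 0, n_basis: int = 16,
                        n_anchors: int = 8) -> np.ndarray:
    """Rotation/translation-invariant positional features from the randomly
    perturbed structure.

    Two distance blocks per atom, both expanded in the fixed radial basis:

    * sorted periodic distances to the atom's k nearest neighbours — the
      local radial environment;
    * the ``n_images`` shortest periodic-image distances to each of
      ``n_anchors`` randomly chosen anchor atoms (the same anchors for
      every atom, redrawn with the seed). Distances to shared reference
      points let the encoder reason about which atoms are mutually close —
      information the unordered k-NN lists cannot carry, and without which
      symmetry-equivalent atoms in a Z′=1 cell would be exactly
      indistinguishable; the deeper image shells additionally encode the
      cell geometry (|a±b| and friends), which carries crystal-system
      information.

    Deterministic given ``seed`` (which draws both the Gaussian
    perturbation of std ``sigma`` Å and the anchors); re-invoked with a
    fresh seed each training epoch. Returns (N, (k + n_anchors)·n_basis).
    """
    from .crystal_io import perturb
    from .topology import perpendicular_widths

    if k < 1:
        raise ValueError("k must be >= 1")
    n_images = 4
    sp = perturb(s, sigma, seed)
    # enumerate periodic images far enough that the k nearest are exact
    widths = perpendicular_widths(sp.lattice)
    max_shift = np.maximum(1, np.ceil(8.0 / widths).astype(int))
    shifts = _periodic_vectors(sp, max_shift) @ sp.lattice
    cart = sp.cart_coords
    n = sp.n_atoms
    feats = np.zeros((n, (k + n_images * n_anchors) * n_basis))
    anchor_rng = np.random.default_rng(seed + 104729)
    anchors = anchor_rng.integers(0, n, size=n_anchors) if n_anchors else []
    for i in range(n):
        delta = cart[None, :, :] + shifts[:, None, :] - cart[i]
        dists = np.sqrt(np.einsum("snj,snj->sn", delta, delta))  # (S, n)
        d = np.sort(dists.ravel()[dists.ravel() > 1e-9])[:k]
        if len(d) < k:
            d = np.concatenate([d, np.full(k - len(d), 8.0)])
        row = [radial_basis(d, n_basis).ravel()]
        for a in anchors:
            da = np.sort(dists[:, a][dists[:, a] > 1e-9])[:n_images]
            if len(da) < n_images:
                da = np.concatenate([da, np.full(n_images - len(da), 8.0)])
            row.append(radial_basis(da, n_basis).ravel())
        feats[i] = np.concatenate(row)
    return feats


def absolute_position_bins(s, bins: int = 100) -> np.ndarray:
    """Discretise fractional coordinates into per-axis bins (ablation mode)."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    return np.minimum((s.frac_coords * bins).astype(int), bins - 1)


def atom_graph_embed(s, embedder: GraphEmbedder,
                     mask_flags: np.ndarray | None = None,
                     graph: AtomGraph | None = None) -> nn.Tensor:
    """Per-atom graph embeddings of one structure; atoms with
    ``mask_flags`` true enter with the reserved MASK identity."""
    ids = embedder.vocab.encode(s.elements)
    if mask_flags is not None:
        ids = np.where(np.asarray(mask_flags, dtype=bool), embedder.vocab.mask_id, ids)
    if graph is None:
        graph = build_graph(s)
    return embedder(ids, [graph])
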