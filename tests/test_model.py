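"""Token layout, corruption/sampling schemes, heads and encoder contracts."""

import numpy as np
import pytest

from xtalformer import nn
from xtalformer.featurize import ElementVocab
from xtalformer.model import (APC_DISABLED, CrystalTransformer, ModelConfig,
                              bce_with_logits, cross_entropy, load_checkpoint,
                              mask_atoms, pretrain_loss, sample_pairs,
                              save_checkpoint, token_layout,
                              weighted_sep_loss)

VOCAB = ElementVocab(["C", "H", "N", "O"])


def small_config(**over):
    base = dict(layers=2, hidden=32, heads=2, graph_width=32, graph_layers=1,
                resolution=20, patch=5, ff_mult=2)
    base.update(over)
    return ModelConfig(**base)


class TestTokenLayout:
    def test_default_counts_with_images(self):
        cfg = ModelConfig()  # resolution 50, patch 5 → 100 patches per image
        layout = token_layout(10, cfg)
        counts = {t: layout.token_types.count(t) for t in set(layout.token_types)}
        assert counts == {"CLS": 1, "ATOM": 10, "SEP": 2,
                          "PATCH1D": 100, "PATCH2D": 100, "SCL": 4}
        assert layout.length == 10 + 207

    def test_layout_order(self):
        cfg = ModelConfig()
        t = token_layout(3, cfg).token_types
        assert t[:5] == ["CLS", "ATOM", "ATOM", "ATOM", "SEP"]
        assert t[5:105] == ["PATCH1D"] * 100
        assert t[105:108] == ["SCL", "SCL", "SEP"]
        assert t[108:208] == ["PATCH2D"] * 100
        assert t[208:] == ["SCL", "SCL"]

    def test_images_off_ends_after_first_sep(self):
        cfg = ModelConfig(use_images=False)
        layout = token_layout(7, cfg)
        assert layout.token_types == ["CLS"] + ["ATOM"] * 7 + ["SEP"]

    def test_atom_map_bijective(self):
        layout = token_layout(12, ModelConfig())
        assert sorted(layout.atom_index_map.values()) == list(range(12))
        assert all(layout.token_types[p] == "ATOM" for p in layout.atom_index_map)

    def test_max_atoms_hard_error(self):
        with pytest.raises(ValueError):
            token_layout(513, ModelConfig())


class TestMaskAtoms:
    def test_count_rounding(self):
        ids = np.zeros(20, dtype=int)
        _, _, selected, _ = mask_atoms(ids, VOCAB, 0.15, seed=0)
        assert len(selected) == 3  # round(0.15 · 20)

    def test_floor_one(self):
        ids = np.zeros(2, dtype=int)
        _, _, selected, _ = mask_atoms(ids, VOCAB, 0.15, seed=0)
        assert len(selected) == 1

    def test_selection_fraction(self):
        ids = np.zeros(600, dtype=int)
        fractions = [len(mask_atoms(ids, VOCAB, 0.15, seed=s)[2]) / 600
                     for s in range(200)]
        assert np.mean(fractions) == pytest.approx(0.15, abs=0.01)

    def test_corruption_mode_proportions(self):
        """80/10/10 replacement draws within 3 binomial σ over 10⁴ picks."""
        rng_ids = np.random.default_rng(0).integers(0, 4, size=100)
        n_mask = n_random = n_keep = total = 0
        seed = 0
        while total < 10_000:
            corrupted, flags, selected, truth = mask_atoms(rng_ids, VOCAB, 0.15,
                                                           seed=seed)
            for pos in selected:
                total += 1
                if corrupted[pos] == VOCAB.mask_id:
                    n_mask += 1
                elif corrupted[pos] != rng_ids[pos]:
                    n_random += 1
                else:
                    n_keep += 1
            seed += 1
        for count, p in ((n_mask, 0.8), (n_random, 0.1), (n_keep, 0.1)):
            sigma = np.sqrt(total * p * (1 - p))
            assert abs(count - total * p) < 3 * sigma

    def test_labels_record_truth(self):
        ids = np.array([0, 1, 2, 3, 0, 1, 2])
        corrupted, flags, selected, truth = mask_atoms(ids, VOCAB, 0.5, seed=3)
        assert np.array_equal(truth, ids[selected])
        assert np.array_equal(flags, corrupted == VOCAB.mask_id)


class TestSamplePairs:
    def test_balanced_counts(self, two_molecule_ids):
        pairs, flags = sample_pairs(two_molecule_ids, 200, seed=0)
        assert len(pairs) == 200
        assert flags.sum() == 100 and (1 - flags).sum() == 100
        mol = two_molecule_ids
        for (i, j), f in zip(pairs, flags):
            assert i != j
            assert (mol[i] == mol[j]) == bool(f)

    def test_single_molecule_sentinel(self):
        assert sample_pairs(np.zeros(10, dtype=int), 200, seed=0) is APC_DISABLED

    def test_seed_reproducible(self, two_molecule_ids):
        a = sample_pairs(two_molecule_ids, 200, seed=5)
        b = sample_pairs(two_molecule_ids, 200, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestHeads:
    def _model(self):
        return CrystalTransformer(small_config(), VOCAB, seed=0)

    def test_apc_head_exactly_symmetric(self):
        model = self._model()
        rng = np.random.default_rng(1)
        a = nn.Tensor(rng.normal(size=(5, 32)))
        b = nn.Tensor(rng.normal(size=(5, 32)))
        ab = model.apc_logit(a, b).data
        ba = model.apc_logit(b, a).data
        assert np.array_equal(ab, ba)

    def test_apc_equal_args(self):
        model = self._model()
        a = nn.Tensor(np.random.default_rng(2).normal(size=(1, 32)))
        def g(x, y):
            return model.apc_g2(nn.gelu(model.apc_g1(nn.concat([x, y], axis=-1))))
        assert model.apc_logit(a, a).data == pytest.approx(2 * g(a, a).data)

    def test_cdp_head_affine(self):
        model = self._model()
        model.cdp_head.W.data[:] = 0.0
        model.cdp_head.b.data[:] = 1.25
        out = model.cdp_head(nn.Tensor(np.random.normal(size=(4, 32))))
        assert np.allclose(out.data, 1.25)

    def test_sep_loss_uniform_weights_is_plain_bce(self):
        logits = nn.Tensor(np.random.default_rng(0).normal(size=(3, 7)))
        bits = np.random.default_rng(1).integers(0, 2, size=(3, 7))
        assert weighted_sep_loss(logits, bits, np.ones(7)).item() == \
            pytest.approx(bce_with_logits(logits, bits).item())

    def test_sep_loss_perfect_prediction(self):
        bits = np.array([[1, 0, 0, 0, 1, 0, 1.0]])
        logits = nn.Tensor((2 * bits - 1) * 30.0)
        assert weighted_sep_loss(logits, bits, np.ones(7)).item() < 1e-4

    def test_sep_weight_scales_gradient(self):
        rng = np.random.default_rng(0)
        logits_data = rng.normal(size=(2, 7)).astype(np.float32)
        bits = rng.integers(0, 2, size=(2, 7)).astype(float)
        grads = []
        for wk in (1.0, 2.0):
            w = np.ones(7)
            w[3] = wk
            logits = nn.Tensor(logits_data.copy(), requires_grad=True)
            weighted_sep_loss(logits, bits, w).backward()
            grads.append(logits.grad[:, 3].copy())
        assert np.allclose(grads[1], 2 * grads[0], rtol=1e-4)

    def test_sep_weight_length_enforced(self):
        logits = nn.Tensor(np.zeros((1, 7)))
        with pytest.raises(ValueError):
            weighted_sep_loss(logits, np.zeros((1, 7)), np.ones(6))

    def test_pretrain_loss_sums_tasks(self):
        parts = {"map": nn.Tensor(1.5), "apc": nn.Tensor(0.5),
                 "cdp": nn.Tensor(2.0), "sep": nn.Tensor(0.25)}
        assert pretrain_loss(parts).item() == pytest.approx(4.25)
        parts["apc"] = None  # APC disabled
        assert pretrain_loss(parts).item() == pytest.approx(3.75)

    def test_cross_entropy_matches_manual(self):
        logits = nn.Tensor(np.array([[2.0, 0.0, -1.0]]))
        labels = np.array([0])
        z = np.array([2.0, 0.0, -1.0])
        expected = -(z[0] - np.log(np.exp(z).sum()))
        assert cross_entropy(logits, labels).item() == pytest.approx(expected, rel=1e-5)


class TestEncoder:
    def _inputs(self, model, n=3, seed=0):
        from xtalformer.crystal_io import CrystalStructure
        from xtalformer.featurize import build_graph, relative_positional
        rng = np.random.default_rng(seed)
        s = CrystalStructure(lattice=np.eye(3) * 10.0,
                             frac_coords=rng.uniform(0.1, 0.5, (n, 3)),
                             elements=["C"] * n)
        cfg = model.cfg
        return {
            "element_ids": model.vocab.encode(s.elements),
            "graph": build_graph(s, k_neighbors=cfg.knn_k),
            "pos_feats": relative_positional(s, 0.0, cfg.knn_k, seed=0,
                                             n_anchors=cfg.n_anchors),
            "patches_1d": np.zeros((cfg.n_patches, cfg.patch ** 2)),
            "patches_2d": np.zeros((cfg.n_patches, cfg.patch ** 2)),
            "scl": (0.5, 1.0, 0.2, 0.8),
        }

    def test_output_width_and_determinism(self):
        model = CrystalTransformer(small_config(), VOCAB, seed=0)
        inp = self._inputs(model)
        with nn.set_grad_enabled(False):
            a, layouts, _ = model.forward([inp])
            b, _, _ = model.forward([inp])
        assert a.shape == (1, layouts[0].length, 32)
        assert np.array_equal(a.data, b.data)

    def test_attention_rows_stochastic(self):
        model = CrystalTransformer(small_config(), VOCAB, seed=0)
        with nn.set_grad_enabled(False):
            _, layouts, attns = model.forward([self._inputs(model)],
                                              collect_attention=True)
        T = layouts[0].length
        for layer in attns:
            sums = layer[0, :, :T, :T].sum(axis=-1)
            assert np.allclose(sums, 1.0, atol=1e-5)

    def test_images_off_pure_atom_transformer(self):
        cfg = small_config(use_images=False)
        model = CrystalTransformer(cfg, VOCAB, seed=0)
        inp = self._inputs(model)
        inp["patches_1d"] = inp["patches_2d"] = np.zeros((0, 25))
        with nn.set_grad_enabled(False):
            reps, layouts, _ = model.forward([inp])
        assert layouts[0].token_types == ["CLS"] + ["ATOM"] * 3 + ["SEP"]


def test_checkpoint_roundtrip_and_hash_guard(tmp_path):
    model = CrystalTransformer(small_config(), VOCAB, seed=0)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path, featurization_hash="abc123")
    loaded, meta = load_checkpoint(path, expected_hash="abc123")
    assert all(np.array_equal(a, b) for a, b in
               zip(model.state_arrays(), loaded.state_arrays()))
    assert meta["vocab"] == VOCAB.symbols
    with pytest.raises(ValueError):
        load_checkpoint(path, expected_hash="other")


# -- property tests ---------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n=st.integers(1, 60), rate=st.floats(0.05, 0.5), seed=st.integers(0, 999))
def test_mask_count_property(n, rate, seed):
    """Selection count is max(1, round-half-up(rate·n)), without replacement."""
    ids = np.zeros(n, dtype=int)
    _, _, selected, _ = mask_atoms(ids, VOCAB, rate, seed=seed)
    import math
    assert len(selected) == max(1, int(math.floor(rate * n + 0.5)))
    assert len(set(selected)) == len(selected)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(sizes=st.lists(st.integers(2, 6), min_size=2, max_size=4),
       seed=st.integers(0, 999))
def test_sample_pairs_property(sizes, seed):
    """Balanced pair lists always respect molecule membership and i≠j."""
    mol = np.concatenate([np.full(k, i) for i, k in enumerate(sizes)])
    pairs, flags = sample_pairs(mol, 40, seed=seed)
    assert flags.sum() == 20
    for (i, j), f in zip(pairs, flags):
        assert i != j
        assert (mol[i] == mol[j]) == bool(f)
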