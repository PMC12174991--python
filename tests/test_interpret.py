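"""Attention rollout and attribution plumbing."""

import numpy as np
import pytest

from xtalformer.interpret import AttributionResult, attention_rollout


def _random_stochastic(rng, T):
    A = rng.random((T, T)) + 1e-3
    return A / A.sum(axis=1, keepdims=True)


class TestRollout:
    def test_identity_attention_returns_cls_onehot(self):
        for depth in (1, 3, 6):
            for alpha in (0.0, 0.5, 0.9):
                attns = [np.eye(5)] * depth
                row = attention_rollout(attns, residual_alpha=alpha)
                assert np.allclose(row, np.eye(5)[0])

    def test_two_layer_uniform_hand_product(self):
        attns = [np.full((2, 2), 0.5)] * 2
        row = attention_rollout(attns, residual_alpha=0.0)
        assert np.allclose(row, [0.5, 0.5])

    def test_output_row_stochastic(self):
        rng = np.random.default_rng(0)
        attns = [_random_stochastic(rng, 6) for _ in range(4)]
        row = attention_rollout(attns, residual_alpha=0.5)
        assert row.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(row >= 0)

    def test_matches_bruteforce_oracle(self):
        """Explicit residual-mixed matrix product, written out separately."""
        rng = np.random.default_rng(7)
        for T in (3, 5, 8):
            attns = [_random_stochastic(rng, T) for _ in range(3)]
            rolled = np.eye(T)
            for A in attns:
                M = 0.5 * np.eye(T) + 0.5 * A
                M = M / M.sum(axis=1, keepdims=True)
                rolled = M @ rolled
            expected = rolled[0]
            got = attention_rollout(attns, residual_alpha=0.5)
            assert np.allclose(got, expected, atol=1e-10)

    def test_head_average(self):
        rng = np.random.default_rng(1)
        heads = np.stack([_random_stochastic(rng, 4) for _ in range(3)])
        a = attention_rollout([heads], residual_alpha=0.0)
        b = attention_rollout([heads.mean(axis=0)], residual_alpha=0.0)
        assert np.allclose(a, b)

    def test_non_stochastic_rejected(self):
        bad = np.ones((3, 3))
        with pytest.raises(ValueError):
            attention_rollout([bad])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            attention_rollout([])


class TestAttributionResult:
    def _result(self):
        atom = np.array([0.3, 0.004, 0.1])
        p1 = np.full(10, 0.02)
        p2 = np.full(10, 0.03)
        scl = np.array([0.02, 0.02, 0.01, 0.046])
        total = atom.sum() + p1.sum() + p2.sum() + scl.sum()
        return AttributionResult(atom / total, p1 / total, p2 / total,
                                 scl / total)

    def test_scores_normalised(self):
        r = self._result()
        s = r.atom_scores.sum() + r.patch_scores_1d.sum() + \
            r.patch_scores_2d.sum() + r.scl_scores.sum()
        assert s == pytest.approx(1.0, abs=1e-6)

    def test_clipping_only_removes_below_floor(self):
        r = self._result()
        clipped = r.clipped_atom_scores()
        below = r.atom_scores < r.clip_threshold
        assert np.all(clipped[below] == 0)
        assert np.array_equal(clipped[~below], r.atom_scores[~below])

    def test_top_patches_sorted_descending(self):
        rng = np.random.default_rng(0)
        r = AttributionResult(np.array([0.1]), rng.random(20), rng.random(20),
                              np.zeros(4))
        top = r.top_patches("1d", 10)
        scores = r.patch_scores_1d[top]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert len(top) == 10


class TestPoreAttribution:
    """After fine-tuning on a channel-radius target (a purely geometric
    property carried by the persistence-image modality), rollout mass on
    image tokens should exceed their token-count share."""

    def test_image_share_exceeds_token_share(self):
        import pandas as pd
        from xtalformer.featurize import ElementVocab
        from xtalformer.finetune import PropertyDataset, finetune
        from xtalformer.fixtures import make_pore_series
        from xtalformer.interpret import attribute
        from xtalformer.model import CrystalTransformer, ModelConfig
        from xtalformer.training import prepare_features

        # rings of varying atom count at (nearly) fixed bond length: the
        # local atomic environment barely changes, so the channel radius is
        # carried by the global geometry rather than per-atom features
        import math
        data = []
        for i in range(24):
            n_ring = (8, 12, 16, 20)[i % 4]
            r = 1.5 / (2 * math.sin(math.pi / n_ring))
            data.extend(make_pore_series([r], seed=100 + i, n_ring=n_ring))
        cfg = ModelConfig(layers=2, hidden=32, heads=2, graph_width=32,
                          graph_layers=1, resolution=20, patch=5, ff_mult=2)
        vocab = ElementVocab(["C"])
        feats = prepare_features(data, vocab, cfg, min_extent=10.0)
        fbi = {s.structure_id: f for (s, _), f in zip(data, feats)}
        table = pd.DataFrame({
            "structure_id": [s.structure_id for s, _ in data],
            "label": [r["target"] for _, r in data]})
        ds = PropertyDataset(table, seed=0)
        model = CrystalTransformer(cfg, vocab, seed=0)
        model, _ = finetune(model, fbi, ds, seed=0, epochs=12, batch_size=8,
                            lr=1e-3)

        shares, token_shares = [], []
        for f in list(fbi.values())[:6]:
            result = attribute(model, f, seed=1)
            image_mass = (result.patch_scores_1d.sum()
                          + result.patch_scores_2d.sum()
                          + result.scl_scores.sum())
            n_atoms = len(result.atom_scores)
            n_image = (len(result.patch_scores_1d)
                       + len(result.patch_scores_2d) + 4)
            shares.append(image_mass)
            token_shares.append(n_image / (n_image + n_atoms))
        assert np.mean(shares) / np.mean(token_shares) > 1.0


def test_export_roundtrip(tmp_path):
    from xtalformer.crystal_io import CrystalStructure
    from xtalformer.interpret import export_attribution

    rng = np.random.default_rng(0)
    atom = rng.random(4)
    p1 = rng.random(16)
    p2 = rng.random(16)
    scl = rng.random(4)
    total = atom.sum() + p1.sum() + p2.sum() + scl.sum()
    result = AttributionResult(atom / total, p1 / total, p2 / total,
                               scl / total)
    s = CrystalStructure(lattice=np.eye(3) * 10,
                         frac_coords=rng.uniform(0, 1, (4, 3)),
                         elements=["C", "N", "O", "H"])
    paths = export_attribution(result, s, tmp_path / "attr")
    z = np.load(paths["patches"])
    assert np.allclose(z["patch_scores_1d"].ravel(), result.patch_scores_1d)
    import json
    payload = json.loads(paths["summary"].read_text())
    top = payload["top10_patches_1d"]
    scores = result.patch_scores_1d[top]
    assert all(a >= b for a, b in zip(scores, scores[1:]))
    # per-atom column appears once per atom in the XYZ export
    lines = paths["xyz"].read_text().strip().splitlines()
    assert len(lines) == 2 + 4
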