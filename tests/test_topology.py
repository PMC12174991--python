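"""Persistent homology: filtration correctness, images, patches, cycles.

The correctness oracle is a brute-force Čech filtration (minimum enclosing
sphere radius over every ≤ 3-simplex) with its own naive boundary-matrix
reduction, implemented here from scratch: Čech and alpha filtrations both
describe the growing union of balls, so their persistence diagrams must
coincide exactly.
"""

import itertools
import math

import numpy as np
import pytest

from xtalformer.crystal_io import CrystalStructure
from xtalformer.topology import (PersistenceDiagram, map_cycle_to_atoms,
                                 patchify, periodic_point_cloud,
                                 perpendicular_widths, persistence_diagrams,
                                 persistence_image, unpatchify)


# -- independent Čech oracle ----------------------------------------------


def _meb_radius(pts: np.ndarray) -> float:
    """Minimum enclosing ball radius of ≤ 4 points (exact, brute force)."""
    best = None
    for k in range(1, len(pts) + 1):
        for sub in itertools.combinations(range(len(pts)), k):
            P = pts[list(sub)]
            V = P[1:] - P[0]
            if len(V):
                G = V @ V.T
                if abs(np.linalg.det(G)) < 1e-14:
                    continue
                y = np.linalg.solve(G, 0.5 * np.diag(G))
                c = P[0] + V.T @ y
            else:
                c = P[0]
            r2 = float(np.sum((P[0] - c) ** 2))
            if np.max(np.sum((pts - c) ** 2, axis=1)) <= r2 + 1e-12:
                if best is None or r2 < best:
                    best = r2
    return math.sqrt(best)


def _cech_diagrams(pts: np.ndarray) -> dict[int, np.ndarray]:
    simplices = []
    for k in range(1, 5):
        for sub in itertools.combinations(range(len(pts)), k):
            r = 0.0 if k == 1 else _meb_radius(pts[list(sub)])
            simplices.append((sub, r))
    simplices.sort(key=lambda s: (s[1], len(s[0]), s[0]))
    rank = {s: i for i, (s, _) in enumerate(simplices)}
    cols: dict[int, set] = {}
    pivots: dict[int, int] = {}
    pairs = {1: [], 2: []}
    for i, (s, r) in enumerate(simplices):
        if len(s) == 1:
            continue
        col = set()
        for d in range(len(s)):
            col ^= {rank[s[:d] + s[d + 1:]]}
        while col:
            low = max(col)
            if low not in pivots:
                break
            col ^= cols[pivots[low]]
        if col:
            low = max(col)
            pivots[low] = i
            cols[i] = col
            d = len(simplices[low][0]) - 1
            if d in pairs:
                birth, death = simplices[low][1], r
                if death - birth > 1e-9:
                    pairs[d].append((birth, death - birth))
    return {d: np.array(sorted(v)).reshape(-1, 2) for d, v in pairs.items()}


def _sorted_points(diagram: PersistenceDiagram) -> np.ndarray:
    if len(diagram.points) == 0:
        return np.empty((0, 2))
    return np.array(sorted(map(tuple, diagram.points)))


@pytest.mark.parametrize("trial", range(3))
def test_alpha_matches_cech_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    pts = rng.uniform(0, 5, size=(14, 3))
    alpha = persistence_diagrams(pts, dims=(1, 2))
    cech = _cech_diagrams(pts)
    for d in (1, 2):
        a, c = _sorted_points(alpha[d]), cech[d]
        assert a.shape == c.shape
        if a.size:
            assert np.allclose(a, c, atol=1e-6)


def test_single_point_gives_empty_diagrams():
    d = persistence_diagrams(np.zeros((1, 3)))
    assert len(d[1].points) == 0 and len(d[2].points) == 0


def test_cube_corners_enclose_a_void():
    rng = np.random.default_rng(1)
    cube = np.array([[i, j, k] for i in (0, 3) for j in (0, 3) for k in (0, 3)],
                    dtype=float) + rng.normal(0, 0.01, (8, 3))
    d = persistence_diagrams(cube, dims=(1, 2))
    assert len(d[2].points) >= 1


def _tube(radius: float, n_ring: int = 12, n_stack: int = 6, spacing: float = 2.0):
    th = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    ring = np.stack([radius * np.cos(th), radius * np.sin(th), np.zeros(n_ring)], 1)
    return np.concatenate([ring + [0, 0, spacing * k] for k in range(n_stack)])


def test_ring_persistence_monotone_in_radius():
    values = [persistence_diagrams(_tube(r), dims=(1, 2))[1].max_persistence
              for r in (2.0, 3.0, 4.0)]
    assert values[0] < values[1] < values[2]


def test_diagram_invariant_under_rigid_motion():
    rng = np.random.default_rng(5)
    pts = rng.uniform(0, 4, size=(16, 3))
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    moved = pts @ q.T + np.array([3.0, -2.0, 7.0])
    a = persistence_diagrams(pts, dims=(1, 2))
    b = persistence_diagrams(moved, dims=(1, 2))
    for d in (1, 2):
        pa, pb = _sorted_points(a[d]), _sorted_points(b[d])
        assert pa.shape == pb.shape
        if pa.size:
            assert np.allclose(pa, pb, atol=1e-6)


# -- periodic point cloud ---------------------------------------------------


def test_point_cloud_replication_counts():
    s = CrystalStructure(lattice=np.eye(3) * 25.0,
                         frac_coords=[[0.1, 0.1, 0.1], [0.3, 0.3, 0.3]],
                         elements=["C", "C"])
    pts, idx = periodic_point_cloud(s, min_extent=20.0)
    assert len(pts) == 2 and list(idx) == [0, 1]
    small = CrystalStructure(lattice=np.eye(3) * 6.0,
                             frac_coords=[[0.2, 0.2, 0.2]], elements=["C"])
    pts, idx = periodic_point_cloud(small, min_extent=20.0)
    assert len(pts) == 4 ** 3  # ceil(20/6) = 4 per axis
    assert np.all(idx == 0)


def test_perpendicular_widths_match_reciprocal_lattice():
    rng = np.random.default_rng(2)
    lattice = rng.uniform(-1, 1, (3, 3)) * 5 + np.eye(3) * 10
    widths = perpendicular_widths(lattice)
    recip = np.linalg.inv(lattice).T  # rows b_i (no 2π)
    assert np.allclose(widths, 1.0 / np.linalg.norm(recip, axis=1))


def test_degenerate_cell_rejected():
    with pytest.raises(ValueError):
        perpendicular_widths(np.array([[1, 0, 0], [2, 0, 0], [0, 0, 1.0]]))


# -- persistence images -----------------------------------------------------


def test_empty_diagram_zero_image():
    grid, mp, mb = persistence_image(PersistenceDiagram(1, np.empty((0, 2))))
    assert grid.shape == (50, 50)
    assert not grid.any() and mp == 0.0 and mb == 0.0


def test_single_point_unit_mass_at_corner():
    d = PersistenceDiagram(1, [[0.5, 0.3]])
    grid, mp, mb = persistence_image(d, resolution=50, spread=0.15)
    assert (mp, mb) == (0.3, 0.5)
    # unit mass up to boundary truncation (point sits at the (1,1) corner)
    assert 0.2 <= grid.sum() <= 1.0
    assert grid.sum() >= 0.25 - 0.02  # quarter-plane mass of a corner Gaussian
    iy, ix = np.unravel_index(np.argmax(grid), grid.shape)
    assert iy >= 45 and ix >= 45


def test_interior_point_mass_within_truncation():
    d = PersistenceDiagram(1, [[0.5, 0.5], [1.0, 1.0]])
    grid, _, _ = persistence_image(d, resolution=50, spread=0.15)
    # interior point contributes ~1, corner point ~0.25
    assert grid.sum() == pytest.approx(1.25, abs=0.07)


def test_image_resolution_configurable():
    d = PersistenceDiagram(1, [[0.5, 0.3]])
    grid, _, _ = persistence_image(d, resolution=30, spread=0.15)
    assert grid.shape == (30, 30)


def test_patchify_counts_and_roundtrip():
    rng = np.random.default_rng(0)
    img = rng.random((50, 50))
    patches = patchify(img, 5)
    assert patches.shape == (100, 25)
    assert np.array_equal(unpatchify(patches, 50, 5), img)
    const = patchify(np.full((50, 50), 3.5), 5)
    assert np.all(const == const[0])
    with pytest.raises(ValueError):
        patchify(img, 7)


# -- representative cycles --------------------------------------------------


def test_cycle_maps_back_to_ring_atoms():
    ring = _tube(3.0, n_stack=4)
    n = len(ring)
    atom_index = np.arange(n) % 12  # pretend a 12-atom cell replicated
    d = persistence_diagrams(ring, dims=(1, 2), with_cycles=True)[1]
    best = int(np.argmax(d.points[:, 1]))
    atoms = map_cycle_to_atoms(d, best, atom_index)
    assert len(atoms) > 0
    assert np.all(atoms < 12)


def test_cycle_errors():
    pts = np.random.default_rng(0).uniform(0, 4, (10, 3))
    d = persistence_diagrams(pts, dims=(1, 2), with_cycles=False)[1]
    with pytest.raises(ValueError):
        map_cycle_to_atoms(d, 0, np.arange(10))


# -- property tests ---------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=20, deadline=None, derandomize=True)
@given(k=st.sampled_from([2, 5, 10]), patch=st.sampled_from([1, 2, 5]),
       seed=st.integers(0, 99))
def test_patchify_roundtrip_property(k, patch, seed):
    rng = np.random.default_rng(seed)
    R = k * patch
    img = rng.random((R, R))
    assert np.array_equal(unpatchify(patchify(img, patch), R, patch), img)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 999))
def test_image_mass_counts_points(seed):
    """Total image mass equals the diagram size up to boundary truncation."""
    rng = np.random.default_rng(seed)
    pts = np.column_stack([rng.uniform(0.1, 1.0, 5), rng.uniform(0.1, 1.0, 5)])
    grid, _, _ = persistence_image(PersistenceDiagram(1, pts), 50, 0.15)
    # points on the scaled boundary lose up to ~half (corner: 3/4) of
    # their Gaussian mass outside the unit square
    assert 5 * 0.2 <= grid.sum() <= 5.0
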