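"""Crystal container, CIF I/O, P1 expansion, molecules, density, perturbation."""

import math
import textwrap

import numpy as np
import pytest

from xtalformer.crystal_io import (CIFError, CrystalStructure, DisorderError,
                                   assign_molecules, density, perturb, read_cif,
                                   to_p1, write_cif)

CUBE10 = np.eye(3) * 10.0


def _write(tmp_path, body, name="t.cif"):
    p = tmp_path / name
    p.write_text(textwrap.dedent(body))
    return p


def test_read_single_carbon_identity(tmp_path):
    p = _write(tmp_path, """\
        data_c1
        _cell_length_a 10.0
        _cell_length_b 10.0
        _cell_length_c 10.0
        _cell_angle_alpha 90
        _cell_angle_beta 90
        _cell_angle_gamma 90
        _symmetry_space_group_name_H-M 'P 1'
        loop_
        _atom_site_label
        _atom_site_type_symbol
        _atom_site_fract_x
        _atom_site_fract_y
        _atom_site_fract_z
        _atom_site_occupancy
        C1 C 0.5 0.5 0.5 1.0
        """)
    s = read_cif(p)
    assert s.n_atoms == 1
    assert s.elements == ["C"]
    assert s.space_group_number == 1
    # 12.011 u in a 1000 Å³ cube
    assert density(s) == pytest.approx(12.011 / (6.02214076e23 * 1e-21), rel=1e-6)


def test_read_p21_fixture_roundtrip(tmp_path, p21_crystal):
    s, record = p21_crystal
    asym = record["asymmetric_unit"]
    path = tmp_path / "p21.cif"
    write_cif(asym, path)
    back = read_cif(path)
    assert back.space_group_number == 4
    assert back.n_atoms == asym.n_atoms
    full = to_p1(back)
    assert full.n_atoms == s.n_atoms
    assert density(full) == pytest.approx(record["density"], rel=1e-6)


def test_partial_occupancy_rejected(tmp_path):
    p = _write(tmp_path, """\
        data_dis
        _cell_length_a 10.0
        _cell_length_b 10.0
        _cell_length_c 10.0
        _cell_angle_alpha 90
        _cell_angle_beta 90
        _cell_angle_gamma 90
        loop_
        _atom_site_label
        _atom_site_type_symbol
        _atom_site_fract_x
        _atom_site_fract_y
        _atom_site_fract_z
        _atom_site_occupancy
        C1 C 0.1 0.1 0.1 0.5
        """)
    with pytest.raises(DisorderError):
        read_cif(p)


def test_malformed_cif_raises(tmp_path):
    p = tmp_path / "bad.cif"
    p.write_text("data_x\nloop_\n_atom_site_label\n")
    with pytest.raises(CIFError):
        read_cif(p)


@pytest.mark.parametrize("group,ops,expected_atoms", [
    # space group 4 (P21, unique axis b): (x,y,z), (-x, y+1/2, -z)
    (4, [(np.eye(3), np.zeros(3)),
         (np.diag([-1, 1, -1]), np.array([0, 0.5, 0]))], 10),
    # space group 19 (P212121): four screw-related positions
    (19, [(np.eye(3), np.zeros(3)),
          (np.diag([-1, -1, 1]), np.array([0.5, 0, 0.5])),
          (np.diag([1, -1, -1]), np.array([0.5, 0.5, 0])),
          (np.diag([-1, 1, -1]), np.array([0, 0.5, 0.5]))], 20),
])
def test_to_p1_multiplicity_against_textbook_ops(group, ops, expected_atoms):
    """P1 expansion of a 5-atom molecule matches explicit application of the
    group's textbook operations (frozen here, independent of the reader)."""
    rng = np.random.default_rng(5)
    frac = rng.uniform(0.05, 0.2, size=(5, 3))
    s = CrystalStructure(lattice=np.diag([12.0, 13.0, 14.0]), frac_coords=frac,
                         elements=["C", "N", "O", "H", "H"],
                         space_group_number=group, symmetry_ops=ops)
    full = to_p1(s)
    assert full.n_atoms == expected_atoms
    assert full.space_group_number == 1
    # every textbook image appears in the expansion
    expected = []
    for R, t in ops:
        expected.extend((frac @ R.T + t) % 1.0)
    got = full.frac_coords
    for img in expected:
        d = got - img
        d -= np.round(d)
        assert np.min(np.abs(d).max(axis=1)) < 1e-8


def test_to_p1_identity_for_p1():
    s = CrystalStructure(lattice=CUBE10, frac_coords=[[0.1, 0.2, 0.3]],
                         elements=["C"])
    assert to_p1(s).n_atoms == 1


def test_density_invariant_under_p1_and_supercell(p21_crystal):
    s, record = p21_crystal
    asym = record["asymmetric_unit"]
    assert density(to_p1(asym)) == pytest.approx(density(to_p1(asym)), rel=1e-12)
    # doubling the cell with doubled contents leaves density unchanged
    doubled = CrystalStructure(
        lattice=s.lattice * np.array([[2.0], [1.0], [1.0]]),
        frac_coords=np.concatenate([s.frac_coords * [0.5, 1, 1],
                                    s.frac_coords * [0.5, 1, 1] + [0.5, 0, 0]]),
        elements=s.elements * 2)
    assert density(doubled) == pytest.approx(density(s), rel=1e-10)
    assert density(to_p1(asym)) == pytest.approx(density(asym), rel=1e-10)


def test_density_errors():
    with pytest.raises(ValueError):
        density(CrystalStructure(lattice=CUBE10, frac_coords=np.empty((0, 3)),
                                 elements=[]))


def test_assign_molecules_two_n2():
    s = CrystalStructure(
        lattice=np.eye(3) * 20.0,
        frac_coords=[[0.1, 0.1, 0.1], [0.155, 0.1, 0.1],
                     [0.4, 0.4, 0.4], [0.455, 0.4, 0.4]],
        elements=["N", "N", "N", "N"])
    out = assign_molecules(s)
    assert sorted(np.bincount(out.molecule_ids)) == [2, 2]
    assert out.molecule_ids[0] == out.molecule_ids[1]
    assert out.molecule_ids[0] != out.molecule_ids[2]


def test_molecule_across_cell_boundary():
    s = CrystalStructure(
        lattice=np.eye(3) * 15.0,
        frac_coords=[[0.98, 0.1, 0.1], [0.02, 0.1, 0.1]],
        elements=["N", "N"])
    out = assign_molecules(s)
    assert out.molecule_ids[0] == out.molecule_ids[1] == 0


def test_assign_molecules_p1_expanded_p21(p21_crystal):
    s, record = p21_crystal
    assert record["n_molecules"] == 2
    assert set(s.molecule_ids) == {0, 1}


def test_assign_molecules_permutation_invariant(p21_crystal):
    s, _ = p21_crystal
    rng = np.random.default_rng(0)
    perm = rng.permutation(s.n_atoms)
    permuted = CrystalStructure(lattice=s.lattice,
                                frac_coords=s.frac_coords[perm],
                                elements=[s.elements[i] for i in perm])
    out = assign_molecules(permuted)
    # same partition up to relabeling
    orig = s.molecule_ids[perm]
    mapping = {}
    for a, b in zip(orig, out.molecule_ids):
        mapping.setdefault(a, b)
        assert mapping[a] == b


def test_perturb_identity_and_determinism(p21_crystal):
    s, _ = p21_crystal
    assert np.allclose(perturb(s, 0.0, 1).frac_coords, s.frac_coords)
    a = perturb(s, 0.1, 42).frac_coords
    b = perturb(s, 0.1, 42).frac_coords
    assert np.array_equal(a, b)
    assert not np.allclose(perturb(s, 0.1, 43).frac_coords, a)
    with pytest.raises(ValueError):
        perturb(s, -0.1, 0)


def test_perturb_rms_matches_chi_distribution():
    n = 10_000
    rng = np.random.default_rng(3)
    s = CrystalStructure(lattice=np.eye(3) * 200.0,
                         frac_coords=rng.uniform(0.2, 0.8, size=(n, 3)),
                         elements=["C"] * n)
    moved = perturb(s, 0.05, 7)
    disp = (moved.frac_coords - s.frac_coords)
    disp -= np.round(disp)
    rms = np.sqrt(np.mean(np.sum((disp @ s.lattice) ** 2, axis=1)))
    assert rms == pytest.approx(0.05 * math.sqrt(3), rel=0.05)
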