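"""Crystal structure container and I/O.

A :class:`CrystalStructure` is the universal input record of the package: a
periodic cell (row-wise lattice vectors, Å), fractional coordinates wrapped
into [0, 1), element symbols, optional molecule labels and the space-group
number of the setting the structure was read in.

Structures are read from CIF (via gemmi), expanded to P1 by applying the
listed symmetry operations, partitioned into molecules by connected
components of the periodic covalent-bond graph, and can be perturbed with
i.i.d. Gaussian displacements (used to build positional embeddings).

Any site with occupancy different from 1 is rejected outright — disordered
structures are outside the model's domain, mirroring the pre-filters used to
assemble experimental training sets.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import gemmi
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .data import ATOMIC_MASSES, AVOGADRO, COVALENT_RADII

__all__ = [
    "CrystalStructure",
    "CIFError",
    "DisorderError",
    "read_cif",
    "write_cif",
    "write_xyz",
    "to_p1",
    "assign_molecules",
    "density",
    "perturb",
]


class CIFError(ValueError):
    """Malformed or unsupported CIF content."""


class DisorderError(CIFError):
    """Structure contains partial occupancy / disorder and is rejected."""


SymOp = tuple[np.ndarray, np.ndarray]  # (3x3 rotation, translation) in fractional basis


@dataclasses.dataclass
class CrystalStructure:
    """Periodic crystal: cell, atoms, element identities, molecule labels.

    Attributes
    ----------
    lattice : (3, 3) float array
        Row-wise cell vectors in Å.
    frac_coords : (N, 3) float array
        Fractional coordinates, wrapped into [0, 1).
    elements : list of str
        Element symbol per atom.
    molecule_ids : (N,) int array
        Molecule label per atom; -1 until :func:`assign_molecules` runs.
    space_group_number : int
        1–230, as read from the file or 1 after P1 expansion.
    structure_id : str
        Opaque identifier (CIF data block name by default).
    symmetry_ops : list of (R, t)
        Fractional symmetry operations of the setting (identity included).
    """

    lattice: np.ndarray
    frac_coords: np.ndarray
    elements: list[str]
    molecule_ids: np.ndarray = None
    space_group_number: int = 1
    structure_id: str = ""
    symmetry_ops: list[SymOp] = None

    def __post_init__(self):
        self.lattice = np.asarray(self.lattice, dtype=float)
        if self.lattice.shape != (3, 3):
            raise ValueError("lattice must be a 3x3 matrix of row vectors")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")
        self.frac_coords = wrap_frac(np.atleast_2d(np.asarray(self.frac_coords, dtype=float)))
        if self.frac_coords.shape[1] != 3:
            raise ValueError("frac_coords must be (N, 3)")
        if len(self.elements) != len(self.frac_coords):
            raise ValueError("elements and frac_coords length mismatch")
        self.elements = [str(e) for e in self.elements]
        if self.molecule_ids is None:
            self.molecule_ids = np.full(len(self.elements), -1, dtype=int)
        else:
            self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if self.symmetry_ops is None:
            self.symmetry_ops = [(np.eye(3), np.zeros(3))]

    # -- geometry -----------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        return float(abs(np.linalg.det(self.lattice)))

    @property
    def cart_coords(self) -> np.ndarray:
        """Cartesian coordinates in Å (frac @ lattice)."""
        return self.frac_coords @ self.lattice

    def copy(self, **replace) -> "CrystalStructure":
        kw = dict(
            lattice=self.lattice.copy(),
            frac_coords=self.frac_coords.copy(),
            elements=list(self.elements),
            molecule_ids=self.molecule_ids.copy(),
            space_group_number=self.space_group_number,
            structure_id=self.structure_id,
            symmetry_ops=[(R.copy(), t.copy()) for R, t in self.symmetry_ops],
        )
        kw.update(replace)
        return CrystalStructure(**kw)

    def min_image_distances(self) -> np.ndarray:
        """N×N matrix of minimum-image interatomic distances (Å)."""
        d = self.frac_coords[:, None, :] - self.frac_coords[None, :, :]
        d -= np.round(d)
        cart = d @ self.lattice
        return np.linalg.norm(cart, axis=-1)


def wrap_frac(frac: np.ndarray) -> np.ndarray:
    """Wrap fractional coordinates into [0, 1), mapping values within
    float tolerance of 1 to exactly 0."""
    w = frac - np.floor(frac)
    w[np.isclose(w, 1.0, atol=1e-9)] = 0.0
    return w


# -- CIF I/O ---------------------------------------------------------------


def _ops_from_gemmi(ops) -> list[SymOp]:
    den = float(gemmi.Op.DEN)
    out = []
    for op in ops:
        R = np.array(op.rot, dtype=float) / den
        t = np.array(op.tran, dtype=float) / den
        out.append((R, t))
    return out


def read_cif(path: str | Path) -> CrystalStructure:
    """Read a small-molecule CIF into a :class:`CrystalStructure`.

    The structure is returned in the file's own setting; symmetry operations
    listed in (or implied by) the file are retained on ``symmetry_ops``.

    Raises
    ------
    CIFError
        If the file cannot be parsed or holds no atoms (the gemmi message,
        which names the offending tag/line, is propagated).
    DisorderError
        If any site has occupancy != 1 (disorder pre-filter).
    """
    path = Path(path)
    try:
        small = gemmi.read_small_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise CIFError(f"cannot parse CIF {path.name}: {exc}") from exc
    if not small.sites:
        raise CIFError(f"CIF {path.name} contains no atom sites (_atom_site loop missing or empty)")
    for site in small.sites:
        if not math.isclose(site.occ, 1.0, abs_tol=1e-6):
            raise DisorderError(
                f"site {site.label!r} has occupancy {site.occ}; "
                "disordered/partially occupied structures are rejected"
            )
    cell = small.cell
    lattice = np.array(cell.orth.mat.tolist(), dtype=float).T  # row vectors
    frac = np.array([[s.fract.x, s.fract.y, s.fract.z] for s in small.sites])
    elements = [s.element.name for s in small.sites]
    for el in elements:
        if el not in ATOMIC_MASSES:
            raise CIFError(f"unknown element symbol {el!r} in {path.name}")

    sg_number = 1
    ops = None
    if small.symops:
        try:
            gops = gemmi.GroupOps([gemmi.Op(trip) for trip in small.symops])
            ops = _ops_from_gemmi(gops)
            sg = gemmi.find_spacegroup_by_ops(gops)
            if sg is not None:
                sg_number = sg.number
        except (RuntimeError, ValueError) as exc:
            raise CIFError(f"unresolvable symmetry operation list in {path.name}: {exc}") from exc
    if ops is None and small.spacegroup_hm:
        sg = gemmi.find_spacegroup_by_name(small.spacegroup_hm)
        if sg is not None:
            sg_number = sg.number
            ops = _ops_from_gemmi(sg.operations())
    if ops is None:
        ops = [(np.eye(3), np.zeros(3))]

    return CrystalStructure(
        lattice=lattice,
        frac_coords=frac,
        elements=elements,
        space_group_number=sg_number,
        structure_id=small.name or path.stem,
        symmetry_ops=ops,
    )


def _cell_parameters(lattice: np.ndarray) -> tuple[float, float, float, float, float, float]:
    a, b, c = (np.linalg.norm(lattice[i]) for i in range(3))
    def ang(u, v):
        return math.degrees(math.acos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))))
    return a, b, c, ang(lattice[1], lattice[2]), ang(lattice[0], lattice[2]), ang(lattice[0], lattice[1])


def _op_triplet(R: np.ndarray, t: np.ndarray) -> str:
    den = gemmi.Op.DEN
    op = gemmi.Op()
    op.rot = [[int(round(x * den)) for x in row] for row in R]
    op.tran = [int(round(x * den)) for x in t]
    return op.triplet()


def write_cif(s: CrystalStructure, path: str | Path, hm_symbol: str | None = None) -> None:
    """Write a CIF with explicit symmetry operation list.

    P1 structures are written with ``_symmetry_space_group_name_H-M 'P 1'``.
    """
    a, b, c, al, be, ga = _cell_parameters(s.lattice)
    if hm_symbol is None:
        sg = gemmi.find_spacegroup_by_number(s.space_group_number)
        hm_symbol = sg.hm if sg is not None else "P 1"
    lines = [
        f"data_{s.structure_id or 'crystal'}",
        f"_cell_length_a {a:.6f}",
        f"_cell_length_b {b:.6f}",
        f"_cell_length_c {c:.6f}",
        f"_cell_angle_alpha {al:.6f}",
        f"_cell_angle_beta {be:.6f}",
        f"_cell_angle_gamma {ga:.6f}",
        f"_symmetry_space_group_name_H-M '{hm_symbol}'",
        f"_symmetry_Int_Tables_number {s.space_group_number}",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
    ]
    for R, t in s.symmetry_ops:
        lines.append(f"'{_op_triplet(R, t)}'")
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
    ]
    counts: dict[str, int] = {}
    for el, fr in zip(s.elements, s.frac_coords):
        counts[el] = counts.get(el, 0) + 1
        lines.append(f"{el}{counts[el]} {el} {fr[0]:.8f} {fr[1]:.8f} {fr[2]:.8f} 1.0")
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(s: CrystalStructure, path: str | Path,
              extra_columns: dict[str, np.ndarray] | None = None) -> None:
    """Extended-XYZ export (debugging / attribution overlays)."""
    cart = s.cart_coords
    flat = " ".join(f"{x:.8f}" for x in s.lattice.flatten())
    props = "species:S:1:pos:R:3"
    cols: list[np.ndarray] = []
    if extra_columns:
        for name, values in extra_columns.items():
            values = np.asarray(values, dtype=float)
            if len(values) != s.n_atoms:
                raise ValueError(f"extra column {name!r} has wrong length")
            props += f":{name}:R:1"
            cols.append(values)
    lines = [str(s.n_atoms), f'Lattice="{flat}" Properties={props}']
    for i in range(s.n_atoms):
        row = f"{s.elements[i]} {cart[i, 0]:.8f} {cart[i, 1]:.8f} {cart[i, 2]:.8f}"
        for col in cols:
            row += f" {col[i]:.8f}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


# -- operations ------------------------------------------------------------


def to_p1(s: CrystalStructure, tol: float = 1e-4) -> CrystalStructure:
    """Expand all symmetry-equivalent atoms, giving an explicit P1 cell.

    Atoms on special positions whose images coincide (within ``tol``
    fractional units under the minimum image) are merged, so the formula
    count scales by the multiplicity of the position actually occupied.
    Density is exactly preserved.
    """
    new_frac: list[np.ndarray] = []
    new_elems: list[str] = []
    for R, t in s.symmetry_ops:
        imgs = wrap_frac(s.frac_coords @ R.T + t)
        for el, fr in zip(s.elements, imgs):
            dup = False
            for prev in new_frac:
                d = fr - prev
                d -= np.round(d)
                if np.max(np.abs(d)) < tol:
                    dup = True
                    break
            if not dup:
                new_frac.append(fr)
                new_elems.append(el)
    return CrystalStructure(
        lattice=s.lattice.copy(),
        frac_coords=np.array(new_frac),
        elements=new_elems,
        space_group_number=1,
        structure_id=s.structure_id,
        symmetry_ops=[(np.eye(3), np.zeros(3))],
    )


def assign_molecules(s: CrystalStructure, radius_scale: float = 1.2) -> CrystalStructure:
    """Label molecules as connected components of the periodic bond graph.

    Two atoms are bonded when their minimum-image distance is at most
    ``radius_scale`` times the sum of their covalent radii. Labels are
    contiguous 0..M-1, ordered by each molecule's lowest atom index. A fully
    disconnected structure yields N single-atom molecules.
    """
    n = s.n_atoms
    radii = np.array([COVALENT_RADII[el] for el in s.elements])
    dist = s.min_image_distances()
    cutoff = radius_scale * (radii[:, None] + radii[None, :])
    bonded = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    ii, jj = np.nonzero(bonded)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    # relabel by first occurrence so the labeling is deterministic
    order: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return s.copy(molecule_ids=out)


def density(s: CrystalStructure) -> float:
    """Mass density in g cm⁻³: total atomic mass of the full cell / volume.

    A structure carrying symmetry operations is expanded first, so the
    density of an asymmetric unit equals that of its P1 cell; the value is
    likewise invariant under supercell replication.
    """
    if s.n_atoms == 0:
        raise ValueError("cannot compute density of an empty structure")
    if len(s.symmetry_ops) > 1:
        s = to_p1(s)
    try:
        mass_u = sum(ATOMIC_MASSES[el] for el in s.elements)
    except KeyError as exc:
        raise ValueError(f"unknown element symbol {exc.args[0]!r}") from exc
    grams = mass_u / AVOGADRO
    cm3 = s.volume * 1e-24  # Å³ → cm³
    return grams / cm3


def perturb(s: CrystalStructure, sigma: float, seed: int) -> CrystalStructure:
    """Add i.i.d. Gaussian displacements (std ``sigma`` Å per Cartesian
    component) and rewrap. Deterministic given ``seed``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return s.copy()
    rng = np.random.default_rng(seed)
    cart = s.cart_coords + rng.normal(0.0, sigma, size=(s.n_atoms, 3))
    frac = cart @ np.linalg.inv(s.lattice)
    return s.copy(frac_coords=wrap_frac(frac))
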