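"""Persistent homology of the periodic atomic point cloud.

The global-geometry modality of the model: grow spheres centred on the
atoms and record when channels (1-dimensional homology classes) and voids
(2-dimensional classes) appear and disappear. The filtration is an alpha
complex built on a finite supercell replication of the P1 cell — each
supercell edge is replicated until its perpendicular width reaches
``min_extent`` (default 20 Å) so that features up to ~10 Å radius are seen
away from boundary artefacts.

Diagrams are rasterized into per-image-scaled persistence images: every
diagram is scaled by its own maximum birth and maximum persistence onto
[0, 1]², then each point deposits a unit-mass isotropic Gaussian (std =
``spread`` in scaled units) on a ``resolution`` × ``resolution`` grid. The
two maxima are kept alongside as scalar tokens, so no information is lost
by the scaling and mass does not concentrate in a few pixels for small
structures.

The persistence pairing is computed by standard Z/2 boundary-matrix
reduction; the reduced column of each death simplex provides a
representative cycle, which can be folded back from supercell points to
original-cell atoms for attribution overlays.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay
from scipy.stats import norm

__all__ = [
    "PersistenceDiagram",
    "PersistenceImageSet",
    "periodic_point_cloud",
    "persistence_diagrams",
    "persistence_image",
    "patchify",
    "unpatchify",
    "map_cycle_to_atoms",
    "featurize_structure",
    "FeatureCache",
]


@dataclasses.dataclass
class PersistenceDiagram:
    """Finite persistence pairs of one homology dimension.

    points[i] = (birth, persistence), in Å (alpha-complex radius units).
    representative_cycles[i] optionally lists the point-cloud indices of a
    representative cycle for pair i.
    """

    dim: int
    points: np.ndarray  # (M, 2): birth, persistence
    representative_cycles: list[list[int]] | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) and (np.any(self.points[:, 1] <= 0) or np.any(self.points[:, 0] < 0)):
            raise ValueError("diagram points need birth >= 0 and persistence > 0")

    @property
    def max_birth(self) -> float:
        return float(self.points[:, 0].max()) if len(self.points) else 0.0

    @property
    def max_persistence(self) -> float:
        return float(self.points[:, 1].max()) if len(self.points) else 0.0


@dataclasses.dataclass
class PersistenceImageSet:
    """Scaled 50×50 persistence images for dims 1 and 2 plus their scale
    scalars (the [SCL] token values)."""

    image_1d: np.ndarray
    image_2d: np.ndarray
    max_persistence_1d: float
    max_birth_1d: float
    max_persistence_2d: float
    max_birth_2d: float
    spread: float = 0.15


# -- point cloud -----------------------------------------------------------


def perpendicular_widths(lattice: np.ndarray) -> np.ndarray:
    """Perpendicular width of the cell along each lattice direction:
    volume / area of the opposite face, i.e. 1/|b_i| for reciprocal
    vectors b_i (no 2π). Correct for arbitrarily skewed cells."""
    lattice = np.asarray(lattice, dtype=float)
    vol = abs(np.linalg.det(lattice))
    if vol <= 1e-9:
        raise ValueError("degenerate cell")
    widths = np.empty(3)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        widths[i] = vol / np.linalg.norm(np.cross(lattice[j], lattice[k]))
    return widths


def periodic_point_cloud(s, min_extent: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Replicate a P1 structure into an a×b×c supercell whose perpendicular
    widths all reach ``min_extent`` Å.

    Returns (points, atom_index): Cartesian points in deterministic order
    (lexicographic over replicas, then original atom order) and the map
    from each point to its original-cell atom index.
    """
    widths = perpendicular_widths(s.lattice)
    reps = np.maximum(1, np.ceil(min_extent / widths - 1e-9).astype(int))
    shifts = np.array([[i, j, k]
                       for i in range(reps[0])
                       for j in range(reps[1])
                       for k in range(reps[2])], dtype=float)
    frac = (shifts[:, None, :] + s.frac_coords[None, :, :]).reshape(-1, 3)
    points = frac @ s.lattice
    atom_index = np.tile(np.arange(s.n_atoms), len(shifts))
    return points, atom_index


# -- alpha complex ---------------------------------------------------------


def _circumradius2(points: np.ndarray, simplices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared circumradius and circumcenter of each k-simplex (batched).

    The circumcenter is the point of the simplex's affine hull equidistant
    from all vertices.
    """
    p0 = points[simplices[:, 0]]
    V = points[simplices[:, 1:]] - p0[:, None, :]        # (M, k, 3)
    G = np.einsum("mij,mkj->mik", V, V)                  # Gram matrices
    b = 0.5 * np.einsum("mii->mi", G).copy()
    try:
        y = np.linalg.solve(G, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        y = np.array([np.linalg.lstsq(Gi, bi, rcond=None)[0] for Gi, bi in zip(G, b)])
    offset = np.einsum("mi,mij->mj", y, V)
    centers = p0 + offset
    r2 = np.einsum("mj,mj->m", offset, offset)
    return r2, centers


def _alpha_filtration(points: np.ndarray):
    """Alpha-complex filtration of a 3-D point cloud.

    Returns (simplices, filtration) where simplices is a list of vertex
    tuples (dims 0..3) and filtration the matching alpha values in squared
    radius units. Follows the standard algorithm: Delaunay simplices get
    their circumradius; faces inherit the minimum over cofaces unless they
    are Gabriel (their smallest circumsphere is empty), in which case they
    get their own circumradius.
    """
    tri = Delaunay(points)
    tets = np.sort(tri.simplices, axis=1)
    # drop degenerate (zero-volume) tetrahedra defensively
    v = points[tets]
    vol6 = np.abs(np.linalg.det(v[:, 1:] - v[:, :1]))
    tets = tets[vol6 > 1e-12]

    filt: dict[tuple[int, ...], float] = {}
    r2_t, _ = _circumradius2(points, tets)
    for t, r2 in zip(map(tuple, tets), r2_t):
        filt[t] = min(filt.get(t, np.inf), float(r2))

    def faces_of(simp: tuple[int, ...]):
        for drop in range(len(simp)):
            yield simp[:drop] + simp[drop + 1:], simp[drop]

    current = {t: filt[t] for t in map(tuple, tets)}
    for dim in (3, 2):
        # a face is Gabriel when its smallest circumsphere contains no
        # opposite vertex of any Delaunay coface; then it enters at its own
        # circumradius, otherwise it inherits the min over its cofaces
        cofaces: dict[tuple[int, ...], list[tuple[float, int]]] = {}
        for simp, value in current.items():
            for face, opposite in faces_of(simp):
                cofaces.setdefault(face, []).append((value, opposite))
        face_list = np.array(list(cofaces.keys()), dtype=int)
        r2_f, centers_f = _circumradius2(points, face_list)
        next_level: dict[tuple[int, ...], float] = {}
        for face, own, center in zip(map(tuple, face_list), r2_f, centers_f):
            gabriel = True
            inherit = np.inf
            for value, opposite in cofaces[face]:
                inherit = min(inherit, value)
                if np.dot(points[opposite] - center, points[opposite] - center) < own - 1e-12:
                    gabriel = False
            next_level[face] = float(own) if gabriel else float(inherit)
        filt.update(next_level)
        current = next_level

    for i in range(len(points)):
        filt[(i,)] = 0.0
    # monotone cleanup: a face never enters later than any coface
    for simp in sorted(filt, key=len, reverse=True):
        if len(simp) > 2:
            value = filt[simp]
            for drop in range(len(simp)):
                face = simp[:drop] + simp[drop + 1:]
                if filt[face] > value:
                    filt[face] = value
    simplices = list(filt.keys())
    values = np.array([filt[s] for s in simplices])
    return simplices, values


def _reduce_boundary(simplices, values, dims=(1, 2), with_cycles=False):
    """Z/2 boundary-matrix reduction; returns persistence pairs per dim.

    Pairs are (birth_value, death_value, cycle) with values still in squared
    radius units; essential (infinite) classes are dropped.
    """
    order = sorted(range(len(simplices)), key=lambda i: (values[i], len(simplices[i]), simplices[i]))
    rank = {simplices[i]: r for r, i in enumerate(order)}
    columns: list[set[int] | None] = [None] * len(order)
    pivot_of: dict[int, int] = {}
    pairs: dict[int, list[tuple[float, float, list[int] | None]]] = {d: [] for d in dims}

    for r, i in enumerate(order):
        simp = simplices[i]
        if len(simp) == 1:
            continue
        col = set()
        for drop in range(len(simp)):
            col ^= {rank[simp[:drop] + simp[drop + 1:]]}
        while col:
            low = max(col)
            other = pivot_of.get(low)
            if other is None:
                break
            col ^= columns[other]
        if col:
            low = max(col)
            pivot_of[low] = r
            columns[r] = col
            d = len(simplices[order[low]]) - 1
            if d in dims:
                birth = values[order[low]]
                death = values[i]
                if death > birth + 1e-14:
                    cycle = None
                    if with_cycles:
                        verts: set[int] = set()
                        for member in col:
                            verts.update(simplices[order[member]])
                        cycle = sorted(verts)
                    pairs[d].append((birth, death, cycle))
    return pairs


def persistence_diagrams(points: np.ndarray, dims=(1, 2),
                         with_cycles: bool = False) -> dict[int, PersistenceDiagram]:
    """Alpha-complex persistence diagrams of a Cartesian point cloud.

    Values are converted to radius units (Å). Infinite-persistence features
    are dropped; clouds too small to triangulate yield empty diagrams.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 1:
        raise ValueError("need at least one point")
    empty = {d: PersistenceDiagram(d, np.empty((0, 2)),
                                   [] if with_cycles else None) for d in dims}
    if len(points) < 5:
        return empty
    try:
        simplices, values = _alpha_filtration(points)
    except Exception:
        return empty
    pairs = _reduce_boundary(simplices, values, dims=dims, with_cycles=with_cycles)
    out = {}
    for d in dims:
        pts, cycles = [], []
        for birth2, death2, cycle in pairs[d]:
            birth = math.sqrt(max(birth2, 0.0))
            death = math.sqrt(max(death2, 0.0))
            if death - birth > 1e-9:
                pts.append((birth, death - birth))
                cycles.append(cycle if cycle is not None else [])
        out[d] = PersistenceDiagram(d, np.array(pts).reshape(-1, 2),
                                    cycles if with_cycles else None)
    return out


# -- persistence images ----------------------------------------------------


def persistence_image(diagram: PersistenceDiagram, resolution: int = 50,
                      spread: float = 0.15) -> tuple[np.ndarray, float, float]:
    """Rasterize a diagram into a per-image-scaled persistence image.

    Each point is scaled by the diagram's own maxima onto [0, 1]² (birth on
    x, persistence on y) and deposits a unit-mass isotropic Gaussian of std
    ``spread`` (scaled units), integrated exactly over pixels via the
    Gaussian CDF. Returns (grid, max_persistence, max_birth); an empty
    diagram gives a zero grid and zero maxima.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    grid = np.zeros((resolution, resolution))
    if len(diagram.points) == 0:
        return grid, 0.0, 0.0
    mb, mp = diagram.max_birth, diagram.max_persistence
    xs = diagram.points[:, 0] / mb if mb > 0 else np.zeros(len(diagram.points))
    ys = diagram.points[:, 1] / mp  # mp > 0 by diagram invariant
    edges = np.linspace(0.0, 1.0, resolution + 1)
    for x, y in zip(xs, ys):
        cx = np.diff(norm.cdf(edges, loc=x, scale=spread))
        cy = np.diff(norm.cdf(edges, loc=y, scale=spread))
        grid += np.outer(cy, cx)  # row = persistence axis, col = birth axis
    return grid, float(mp), float(mb)


def patchify(grid: np.ndarray, patch: int = 5) -> np.ndarray:
    """Split an R×R image into (R/P)² non-overlapping P×P patches, row-major,
    each flattened row-major. ``patch`` must divide the resolution."""
    R = grid.shape[0]
    if grid.shape != (R, R):
        raise ValueError("grid must be square")
    if R % patch != 0:
        raise ValueError(f"patch size {patch} does not divide resolution {R}")
    k = R // patch
    return (grid.reshape(k, patch, k, patch)
                .transpose(0, 2, 1, 3)
                .reshape(k * k, patch * patch))


def unpatchify(patches: np.ndarray, resolution: int, patch: int = 5) -> np.ndarray:
    """Inverse of :func:`patchify` (bit-exact)."""
    k = resolution // patch
    return (patches.reshape(k, k, patch, patch)
                   .transpose(0, 2, 1, 3)
                   .reshape(resolution, resolution))


def map_cycle_to_atoms(diagram: PersistenceDiagram, point_index: int,
                       atom_index: np.ndarray) -> np.ndarray:
    """Fold the representative cycle of diagram point ``point_index`` back
    to original-cell atom indices (modulo supercell replication)."""
    if diagram.representative_cycles is None:
        raise ValueError("diagram was computed without representative cycles")
    cycle = diagram.representative_cycles[point_index]
    if len(cycle) == 0 and len(diagram.points) == 0:
        raise IndexError("empty diagram has no cycles")
    return np.unique(np.asarray(atom_index)[np.asarray(cycle, dtype=int)])


# -- structure-level featurization + cache ---------------------------------


def featurize_structure(s, resolution: int = 50, spread: float = 0.15,
                        min_extent: float = 20.0,
                        with_cycles: bool = False):
    """Full topology featurization of a P1 structure.

    Returns (PersistenceImageSet, diagrams dict, atom_index map).
    """
    points, atom_index = periodic_point_cloud(s, min_extent=min_extent)
    diagrams = persistence_diagrams(points, dims=(1, 2), with_cycles=with_cycles)
    img1, mp1, mb1 = persistence_image(diagrams[1], resolution, spread)
    img2, mp2, mb2 = persistence_image(diagrams[2], resolution, spread)
    images = PersistenceImageSet(img1, img2, mp1, mb1, mp2, mb2, spread)
    return images, diagrams, atom_index


def featurization_hash(resolution: int = 50, spread: float = 0.15,
                       min_extent: float = 20.0, patch: int = 5) -> str:
    """Stable hash of the featurization configuration; stamped into caches
    and checkpoints so stale features are never mixed with a model."""
    payload = json.dumps({"resolution": resolution, "spread": spread,
                          "min_extent": min_extent, "patch": patch}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class FeatureCache:
    """Per-structure persistence-feature cache (one .npz per structure,
    keyed by structure_id + featurization hash)."""

    def __init__(self, directory: str | Path, config_hash: str):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self.config_hash = config_hash

    def _path(self, structure_id: str) -> Path:
        safe = structure_id.replace("/", "_")
        return self.directory / f"{safe}.{self.config_hash}.npz"

    def get(self, structure_id: str) -> PersistenceImageSet | None:
        p = self._path(structure_id)
        if not p.exists():
            return None
        z = np.load(p)
        return PersistenceImageSet(z["image_1d"], z["image_2d"],
                                   float(z["mp1"]), float(z["mb1"]),
                                   float(z["mp2"]), float(z["mb2"]),
                                   float(z["spread"]))

    def put(self, structure_id: str, images: PersistenceImageSet) -> None:
        np.savez(self._path(structure_id),
                 image_1d=images.image_1d, image_2d=images.image_2d,
                 mp1=images.max_persistence_1d, mb1=images.max_birth_1d,
                 mp2=images.max_persistence_2d, mb2=images.max_birth_2d,
                 spread=images.spread)
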