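"""Space-group → symmetry-element labels and the weighted multi-label loss
support for the symmetry-element prediction (SEP) task.

Direct space-group classification is hopeless for molecular crystals
(a handful of groups dominate), so the global-symmetry pre-training signal
is the *set of symmetry-element types* present in the group: a 7-bit
multi-hot vector in the fixed order

    [no-element (P1), inversion center, mirror plane, rotation axis,
     screw axis, rotoinversion axis, glide plane]

Bit 0 is set exactly when the group has no element at all beyond lattice
translations, i.e. for P1 itself.

Each symmetry operation (R, t) of the group — identity excluded, centering
translations expanded — is classified from its rotation part and *intrinsic*
translation (the component of t invariant under the operation, i.e. the
screw/glide vector):

* R == -I                              → inversion center
* det R = +1, order > 1, intrinsic = 0 → rotation axis
* det R = +1, order > 1, intrinsic ≠ 0 → screw axis
* det R = -1, order of -R == 2 (mirror), intrinsic = 0 → mirror plane
* ... intrinsic ≠ 0                                    → glide plane
* det R = -1, rotational order > 2     → rotoinversion axis
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "ELEMENT_NAMES",
    "SymmetryElementLabel",
    "classify_operation",
    "symmetry_elements",
    "element_weights",
    "sep_exact_match",
    "full_label_table",
    "export_label_table",
    "detect_space_group",
]

ELEMENT_NAMES = (
    "no_element",
    "inversion_center",
    "mirror_plane",
    "rotation_axis",
    "screw_axis",
    "rotoinversion_axis",
    "glide_plane",
)

_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class SymmetryElementLabel:
    """7-bit multi-hot symmetry-element label."""

    bits: tuple[int, ...]

    def __post_init__(self):
        if len(self.bits) != 7 or any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 7 binary flags")
        if sum(self.bits) == 0:
            raise ValueError("at least one bit must be set")
        if self.bits[0] == 1 and any(self.bits[1:]):
            raise ValueError("no-element bit excludes all other bits")

    def as_array(self) -> np.ndarray:
        return np.array(self.bits, dtype=float)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, b in zip(ELEMENT_NAMES, self.bits) if b)


def _intrinsic_translation(R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Screw/glide vector of operation (R, t): averaging t over the cyclic
    group of R projects t onto R's invariant subspace. Components are
    reduced mod 1 so full lattice translations do not count."""
    order = _rotation_order(R)
    P = sum(np.linalg.matrix_power(R, k) for k in range(order))
    intrinsic = (P @ t) / order
    intrinsic -= np.round(intrinsic)
    return intrinsic


def _rotation_order(R: np.ndarray) -> int:
    order = 1
    M = np.array(R, dtype=float)
    while not np.allclose(M, np.eye(3), atol=_TOL):
        M = M @ R
        order += 1
        if order > 12:
            raise ValueError("not a crystallographic rotation part")
    return order


def classify_operation(R: np.ndarray, t: np.ndarray) -> str | None:
    """Classify one symmetry operation into an element type name.

    Returns None for the identity (and pure lattice translations).
    """
    R = np.asarray(R, dtype=float)
    t = np.asarray(t, dtype=float)
    det = np.linalg.det(R)
    if np.allclose(R, np.eye(3), atol=_TOL):
        return None  # identity / pure translation
    if np.allclose(R, -np.eye(3), atol=_TOL):
        return "inversion_center"
    intrinsic = _intrinsic_translation(R, t)
    has_intrinsic = np.max(np.abs(intrinsic)) > 1e-5
    if det > 0:
        return "screw_axis" if has_intrinsic else "rotation_axis"
    # improper operation, not inversion: mirror if -R is a 2-fold rotation
    if _rotation_order(-R) == 2:
        return "glide_plane" if has_intrinsic else "mirror_plane"
    return "rotoinversion_axis"


def _group_ops(space_group_number: int) -> list[tuple[np.ndarray, np.ndarray]]:
    if not 1 <= int(space_group_number) <= 230:
        raise ValueError(f"space group number must be in 1..230, got {space_group_number}")
    sg = gemmi.find_spacegroup_by_number(int(space_group_number))
    den = float(gemmi.Op.DEN)
    ops = []
    for op in sg.operations():  # iteration expands centering vectors
        ops.append((np.array(op.rot, dtype=float) / den,
                    np.array(op.tran, dtype=float) / den))
    return ops


def symmetry_elements(space_group_number: int) -> SymmetryElementLabel:
    """Symmetry-element multi-hot label of a space group (1–230)."""
    bits = [0] * 7
    for R, t in _group_ops(space_group_number):
        name = classify_operation(R, t)
        if name is not None:
            bits[ELEMENT_NAMES.index(name)] = 1
    if sum(bits) == 0:
        bits[0] = 1
    return SymmetryElementLabel(tuple(bits))


def full_label_table() -> dict[int, tuple[int, ...]]:
    """Labels for all 230 space groups (standard settings)."""
    return {n: symmetry_elements(n).bits for n in range(1, 231)}


def export_label_table(path: str | Path) -> None:
    """Write the 230-group label table as JSON (bit order documented)."""
    table = {str(n): list(bits) for n, bits in full_label_table().items()}
    payload = {"bit_order": list(ELEMENT_NAMES), "labels": table}
    Path(path).write_text(json.dumps(payload, indent=1))


def element_weights(frequencies, epsilon: float = 1.1) -> np.ndarray:
    """Class-balancing weights for the SEP loss: w_i ∝ p_i^(−1/ε).

    p_i are the per-element occurrence proportions over the training set;
    add-one smoothing is applied to zero counts. Weights are normalised to
    mean 1, are strictly decreasing in frequency, and flatten to uniform as
    ε → ∞. ε ≥ 1 (default 1.1) damps extreme weights for rare elements.
    """
    if epsilon < 1:
        raise ValueError("epsilon must be >= 1")
    x = np.asarray(frequencies, dtype=float)
    if np.any(x < 0):
        raise ValueError("frequencies must be non-negative")
    x = np.where(x == 0, x + 1.0, x)
    p = x / x.sum()
    w = p ** (-1.0 / epsilon)
    return w / w.mean()


def sep_exact_match(pred_probs, label: SymmetryElementLabel | np.ndarray,
                    threshold: float = 0.5) -> bool:
    """Exact-match metric of the SEP task: every thresholded probability
    must equal the label bit."""
    p = np.asarray(pred_probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    target = label.as_array() if isinstance(label, SymmetryElementLabel) else np.asarray(label, float)
    return bool(np.array_equal((p > threshold).astype(float), target))


# -- coordinate-based detection (oracle-style helper) ----------------------


def _op_maps_structure(s, R: np.ndarray, t: np.ndarray, tol: float) -> bool:
    imgs = s.frac_coords @ R.T + t
    for el, img in zip(s.elements, imgs):
        d = s.frac_coords - img
        d -= np.round(d)
        match = (np.max(np.abs(d), axis=1) < tol)
        if not any(match[i] and s.elements[i] == el for i in np.nonzero(match)[0]):
            return False
    return True


def detect_space_group(s, tol: float = 1e-3) -> int:
    """Detect the space group of a P1 structure by testing, for every group
    whose operations preserve the cell metric, whether all its operations
    (in the standard setting, origin as given) map the atom set onto itself.

    Returns the matching group with the largest operation count. Intended
    for structures generated in standard settings (e.g. the fixture
    generator); a general-purpose symmetry finder with origin/setting search
    is out of scope.
    """
    G = s.lattice @ s.lattice.T
    best, best_size = 1, 1
    for number in range(1, 231):
        ops = _group_ops(number)
        ok = True
        for R, t in ops:
            # metric compatibility: fractional op must be a cartesian isometry
            if not np.allclose(R.T @ G @ R, G, atol=1e-6 * np.abs(G).max()):
                ok = False
                break
            if not _op_maps_structure(s, R, t, tol):
                ok = False
                break
        if ok and len(ops) > best_size:
            best, best_size = number, len(ops)
    return best
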