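"""Geometric collective variables for receptor/ligand bead systems.

Implements the CVs the binding analysis is built on:

* ``com_distance`` — distance *d* between two groups' centers of mass;
* ``axis_torsion`` — dihedral φ (or ψ) between the major inertia axes of
  two groups, constructed as a four-point dihedral with the COM–COM vector
  as the central bond;
* ``projection_on_axis`` (POA) — signed projection of a group's COM on the
  oriented major inertia axis of the receptor;
* ``distance_from_axis`` (DFA) — perpendicular distance from that axis;

plus the half-harmonic upper wall used to confine the unbound state and a
uniform finite-difference gradient facility used when a CV is biased.

The "major inertia axis" is the long axis: the eigenvector of the
mass-weighted inertia tensor with the smallest eigenvalue.  Its sign is
fixed by a named reference bead pair (by convention 5'-end bead to 3'-end
bead, so the 3' side of the receptor is the positive POA direction); a
near-degenerate smallest eigenvalue raises an explicit error rather than
returning an arbitrary axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AtomGroup",
    "AxisDegeneracyError",
    "CVSpec",
    "CVValue",
    "WallSpec",
    "axis_torsion",
    "center_of_mass",
    "com_distance",
    "cv_gradient",
    "distance_from_axis",
    "evaluate_cv",
    "major_inertia_axis",
    "projection_on_axis",
    "wall_energy",
]

_CV_KINDS = ("com_distance", "axis_torsion", "projection_on_axis",
             "distance_from_axis")


class AxisDegeneracyError(ValueError):
    """The two smallest inertia eigenvalues are too close to define an axis."""


class UndefinedTorsionError(ValueError):
    """The torsion is geometrically undefined (coincident centers of mass)."""


@dataclass
class AtomGroup:
    """A named selection of beads with their masses."""

    indices: np.ndarray
    masses: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.indices.size == 0:
            raise ValueError(f"atom group {self.label!r} is empty")
        if self.indices.size != self.masses.size:
            raise ValueError("indices and masses must have equal length")
        if np.any(self.masses <= 0):
            raise ValueError("atom masses must be positive")


@dataclass
class CVSpec:
    """Declarative CV definition: kind, groups, axis owner and orientation.

    ``orientation_reference`` is a pair of bead indices (i, j); the vector
    from bead i to bead j fixes the sign of any inertia axis involved.  For
    ``axis_torsion`` two references are needed (one per group).
    """

    kind: str
    groups: Sequence[AtomGroup]
    label: str = ""
    orientation_reference: tuple[int, int] | None = None
    orientation_reference_2: tuple[int, int] | None = None
    periodic: bool = False
    units: str = "A"

    def __post_init__(self):
        if self.kind not in _CV_KINDS:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        n = len(self.groups)
        if self.kind == "com_distance" and n != 2:
            raise ValueError("com_distance requires two groups")
        if self.kind == "axis_torsion":
            if n != 2:
                raise ValueError("axis_torsion requires two groups")
            if self.orientation_reference is None \
                    or self.orientation_reference_2 is None:
                raise ValueError("axis_torsion requires two orientation "
                                 "references (one per axis)")
            if not self.periodic:
                raise ValueError("axis_torsion must be declared periodic")
        if self.kind in ("projection_on_axis", "distance_from_axis"):
            if n != 2:
                raise ValueError(f"{self.kind} requires a point group and "
                                 "an axis-owner group")
            if self.orientation_reference is None:
                raise ValueError(f"{self.kind} requires an orientation "
                                 "reference for the axis")
        if not self.label:
            self.label = self.kind


@dataclass
class CVValue:
    label: str
    value: float
    units: str = "A"

    def __post_init__(self):
        if self.units == "rad":
            if not (-np.pi < self.value <= np.pi + 1e-12):
                raise ValueError(f"torsion value {self.value} outside (-pi, pi]")
        elif self.value < 0 and self.label != "projection_on_axis" \
                and not self.label.lower().startswith("poa"):
            # distance-type CVs are non-negative; POA is signed
            if self.value < -1e-12:
                raise ValueError(f"distance CV {self.label!r} negative")


@dataclass
class WallSpec:
    """Half-harmonic upper wall on a CV (default: 27.0 Å limit on d)."""

    cv_label: str = "d"
    limit: float = 27.0           # Å
    spring: float = 10.0          # kcal/mol/Å^2

    def __post_init__(self):
        if self.limit <= 0:
            raise ValueError("wall limit must be positive")
        if self.spring <= 0:
            raise ValueError("wall spring constant must be positive")


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def center_of_mass(group: AtomGroup, coords: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position of the group, Å."""
    coords = np.asarray(coords, dtype=float)
    sel = coords[group.indices]
    return group.masses @ sel / group.masses.sum()


def major_inertia_axis(group: AtomGroup, coords: np.ndarray,
                       orientation_reference: tuple[int, int],
                       degeneracy_rtol: float = 1e-6) -> np.ndarray:
    """Oriented long axis: smallest-eigenvalue eigenvector of the inertia
    tensor, with sign fixed by the reference bead pair (i -> j).

    Raises :class:`AxisDegeneracyError` when the relative gap between the
    two smallest eigenvalues is below ``degeneracy_rtol`` — an arbitrary
    axis would make downstream CVs silently meaningless.
    """
    coords = np.asarray(coords, dtype=float)
    sel = coords[group.indices]
    if len(sel) < 2:
        raise ValueError("inertia axis needs at least two beads")
    com = group.masses @ sel / group.masses.sum()
    rel = sel - com
    if np.max(np.linalg.norm(rel, axis=1)) < 1e-12:
        raise ValueError("all beads collocated; inertia axis undefined")
    r2 = np.sum(rel ** 2, axis=1)
    inertia = (np.einsum("i,i,jk->jk", group.masses, r2, np.eye(3))
               - np.einsum("i,ij,ik->jk", group.masses, rel, rel))
    evals, evecs = np.linalg.eigh(inertia)      # ascending eigenvalues
    scale = max(evals[-1], 1e-300)
    if (evals[1] - evals[0]) / scale < degeneracy_rtol:
        raise AxisDegeneracyError(
            f"smallest inertia eigenvalues degenerate for group "
            f"{group.label!r}: {evals[0]:.6g} vs {evals[1]:.6g}")
    axis = evecs[:, 0]
    i, j = orientation_reference
    ref = coords[j] - coords[i]
    if axis @ ref < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def com_distance(g1: AtomGroup, g2: AtomGroup, coords: np.ndarray) -> float:
    """Distance d between the two groups' centers of mass (symmetric)."""
    return float(np.linalg.norm(center_of_mass(g1, coords)
                                - center_of_mass(g2, coords)))


def _dihedral(p0, p1, p2, p3) -> float:
    """Four-point dihedral in (-pi, pi], IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1)
    x = n1 @ n2
    y = np.cross(n1, n2) @ b1n
    ang = float(np.arctan2(y, x))
    if ang <= -np.pi:
        ang += 2 * np.pi
    return ang


def axis_torsion(g1: AtomGroup, g2: AtomGroup, coords: np.ndarray,
                 orientation_ref_1: tuple[int, int],
                 orientation_ref_2: tuple[int, int]) -> float:
    """Dihedral between the oriented major inertia axes of two groups.

    Realised as the four-point dihedral (com1 + axis1, com1, com2,
    com2 + axis2): the COM–COM vector is the central bond.  Periodic in
    (-pi, pi].
    """
    axis1 = major_inertia_axis(g1, coords, orientation_ref_1)
    axis2 = major_inertia_axis(g2, coords, orientation_ref_2)
    com1 = center_of_mass(g1, coords)
    com2 = center_of_mass(g2, coords)
    if np.linalg.norm(com2 - com1) < 1e-8:
        raise UndefinedTorsionError(
            "centers of mass coincide; axis torsion undefined")
    return _dihedral(com1 + axis1, com1, com2, com2 + axis2)


def projection_on_axis(point_group: AtomGroup, axis_group: AtomGroup,
                       coords: np.ndarray,
                       orientation_reference: tuple[int, int]) -> float:
    """Signed projection (POA) of the point group's COM on the oriented
    major inertia axis of the axis-owner group; origin at the axis owner's
    COM, positive toward the orientation reference (the 3' side)."""
    axis = major_inertia_axis(axis_group, coords, orientation_reference)
    delta = (center_of_mass(point_group, coords)
             - center_of_mass(axis_group, coords))
    return float(delta @ axis)


def distance_from_axis(point_group: AtomGroup, axis_group: AtomGroup,
                       coords: np.ndarray,
                       orientation_reference: tuple[int, int]) -> float:
    """Perpendicular distance (DFA) of the point group's COM from the
    axis-owner's oriented major inertia axis; POA² + DFA² = |ΔCOM|²."""
    axis = major_inertia_axis(axis_group, coords, orientation_reference)
    delta = (center_of_mass(point_group, coords)
             - center_of_mass(axis_group, coords))
    perp = delta - (delta @ axis) * axis
    return float(np.linalg.norm(perp))


def evaluate_cv(spec: CVSpec, coords: np.ndarray) -> CVValue:
    """Evaluate a declared CV on a full coordinate set."""
    if spec.kind == "com_distance":
        v = com_distance(spec.groups[0], spec.groups[1], coords)
    elif spec.kind == "axis_torsion":
        v = axis_torsion(spec.groups[0], spec.groups[1], coords,
                         spec.orientation_reference,
                         spec.orientation_reference_2)
    elif spec.kind == "projection_on_axis":
        v = projection_on_axis(spec.groups[0], spec.groups[1], coords,
                               spec.orientation_reference)
    else:
        v = distance_from_axis(spec.groups[0], spec.groups[1], coords,
                               spec.orientation_reference)
    return CVValue(spec.label, v, spec.units)


def wall_energy(value: float, wall: WallSpec,
                label: str | None = None) -> tuple[float, float]:
    """Half-harmonic upper wall: (energy, dE/dCV).

    Zero below the limit, k (v - limit)^2 above; the derivative is
    continuous at the limit.
    """
    if label is not None and label != wall.cv_label:
        raise ValueError(f"wall targets CV {wall.cv_label!r}, got {label!r}")
    over = value - wall.limit
    if over <= 0:
        return 0.0, 0.0
    return wall.spring * over * over, 2.0 * wall.spring * over


def cv_gradient(spec: CVSpec, coords: np.ndarray,
                step: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of a CV w.r.t. all coordinates.

    Uniform for every CV kind (including the inertia-axis CVs, whose
    analytic eigenvector derivatives would add much complexity for no
    accuracy gain at this scale); accuracy is O(step^2) with the default
    step of 1e-5 Å.  Periodic CVs are differenced through the minimum
    image.
    """
    coords = np.asarray(coords, dtype=float)
    grad = np.zeros_like(coords)
    involved = np.unique(np.concatenate([g.indices for g in spec.groups]))
    for i in involved:
        for k in range(3):
            cp = coords.copy()
            cm = coords.copy()
            cp[i, k] += step
            cm[i, k] -= step
            vp = evaluate_cv(spec, cp).value
            vm = evaluate_cv(spec, cm).value
            diff = vp - vm
            if spec.periodic:
                diff = (diff + np.pi) % (2 * np.pi) - np.pi
            grad[i, k] = diff / (2.0 * step)
    return grad
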