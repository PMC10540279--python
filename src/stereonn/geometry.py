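"""Geometric descriptors of the Pd coordination environment in transition states.

A three-coordinate Pd transition-state complex (the phosphine P donor plus the
two substrate carbons undergoing C-C coupling) is characterised by how far the
metal puckers out of the donor plane ("planarity"), how much the projected
donor arrangement deviates from an ideal 120-degree Y shape ("Y-ness"), the
angle between the P-Pd bond and the metal's out-of-plane projection, and
ordinary bond lengths/angles.  Structures are exchanged as plain XYZ text; the
comment line may carry ``ligand=<id> role=<pro_R|pro_S>`` metadata.

All coordinates are in Angstrom and all angles are reported in degrees.
Donor atoms are supplied explicitly (:class:`DonorSet`) -- these complexes are
too specialised for generic bond perception, which is out of scope.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import DEGENERACY_TOL

__all__ = [
    "Role",
    "Structure",
    "DonorSet",
    "DescriptorValue",
    "XYZParseError",
    "DegenerateGeometryError",
    "parse_xyz",
    "write_xyz",
    "bond_length",
    "bond_angle",
    "best_fit_plane",
    "planarity",
    "projected_metal_angle",
    "y_ness",
    "compute_descriptors",
    "descriptors_to_csv",
    "DESCRIPTOR_REGISTRY",
]


class XYZParseError(ValueError):
    """Malformed XYZ input."""


class DegenerateGeometryError(ValueError):
    """Geometry does not admit the requested descriptor (collinear, coplanar...)."""


class Role(str, enum.Enum):
    """Which product enantiomer a transition state leads to."""

    pro_R = "pro_R"
    pro_S = "pro_S"


@dataclass
class Structure:
    """One transition-state geometry: element symbols + Cartesian coordinates (A)."""

    elements: list[str]
    coords: np.ndarray  # (n, 3) float array, Angstrom
    ligand_id: str | None = None
    role: Role | None = None
    comment: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.elements) != len(self.coords):
            raise ValueError(
                f"{len(self.elements)} elements but {len(self.coords)} coordinate rows"
            )
        if len(self.elements) < 4:
            raise ValueError("a transition-state structure needs at least 4 atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinate")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def metal_index(self, symbol: str = "Pd") -> int:
        """Index of the unique metal atom (raises unless exactly one)."""
        hits = [i for i, e in enumerate(self.elements) if e == symbol]
        if len(hits) != 1:
            raise ValueError(
                f"expected exactly one {symbol} atom, found {len(hits)}"
            )
        return hits[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Copy with coordinates rigidly moved: x -> R x + t."""
        new = np.asarray(self.coords) @ np.asarray(rotation).T + np.asarray(translation)
        return Structure(list(self.elements), new, self.ligand_id, self.role, self.comment)


@dataclass(frozen=True)
class DonorSet:
    """The metal atom plus its three donor atoms (P and the two substrate carbons)."""

    metal_index: int
    donor_indices: tuple[int, int, int]
    p_index: int

    def __post_init__(self) -> None:
        idx = (self.metal_index, *self.donor_indices)
        if len(set(idx)) != 4:
            raise ValueError("metal and donor indices must be distinct")
        if self.p_index not in self.donor_indices:
            raise ValueError("p_index must be one of the donor indices")

    def validate_for(self, s: Structure) -> None:
        for i in (self.metal_index, *self.donor_indices):
            if not (0 <= i < s.n_atoms):
                raise IndexError(f"atom index {i} out of range for {s.n_atoms} atoms")


@dataclass(frozen=True)
class DescriptorValue:
    name: str
    value: float
    units: str  # "A", "degrees" or "dimensionless"

    _ALLOWED_UNITS = ("A", "degrees", "dimensionless")

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"descriptor {self.name} is not finite")
        if self.units not in self._ALLOWED_UNITS:
            raise ValueError(f"units must be one of {self._ALLOWED_UNITS}")


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

def parse_xyz(text: str) -> Structure:
    """Parse a single-molecule XYZ block.

    Line 1 is the atom count, line 2 a free comment (optionally carrying
    ``ligand=<id> role=<pro_R|pro_S>`` tokens), then one ``element x y z``
    line per atom.
    """
    lines = text.splitlines()
    # strip trailing blank lines only; internal blanks are malformed
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise XYZParseError("empty XYZ input")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"line 1: expected an atom count, got {lines[0]!r}") from None
    if len(lines) < 2:
        raise XYZParseError("missing comment line")
    comment = lines[1]
    atom_lines = lines[2:]
    if len(atom_lines) != count:
        raise XYZParseError(
            f"declared {count} atoms but found {len(atom_lines)} atom lines"
        )
    elements: list[str] = []
    coords = np.empty((count, 3), dtype=float)
    for k, line in enumerate(atom_lines):
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"line {k + 3}: expected 'element x y z', got {line!r}")
        elements.append(parts[0])
        try:
            coords[k] = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"line {k + 3}: non-numeric coordinate in {line!r}") from None

    ligand_id = None
    role = None
    for token in comment.split():
        if token.startswith("ligand="):
            ligand_id = token[len("ligand="):]
        elif token.startswith("role="):
            try:
                role = Role(token[len("role="):])
            except ValueError:
                raise XYZParseError(f"unknown role {token!r} on comment line") from None
    return Structure(elements, coords, ligand_id=ligand_id, role=role, comment=comment)


def write_xyz(s: Structure, precision: int = 8) -> str:
    """Serialise a structure to XYZ text (round-trips through :func:`parse_xyz`)."""
    comment = s.comment
    meta = []
    if s.ligand_id is not None and "ligand=" not in comment:
        meta.append(f"ligand={s.ligand_id}")
    if s.role is not None and "role=" not in comment:
        meta.append(f"role={s.role.value}")
    if meta:
        comment = (" ".join(meta) + (" " + comment if comment else "")).rstrip()
    out = [str(s.n_atoms), comment]
    for el, (x, y, z) in zip(s.elements, s.coords):
        out.append(f"{el} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Elementary descriptors
# ---------------------------------------------------------------------------

def bond_length(s: Structure, i: int, j: int) -> float:
    """Euclidean distance (A) between atoms ``i`` and ``j``."""
    if i == j:
        raise ValueError("bond_length requires two distinct atoms")
    n = s.n_atoms
    for k in (i, j):
        if not (0 <= k < n):
            raise IndexError(f"atom index {k} out of range for {n} atoms")
    return float(np.linalg.norm(s.coords[i] - s.coords[j]))


def bond_angle(s: Structure, i: int, j: int, k: int) -> float:
    """Angle i-j-k (degrees) with vertex at atom ``j``."""
    if len({i, j, k}) != 3:
        raise ValueError("bond_angle requires three distinct atoms")
    n = s.n_atoms
    for m in (i, j, k):
        if not (0 <= m < n):
            raise IndexError(f"atom index {m} out of range for {n} atoms")
    u = s.coords[i] - s.coords[j]
    v = s.coords[k] - s.coords[j]
    return _vector_angle(u, v)


def _vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < DEGENERACY_TOL or nv < DEGENERACY_TOL:
        raise DegenerateGeometryError("zero-length arm vector: coincident atoms")
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


@dataclass(frozen=True)
class Plane:
    """Least-squares plane: unit normal and the centroid it passes through."""

    normal: np.ndarray
    centroid: np.ndarray

    def signed_distance(self, point: np.ndarray) -> float:
        return float(np.dot(np.asarray(point) - self.centroid, self.normal))

    def project(self, point: np.ndarray) -> np.ndarray:
        p = np.asarray(point, dtype=float)
        return p - self.signed_distance(p) * self.normal


def best_fit_plane(s: Structure, indices: Sequence[int]) -> Plane:
    """Total-least-squares plane through >=3 atoms.

    The normal is the eigenvector of the centred coordinate covariance with the
    smallest eigenvalue; for exactly three non-collinear points the plane
    contains them exactly.
    """
    if len(indices) < 3:
        raise ValueError("a plane needs at least 3 points")
    pts = s.coords[list(indices)]
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    # smallest right singular vector minimises sum of squared point-plane distances
    _, sing, vt = np.linalg.svd(centred, full_matrices=False)
    if sing[1] < DEGENERACY_TOL:
        raise DegenerateGeometryError("points are collinear; plane is undefined")
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    return Plane(normal=normal, centroid=centroid)


def planarity(s: Structure, d: DonorSet) -> float:
    """Out-of-plane displacement of Pd (A): unsigned distance of the metal from
    the plane through its three donor atoms.  Zero iff the complex is planar."""
    d.validate_for(s)
    plane = best_fit_plane(s, d.donor_indices)
    return abs(plane.signed_distance(s.coords[d.metal_index]))


def projected_metal_angle(s: Structure, d: DonorSet) -> float:
    """Angle (degrees) at the metal between the Pd->P bond and the Pd->projected-Pd
    direction, where projected-Pd is the foot of the metal's perpendicular onto the
    donor plane.  Undefined (raises) when the metal lies in the plane."""
    d.validate_for(s)
    plane = best_fit_plane(s, d.donor_indices)
    pd = s.coords[d.metal_index]
    h = plane.signed_distance(pd)
    if abs(h) < DEGENERACY_TOL:
        raise DegenerateGeometryError(
            "Pd lies in the donor plane; the projected-Pd angle is undefined. "
            "Use planarity to test for coplanarity first."
        )
    foot = pd - h * plane.normal
    return _vector_angle(s.coords[d.p_index] - pd, foot - pd)


def y_ness(s: Structure, d: DonorSet) -> float:
    """Deviation from an ideal Y-shaped complex (degrees).

    The metal and donors are projected onto the donor best-fit plane; the three
    donor-Pd-donor angles are measured there and the L1 deviation from 120 deg,
    ``sum_i |theta_i - 120|``, is returned.  Zero iff the projected complex is a
    perfect trigonal Y.
    """
    d.validate_for(s)
    plane = best_fit_plane(s, d.donor_indices)
    pd_proj = plane.project(s.coords[d.metal_index])
    arms = []
    for i in d.donor_indices:
        v = plane.project(s.coords[i]) - pd_proj
        if np.linalg.norm(v) < DEGENERACY_TOL:
            raise DegenerateGeometryError(
                f"donor atom {i} projects onto the metal position"
            )
        arms.append(v)
    pairs = [(0, 1), (1, 2), (2, 0)]
    total = 0.0
    for a, b in pairs:
        total += abs(_vector_angle(arms[a], arms[b]) - 120.0)
    return total


# ---------------------------------------------------------------------------
# Batch descriptor extraction
# ---------------------------------------------------------------------------

#: name -> (callable(structure, donorset) -> value, units)
DESCRIPTOR_REGISTRY = {
    "planarity": (planarity, "A"),
    "y_ness": (y_ness, "degrees"),
    "projected_metal_angle": (projected_metal_angle, "degrees"),
}


def compute_descriptors(
    pair: tuple[Structure, Structure],
    d: DonorSet,
    spec: Iterable[str],
) -> list[DescriptorValue]:
    """Evaluate the requested registry descriptors on a (pro_R, pro_S) pair.

    Returns one value per descriptor per role, named ``<descriptor>_proR`` /
    ``<descriptor>_proS``, ordered by (descriptor name, role).
    """
    pro_r, pro_s = pair
    if pro_r.ligand_id != pro_s.ligand_id:
        raise ValueError(
            f"mismatched ligand ids: {pro_r.ligand_id!r} vs {pro_s.ligand_id!r}"
        )
    requested = list(spec)
    for name in requested:
        if name not in DESCRIPTOR_REGISTRY:
            raise KeyError(f"unknown descriptor {name!r}")
    out: list[DescriptorValue] = []
    for name in sorted(requested):
        func, units = DESCRIPTOR_REGISTRY[name]
        for suffix, struct in (("proR", pro_r), ("proS", pro_s)):
            try:
                value = func(struct, d)
            except Exception as exc:
                raise type(exc)(
                    f"ligand {pro_r.ligand_id!r} ({suffix}): {exc}"
                ) from exc
            out.append(DescriptorValue(f"{name}_{suffix}", float(value), units))
    return out


def descriptors_to_csv(records: dict[str, list[DescriptorValue]]) -> str:
    """Long-format CSV: ligand_id, descriptor, role, value, units."""
    lines = ["ligand_id,descriptor,role,value,units"]
    for ligand_id in sorted(records):
        for dv in records[ligand_id]:
            base, _, role = dv.name.rpartition("_")
            lines.append(f"{ligand_id},{base},{role},{dv.value:.10g},{dv.units}")
    return "\n".join(lines) + "\n"
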