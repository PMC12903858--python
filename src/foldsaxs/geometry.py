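"""Per-frame structural descriptors.

Radius of gyration (mass- or electron-weighted), IUPAC signed torsions for
glycosidic Φ/Ψ analysis, CH···O hydrogen-bond geometry, and inter-residue
minimum distances. Lengths in nm, angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .elements import electron_count
from .models import TrajectoryFrames, ValidationError

__all__ = [
    "RgSeries",
    "HBondGeometry",
    "DihedralSeries",
    "radius_of_gyration",
    "rg_series",
    "dihedral",
    "dihedral_series",
    "hbond_geometry",
    "hbond_occupancy_map",
    "min_interresidue_distance",
]

#: favourable CH···O contact: C–O distance strictly below this, nm
HBOND_DISTANCE_CUTOFF_NM = 0.4
#: ... and C–H···O angle strictly above this, degrees
HBOND_ANGLE_CUTOFF_DEG = 150.0


@dataclass
class RgSeries:
    """Per-frame radius of gyration, nm."""

    values: np.ndarray
    weighting: str = "mass"  # {"mass", "electron"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError("Rg values must be >= 0")
        if self.weighting not in ("mass", "electron"):
            raise ValidationError(f"weighting must be 'mass' or 'electron', got {self.weighting!r}")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class HBondGeometry:
    """Geometry of one C–H···O contact."""

    donor_acceptor_distance: float  # C to O, nm
    dha_angle: float  # C–H···O angle at H, degrees
    favorable: bool


@dataclass
class DihedralSeries:
    """Per-frame glycosidic torsion pair, degrees in (−180, 180]."""

    phi: np.ndarray
    psi: np.ndarray
    atom_quadruples: tuple[tuple[int, int, int, int], tuple[int, int, int, int]]

    def __post_init__(self) -> None:
        for quad in self.atom_quadruples:
            if len(set(quad)) != 4:
                raise ValidationError(f"dihedral quadruple must have 4 distinct indices: {quad}")


def radius_of_gyration(frame: np.ndarray, weights: np.ndarray) -> float:
    """Weighted radius of gyration of one coordinate set.

    Rg² = Σ w_i |r_i − r̄|² / Σ w_i with r̄ the weighted centroid.
    """
    frame = np.asarray(frame, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3 or frame.shape[0] < 1:
        raise ValidationError("frame must be N x 3 with N >= 1")
    if weights.shape != (frame.shape[0],) or np.any(weights < 0):
        raise ValidationError("weights must be per-atom and >= 0")
    total = weights.sum()
    if total <= 0:
        raise ValidationError("weights must have positive sum")
    center = (weights[:, None] * frame).sum(axis=0) / total
    sq = ((frame - center) ** 2).sum(axis=1)
    return float(np.sqrt((weights * sq).sum() / total))


def _weights_for(traj: TrajectoryFrames, weighting: str) -> np.ndarray:
    if weighting == "mass":
        return traj.model.masses()
    if weighting == "electron":
        return np.array([electron_count(a.element) for a in traj.model.atoms], dtype=float)
    raise ValidationError(f"weighting must be 'mass' or 'electron', got {weighting!r}")


def rg_series(traj: TrajectoryFrames, weighting: str = "mass") -> RgSeries:
    """Radius of gyration for every frame, order preserved.

    Mass weighting matches the MD-analysis convention; electron weighting is
    the SAXS-comparable variant (Guinier Rg probes electron density).
    """
    w = _weights_for(traj, weighting)
    values = np.array([radius_of_gyration(f, w) for f in traj.frames])
    return RgSeries(values, weighting)


def dihedral(p1, p2, p3, p4) -> float:
    """IUPAC signed torsion angle of four points, degrees in (−180, 180].

    φ = atan2((n1 × n2)·b̂2, n1·n2) with b1 = p2−p1, b2 = p3−p2, b3 = p4−p3,
    n1 = b1×b2, n2 = b2×b3.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0:
        raise ValidationError("central bond p2-p3 has zero length")
    if np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise ValidationError("undefined torsion: three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / b2n))
    angle = np.degrees(np.arctan2(y, x))
    return 180.0 if angle == -180.0 else float(angle)


def dihedral_series(
    traj: TrajectoryFrames,
    phi_atoms: Sequence[int],
    psi_atoms: Sequence[int],
) -> DihedralSeries:
    """Glycosidic Φ/Ψ torsions over a trajectory.

    ``phi_atoms``/``psi_atoms`` are 4-tuples of atom indices, conventionally
    Φ: O5′-C1′-O2-C2 and Ψ: C1′-O2-C2-C1 for a 1→2 linkage.
    """
    phi_atoms = tuple(int(i) for i in phi_atoms)
    psi_atoms = tuple(int(i) for i in psi_atoms)
    for quad in (phi_atoms, psi_atoms):
        if len(quad) != 4 or len(set(quad)) != 4:
            raise ValidationError(f"need 4 distinct atom indices, got {quad}")
        if any(i < 0 or i >= traj.model.n_atoms for i in quad):
            raise ValidationError(f"atom index out of range in {quad}")
    phi = np.array([dihedral(*(f[i] for i in phi_atoms)) for f in traj.frames])
    psi = np.array([dihedral(*(f[i] for i in psi_atoms)) for f in traj.frames])
    return DihedralSeries(phi, psi, (phi_atoms, psi_atoms))


def hbond_geometry(c, h, o) -> HBondGeometry:
    """CH···O contact geometry: C–O distance and the C–H···O angle at H.

    The contact is favourable iff the distance is strictly below 0.4 nm and
    the angle strictly above 150° (near-linear weak hydrogen bond).
    """
    c, h, o = (np.asarray(p, dtype=float) for p in (c, h, o))
    v1 = c - h
    v2 = o - h
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValidationError("C, H, O positions must be pairwise distinct at H")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    distance = float(np.linalg.norm(c - o))
    favorable = distance < HBOND_DISTANCE_CUTOFF_NM and angle > HBOND_ANGLE_CUTOFF_DEG
    return HBondGeometry(distance, angle, favorable)


def hbond_occupancy_map(
    traj: TrajectoryFrames, c_idx: int, h_idx: int, o_idx: int, stride: int = 1
) -> tuple[list[HBondGeometry], float]:
    """Per-frame CH···O geometries and the favourable-frame fraction."""
    n = traj.model.n_atoms
    for idx in (c_idx, h_idx, o_idx):
        if not 0 <= idx < n:
            raise ValidationError(f"atom index {idx} out of range [0, {n})")
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    geoms = [hbond_geometry(f[c_idx], f[h_idx], f[o_idx]) for f in traj.frames[::stride]]
    fraction = sum(g.favorable for g in geoms) / len(geoms)
    return geoms, fraction


def min_interresidue_distance(
    frame: np.ndarray, residue_a: Sequence[int], residue_b: Sequence[int]
) -> float:
    """Minimum pairwise distance (nm) between two disjoint atom index sets."""
    a = list(residue_a)
    b = list(residue_b)
    if not a or not b:
        raise ValidationError("atom sets must be non-empty")
    if set(a) & set(b):
        raise ValidationError("atom sets must be disjoint")
    frame = np.asarray(frame, dtype=float)
    return float(cdist(frame[a], frame[b]).min())


def export_hbond_map(geoms: Sequence[HBondGeometry], path: str) -> None:
    """Write (distance nm, angle deg) pairs as 2-column ASCII for plotting."""
    with open(path, "w") as fh:
        fh.write("# C-O_distance[nm]  C-H...O_angle[deg]\n")
        for g in geoms:
            fh.write(f"{g.donor_acceptor_distance:.6f} {g.dha_angle:.4f}\n")
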