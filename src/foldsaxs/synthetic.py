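"""Synthetic two-state trajectories and pseudo-experimental SAXS curves.

Real flexible foldamers interconvert between a compact folded conformer and
extended unfolded chains on nanosecond timescales. The generator emulates
exactly that structure — and nothing chemical beyond it — with a bead
chain of alternating C/O atoms whose folded template is a two-leg hairpin
and whose unfolded template is a straight chain, switching states along a
two-state Markov chain with prescribed stationary occupancy and mean dwell
time, plus Gaussian coordinate jitter. Every pipeline stage can therefore
be exercised against known ground truth (per-frame state labels, mixing
weights) without any external download.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .elements import atomic_mass
from .models import (
    Atom,
    MolecularModel,
    ScatteringCurve,
    TrajectoryFrames,
    ValidationError,
)

__all__ = [
    "TwoStateSpec",
    "generate_two_state_trajectory",
    "generate_pseudo_experiment",
    "rigid_reference_shapes",
    "hairpin_template",
    "extended_template",
]


@dataclass
class TwoStateSpec:
    """Ground-truth parameters of a synthetic two-state foldamer.

    Defaults describe an 18-bead chain at glycosidic spacing (0.5 nm bond),
    folding into an antiparallel hairpin with 0.45 nm strand separation,
    75% folded occupancy and 5 ns mean dwell — long against the 1 ns
    interval used downstream, so interval averaging is meaningful.
    """

    n_atoms: int = 18
    bond_length: float = 0.5  # nm
    folded_geometry: str = "hairpin_fold"
    unfolded_geometry: str = "extended"
    occupancy_folded: float = 0.75
    mean_dwell: float = 5.0  # ns per state (visit-averaged)
    jitter_sd: float = 0.05  # nm
    strand_separation: float = 0.45  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy_folded <= 1.0:
            raise ValidationError("occupancy_folded must be in [0, 1]")
        if self.n_atoms < 4:
            raise ValidationError("need at least 4 beads")
        if self.bond_length <= 0 or self.strand_separation <= 0:
            raise ValidationError("lengths must be > 0")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")
        if self.folded_geometry != "hairpin_fold" or self.unfolded_geometry != "extended":
            raise ValidationError("templates: folded_geometry='hairpin_fold', unfolded_geometry='extended'")


def _bead_atoms(n_atoms: int) -> list[Atom]:
    atoms = []
    for i in range(n_atoms):
        el = "C" if i % 2 == 0 else "O"
        atoms.append(Atom(f"{el}{i + 1}", el, atomic_mass(el), residue_id=i + 1, residue_name="BEA"))
    return atoms


def extended_template(n_atoms: int, bond_length: float) -> np.ndarray:
    """Straight chain along x, centred at the origin (nm)."""
    x = (np.arange(n_atoms) - (n_atoms - 1) / 2.0) * bond_length
    return np.column_stack([x, np.zeros(n_atoms), np.zeros(n_atoms)])


def hairpin_template(n_atoms: int, bond_length: float, strand_separation: float) -> np.ndarray:
    """Two antiparallel legs joined at a turn, centred at the origin (nm)."""
    half = n_atoms // 2
    coords = np.zeros((n_atoms, 3))
    for i in range(n_atoms):
        if i < half:
            coords[i] = (i * bond_length, 0.0, 0.0)
        else:
            # second leg runs back antiparallel, offset in y
            coords[i] = ((n_atoms - 1 - i) * bond_length, strand_separation, 0.0)
    return coords - coords.mean(axis=0)


def _markov_labels(
    n_frames: int, occupancy: float, mean_dwell: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-state {1 = folded, 0 = unfolded} chain with stationary occupancy.

    State dwell times are τ_fc = 2·p·m and τ_uf = 2·(1−p)·m for mean dwell m
    and occupancy p, giving the requested stationary distribution with
    visit-averaged dwell m when p = ½.
    """
    if occupancy in (0.0, 1.0):
        warnings.warn(
            f"occupancy_folded = {occupancy}: degenerate single-state trajectory",
            stacklevel=3,
        )
        return np.full(n_frames, int(occupancy))
    tau_f = 2.0 * occupancy * mean_dwell
    tau_u = 2.0 * (1.0 - occupancy) * mean_dwell
    p_leave_f = min(dt / tau_f, 1.0)
    p_leave_u = min(dt / tau_u, 1.0)
    labels = np.empty(n_frames, dtype=int)
    state = int(rng.random() < occupancy)
    for t in range(n_frames):
        labels[t] = state
        leave = p_leave_f if state == 1 else p_leave_u
        if rng.random() < leave:
            state = 1 - state
    return labels


def generate_two_state_trajectory(
    spec: TwoStateSpec, n_frames: int, frame_time_step: float
) -> tuple[TrajectoryFrames, np.ndarray]:
    """Generate a seeded bead-chain trajectory plus its true per-frame labels.

    Returns ``(trajectory, labels)`` with ``labels[t] = 1`` for folded
    frames. Fully reproducible: the same spec and sizes give bit-identical
    output.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    if frame_time_step <= 0:
        raise ValidationError("frame_time_step must be > 0 ns")
    if spec.mean_dwell < frame_time_step:
        raise ValidationError("mean_dwell must be >= frame_time_step")
    rng = np.random.default_rng(spec.seed)
    folded = hairpin_template(spec.n_atoms, spec.bond_length, spec.strand_separation)
    unfolded = extended_template(spec.n_atoms, spec.bond_length)
    labels = _markov_labels(n_frames, spec.occupancy_folded, spec.mean_dwell, frame_time_step, rng)
    frames = []
    for t in range(n_frames):
        template = folded if labels[t] == 1 else unfolded
        frames.append(template + rng.normal(0.0, spec.jitter_sd, size=template.shape))
    model = MolecularModel(_bead_atoms(spec.n_atoms), frames[0])
    return TrajectoryFrames(model, frames, frame_time_step), labels


def generate_pseudo_experiment(
    state_curves: Mapping[str, ScatteringCurve],
    weights: Mapping[str, float],
    scale: float = 1.0,
    background: float = 0.0,
    noise_fraction: float = 0.02,
    seed: Optional[int] = None,
) -> ScatteringCurve:
    """Pseudo-experimental curve: scaled mixture plus proportional noise.

    I_exp(q) = scale·Σ_s w_s I_s(q) + background + ε, ε ~ N(0, noise_fraction·I),
    with the σ column set to the true noise level noise_fraction·I. Weights
    must be on the simplex and name-match the state curves.
    """
    if set(weights) != set(state_curves):
        raise ValidationError(
            f"weight names {sorted(weights)} do not match curve names {sorted(state_curves)}"
        )
    w = np.array([weights[k] for k in state_curves], dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("weights must be non-negative and sum to 1")
    if noise_fraction < 0:
        raise ValidationError("noise_fraction must be >= 0")
    curves = list(state_curves.values())
    q = curves[0].q
    for c in curves[1:]:
        if c.q.shape != q.shape or not np.allclose(c.q, q):
            raise ValidationError("state curves must share one q grid")
    clean = scale * sum(wk * c.intensity for wk, c in zip(w, curves)) + background
    noise_sd = noise_fraction * np.abs(clean)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        intensity = clean + rng.normal(0.0, 1.0, size=clean.shape) * noise_sd
        sigma = np.maximum(noise_sd, np.finfo(float).tiny)
    else:
        intensity = clean
        sigma = None
    return ScatteringCurve(q.copy(), intensity, sigma, meta={"true_weights": dict(weights)})


def rigid_reference_shapes(kind: str, **params) -> MolecularModel:
    """Deterministic reference geometries with closed-form Rg.

    ``rod(n_beads, spacing)``: collinear beads, Rg = spacing·√((n²−1)/12);
    ``two_points(distance)``: Rg = distance/2;
    ``ring(n_beads, radius)``: Rg → radius for many beads;
    ``gaussian_blob(n_beads, rg, seed)``: beads drawn from an isotropic
    Gaussian density of the requested Rg (nm) — the one shape whose Guinier
    plot is exactly linear, so Guinier fits of its scattering recover the
    geometric Rg essentially without truncation bias.
    Beads are carbon unless ``element`` is given.
    """
    element = params.pop("element", "C")
    if kind == "rod":
        n = int(params.pop("n_beads", 9))
        spacing = float(params.pop("spacing", 0.5))
        if n < 2 or spacing <= 0:
            raise ValidationError("rod needs n_beads >= 2 and spacing > 0")
        coords = extended_template(n, spacing)
    elif kind == "two_points":
        d = float(params.pop("distance", 1.0))
        if d <= 0:
            raise ValidationError("two_points needs distance > 0")
        coords = np.array([[-d / 2, 0.0, 0.0], [d / 2, 0.0, 0.0]])
        n = 2
    elif kind == "ring":
        n = int(params.pop("n_beads", 12))
        radius = float(params.pop("radius", 1.0))
        if n < 3 or radius <= 0:
            raise ValidationError("ring needs n_beads >= 3 and radius > 0")
        theta = 2.0 * np.pi * np.arange(n) / n
        coords = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)])
    elif kind == "gaussian_blob":
        n = int(params.pop("n_beads", 200))
        rg = float(params.pop("rg", 1.3))
        seed = int(params.pop("seed", 0))
        if n < 10 or rg <= 0:
            raise ValidationError("gaussian_blob needs n_beads >= 10 and rg > 0")
        rng = np.random.default_rng(seed)
        coords = rng.normal(0.0, rg / np.sqrt(3.0), size=(n, 3))
        coords -= coords.mean(axis=0)
    else:
        raise ValidationError(f"unknown reference shape {kind!r} (rod, two_points, ring)")
    if params:
        raise ValidationError(f"unknown parameters for {kind}: {sorted(params)}")
    atoms = [
        Atom(f"{element}{i + 1}", element, atomic_mass(element), residue_id=1, residue_name="REF")
        for i in range(coords.shape[0])
    ]
    return MolecularModel(atoms, coords)
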