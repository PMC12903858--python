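"""Core domain containers shared across the package.

All internal lengths are nanometres; momentum transfer ``q`` is expressed
in inverse ångström (1 Å⁻¹ = 10 nm⁻¹) at every public interface, matching
the convention of small-angle scattering practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FoldsaxsError",
    "FormatError",
    "ValidationError",
    "EmptyInputError",
    "Atom",
    "MolecularModel",
    "TrajectoryFrames",
    "ScatteringCurve",
    "ANGSTROM_PER_NM",
]

#: 1 nm = 10 Å; q in Å⁻¹ times r in Å is dimensionless.
ANGSTROM_PER_NM = 10.0


class FoldsaxsError(Exception):
    """Base class for all package errors."""


class FormatError(FoldsaxsError):
    """A file did not parse under the expected dialect."""


class ValidationError(FoldsaxsError):
    """An argument violated a documented precondition."""


class EmptyInputError(FoldsaxsError):
    """An input contained no usable records."""


@dataclass(frozen=True)
class Atom:
    """A single atom of a molecular model.

    ``element`` is a recognised chemical symbol (an entry exists in the
    element table / form-factor table) unless ``unknown`` is set.
    """

    name: str
    element: str
    mass: float  # Da
    residue_id: int = 1
    residue_name: str = "UNK"
    unknown: bool = False

    def __post_init__(self) -> None:
        if not self.unknown and self.mass <= 0:
            raise ValidationError(f"atom {self.name!r}: mass must be > 0, got {self.mass}")


class MolecularModel:
    """Topology (ordered atoms) plus one coordinate set, in nm."""

    def __init__(self, atoms: Sequence[Atom], coordinates: np.ndarray):
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.ndim != 2 or coordinates.shape[1] != 3:
            raise ValidationError(f"coordinates must be N x 3, got shape {coordinates.shape}")
        if len(atoms) == 0:
            raise EmptyInputError("model has zero atoms")
        if coordinates.shape[0] != len(atoms):
            raise ValidationError(
                f"coordinate rows ({coordinates.shape[0]}) != atom count ({len(atoms)})"
            )
        if not np.all(np.isfinite(coordinates)):
            raise ValidationError("coordinates contain non-finite values")
        self.atoms = list(atoms)
        self.coordinates = coordinates

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def with_coordinates(self, coordinates: np.ndarray) -> "MolecularModel":
        return MolecularModel(self.atoms, coordinates)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<MolecularModel {self.n_atoms} atoms>"


class TrajectoryFrames:
    """A fixed topology with an ordered series of coordinate frames.

    Parameters
    ----------
    model:
        The topology; its own coordinates are frame 0's by convention of the
        readers but are not otherwise consulted.
    frames:
        Sequence of ``(n_atoms, 3)`` arrays, nm.
    frame_time_step:
        Time between consecutive frames, ns. Supplied by the user; structure
        files carry no reliable time metadata.
    """

    def __init__(self, model: MolecularModel, frames: Sequence[np.ndarray], frame_time_step: float):
        if frame_time_step <= 0:
            raise ValidationError(f"frame_time_step must be > 0 ns, got {frame_time_step}")
        if len(frames) == 0:
            raise EmptyInputError("trajectory has zero frames")
        checked = []
        for i, f in enumerate(frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (model.n_atoms, 3):
                raise FormatError(
                    f"frame {i}: expected {model.n_atoms} atoms, got {f.shape[0]}"
                )
            checked.append(f)
        self.model = model
        self.frames = checked
        self.frame_time_step = float(frame_time_step)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def subset(self, frame_indices: Sequence[int]) -> "TrajectoryFrames":
        """New trajectory restricted to the given frames (original order kept)."""
        return TrajectoryFrames(
            self.model, [self.frames[i] for i in frame_indices], self.frame_time_step
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<TrajectoryFrames {self.n_frames} frames x {self.model.n_atoms} atoms, "
            f"dt={self.frame_time_step} ns>"
        )


@dataclass
class ScatteringCurve:
    """A 1D scattering profile: I(q) with optional point-wise uncertainties.

    ``q`` is in Å⁻¹ and strictly increasing; ``sigma`` (when present) shares
    the intensity's (arbitrary) units and is strictly positive.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.intensity.shape != self.q.shape:
            raise ValidationError("q and intensity must be 1D arrays of equal length")
        if self.q.size == 0:
            raise EmptyInputError("scattering curve is empty")
        if np.any(self.q < 0):
            raise ValidationError("q values must be >= 0")
        if np.any(np.diff(self.q) <= 0):
            raise ValidationError("q must be strictly increasing (duplicates not allowed)")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValidationError("sigma length must match q")
            if np.any(self.sigma <= 0):
                raise ValidationError("sigma values must be > 0")

    def __len__(self) -> int:
        return self.q.size

    def copy(self) -> "ScatteringCurve":
        return ScatteringCurve(
            self.q.copy(),
            self.intensity.copy(),
            None if self.sigma is None else self.sigma.copy(),
            dict(self.meta),
        )
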