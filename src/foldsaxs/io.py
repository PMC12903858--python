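"""Readers and writers for structures, trajectories and scattering curves.

Supported dialects are deliberately small and fully text-based:

* PDB ``ATOM``/``HETATM`` records, with ``MODEL``/``ENDMDL`` blocks for
  trajectories (coordinates in Å, converted to nm on read);
* GRO single frames or concatenated frame series (already nm);
* 2- or 3-column whitespace-delimited ASCII scattering curves
  (``q [Å⁻¹]  I  [σ]``, ``#`` comments).
"""

from __future__ import annotations

import math
import os
from typing import Mapping, Optional

import numpy as np

from .elements import atomic_mass, infer_element
from .models import (
    ANGSTROM_PER_NM,
    Atom,
    EmptyInputError,
    FormatError,
    MolecularModel,
    ScatteringCurve,
    TrajectoryFrames,
    ValidationError,
)

__all__ = [
    "read_structure",
    "read_trajectory",
    "read_scattering_curve",
    "write_scattering_curve",
    "write_pdb_trajectory",
]


def _detect_format(path: str, format: Optional[str]) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt not in ("pdb", "gro"):
            raise ValidationError(f"unsupported structure format {format!r} (pdb or gro)")
        return fmt
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("pdb", "gro"):
        return ext
    raise ValidationError(f"cannot infer format from {path!r}; pass format='pdb'|'gro'")


def _make_atom(
    name: str,
    element_field: str,
    residue_id: int,
    residue_name: str,
    overrides: Optional[Mapping[str, str]],
    lineno: int,
    allow_unknown: bool,
) -> Atom:
    element = element_field.strip()
    # Normalise PDB-style upper-case two-letter symbols (CL -> Cl).
    if element:
        element = element[0].upper() + element[1:].lower()
    else:
        element = infer_element(name, overrides) or ""
    if not element:
        if allow_unknown:
            return Atom(name.strip(), "X", 0.0, residue_id, residue_name, unknown=True)
        raise FormatError(
            f"line {lineno}: cannot infer element for atom name {name!r}; "
            "supply element_overrides or allow_unknown=True"
        )
    try:
        mass = atomic_mass(element)
    except ValidationError:
        if allow_unknown:
            return Atom(name.strip(), element, 0.0, residue_id, residue_name, unknown=True)
        raise FormatError(f"line {lineno}: unrecognised element {element!r} for atom {name!r}")
    return Atom(name.strip(), element, mass, residue_id, residue_name)


def _parse_pdb_models(
    text: str,
    overrides: Optional[Mapping[str, str]],
    allow_unknown: bool,
) -> list[tuple[list[Atom], np.ndarray]]:
    """Parse a (possibly multi-model) PDB into per-model (atoms, coords nm)."""
    models: list[tuple[list[Atom], np.ndarray]] = []
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    in_model = False

    def flush() -> None:
        nonlocal atoms, coords
        if atoms:
            models.append((atoms, np.asarray(coords) / ANGSTROM_PER_NM))
        atoms, coords = [], []

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            flush()
            in_model = True
        elif rec == "ENDMDL":
            flush()
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise FormatError(f"line {lineno}: truncated {rec} record")
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric coordinate field") from None
            name = line[12:16]
            residue_name = line[17:20].strip() or "UNK"
            try:
                residue_id = int(line[22:26])
            except ValueError:
                residue_id = 1
            element_field = line[76:78] if len(line) >= 78 else ""
            atoms.append(
                _make_atom(name, element_field, residue_id, residue_name, overrides, lineno, allow_unknown)
            )
            coords.append([x, y, z])
    flush()
    del in_model
    return models


def _parse_gro_frames(text: str) -> list[tuple[list[tuple[str, int, str]], np.ndarray]]:
    """Parse a concatenated GRO series into per-frame (name records, coords nm)."""
    lines = text.splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if i + 1 >= len(lines):
            raise FormatError(f"line {i + 1}: truncated GRO frame (missing atom count)")
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError:
            raise FormatError(f"line {i + 2}: expected atom count, got {lines[i + 1]!r}") from None
        start = i + 2
        if start + n_atoms + 1 > len(lines):
            raise FormatError(f"line {i + 1}: GRO frame declares {n_atoms} atoms but file ends early")
        records = []
        coords = []
        for k in range(n_atoms):
            line = lines[start + k]
            lineno = start + k + 1
            if len(line) < 44:
                raise FormatError(f"line {lineno}: truncated GRO atom line")
            try:
                resid = int(line[0:5])
            except ValueError:
                resid = 1
            resname = line[5:10].strip() or "UNK"
            name = line[10:15].strip()
            try:
                coords.append([float(line[20:28]), float(line[28:36]), float(line[36:44])])
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric coordinate field") from None
            records.append((name, resid, resname))
        frames.append((records, np.asarray(coords)))
        i = start + n_atoms + 1  # skip box line
    return frames


def read_structure(
    path: str,
    format: Optional[str] = None,
    element_overrides: Optional[Mapping[str, str]] = None,
    allow_unknown: bool = False,
) -> MolecularModel:
    """Read a single structure from a PDB or GRO file.

    The element column wins when present; otherwise the element is inferred
    from the atom name. Coordinates are returned in nm.
    """
    fmt = _detect_format(path, format)
    with open(path) as fh:
        text = fh.read()
    if fmt == "pdb":
        models = _parse_pdb_models(text, element_overrides, allow_unknown)
        if not models:
            raise EmptyInputError(f"{path}: no ATOM/HETATM records found")
        atoms, coords = models[0]
        return MolecularModel(atoms, coords)
    frames = _parse_gro_frames(text)
    if not frames:
        raise EmptyInputError(f"{path}: no GRO frames found")
    records, coords = frames[0]
    atoms = [
        _make_atom(name, "", resid, resname, element_overrides, k + 3, allow_unknown)
        for k, (name, resid, resname) in enumerate(records)
    ]
    return MolecularModel(atoms, coords)


def read_trajectory(
    topology_path: str,
    frames_path: Optional[str] = None,
    frame_time_step: float = 1.0,
    format: Optional[str] = None,
    element_overrides: Optional[Mapping[str, str]] = None,
    allow_unknown: bool = False,
) -> TrajectoryFrames:
    """Read a trajectory from a multi-model PDB or a concatenated GRO series.

    ``frames_path`` defaults to ``topology_path`` (the common case of one
    multi-model file). ``frame_time_step`` is in ns and is user-supplied
    because these formats carry no reliable time metadata.
    """
    model = read_structure(topology_path, format, element_overrides, allow_unknown)
    frames_path = frames_path or topology_path
    fmt = _detect_format(frames_path, format)
    with open(frames_path) as fh:
        text = fh.read()
    if fmt == "pdb":
        parsed = _parse_pdb_models(text, element_overrides, allow_unknown=True)
        coords = [c for _, c in parsed]
    else:
        coords = [c for _, c in _parse_gro_frames(text)]
    if not coords:
        raise EmptyInputError(f"{frames_path}: no frames found")
    for i, c in enumerate(coords):
        if c.shape[0] != model.n_atoms:
            raise FormatError(
                f"frame {i}: expected {model.n_atoms} atoms, got {c.shape[0]}"
            )
    return TrajectoryFrames(model, coords, frame_time_step)


def read_scattering_curve(path: str) -> ScatteringCurve:
    """Read a 2/3-column ASCII scattering curve (q [Å⁻¹], I[, σ]).

    Lines starting with ``#`` are ignored; rows are returned sorted by q;
    duplicate q values are rejected.
    """
    qs: list[float] = []
    intensities: list[float] = []
    sigmas: list[float] = []
    n_cols: Optional[int] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}")
            try:
                values = [float(f) for f in fields[:3]]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from None
            if not all(math.isfinite(v) for v in values):
                raise FormatError(f"{path}:{lineno}: non-finite value")
            cols = min(len(fields), 3)
            if n_cols is None:
                n_cols = cols
            elif cols != n_cols:
                raise FormatError(f"{path}:{lineno}: inconsistent column count")
            qs.append(values[0])
            intensities.append(values[1])
            if cols == 3:
                sigmas.append(values[2])
    if not qs:
        raise EmptyInputError(f"{path}: no data rows")
    order = np.argsort(qs, kind="stable")
    q = np.asarray(qs)[order]
    if np.any(np.diff(q) == 0):
        raise ValidationError(f"{path}: duplicate q values")
    intensity = np.asarray(intensities)[order]
    sigma = np.asarray(sigmas)[order] if sigmas else None
    return ScatteringCurve(q, intensity, sigma)


def write_scattering_curve(curve: ScatteringCurve, path: str) -> None:
    """Write a curve as 2- or 3-column ASCII; round-trips to 6 significant digits."""
    with open(path, "w") as fh:
        if curve.sigma is None:
            fh.write("# q[1/A]  I\n")
            for q, i in zip(curve.q, curve.intensity):
                fh.write(f"{q:.6e} {i:.6e}\n")
        else:
            fh.write("# q[1/A]  I  sigma\n")
            for q, i, s in zip(curve.q, curve.intensity, curve.sigma):
                fh.write(f"{q:.6e} {i:.6e} {s:.6e}\n")


def write_pdb_trajectory(traj: TrajectoryFrames, path: str) -> None:
    """Write a trajectory as a multi-model PDB (nm → Å). Used by `simulate`."""
    with open(path, "w") as fh:
        for m, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (atom, xyz) in enumerate(zip(traj.model.atoms, frame), start=1):
                x, y, z = xyz * ANGSTROM_PER_NM
                name = atom.name[:4]
                # one-letter elements start in column 14 by PDB convention
                name_field = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                fh.write(
                    f"ATOM  {i:5d} {name_field} {atom.residue_name:<3.3s}  {atom.residue_id:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {atom.element:>2.2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
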