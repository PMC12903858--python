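"""Element data and PDB-style element inference.

The table covers the elements occurring in carbohydrate foldamers and
common buffer ions; standard atomic weights (IUPAC 2021 abridged) and
atomic numbers are used for mass- and electron-weighted geometry.
"""

from __future__ import annotations

from typing import Mapping, Optional

from .models import ValidationError

__all__ = ["ATOMIC_MASS", "ATOMIC_NUMBER", "infer_element", "electron_count", "atomic_mass"]

ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
}

ATOMIC_NUMBER: dict[str, int] = {
    "H": 1,
    "C": 6,
    "N": 7,
    "O": 8,
    "Na": 11,
    "P": 15,
    "S": 16,
    "Cl": 17,
}

def infer_element(
    name: str, overrides: Optional[Mapping[str, str]] = None
) -> Optional[str]:
    """Infer the element from a PDB/GRO atom name.

    PDB column semantics are honoured when the 4-character padded name is
    supplied: a name starting with a space (``" CA "``) is a one-letter
    element — the sugar carbon CA, not calcium — while a name filling
    column 13 (``"NA  "``, ``"1HB2"``) prefers a valid two-letter symbol
    (``NA`` → Na, ``CL`` → Cl) before falling back to its first letter.
    Leading digits are ignored (PDB hydrogens like ``1HB2``). Returns
    ``None`` when nothing matches.
    """
    if overrides and name.strip() in overrides:
        return overrides[name.strip()]
    stripped = name.strip().lstrip("0123456789")
    letters = "".join(ch for ch in stripped if ch.isalpha())
    if not letters:
        return None
    first = letters[0].upper()
    two = first + letters[1].lower() if len(letters) >= 2 else None
    if name.startswith(" "):  # one-letter element by PDB column convention
        candidates = [first, two]
    else:
        candidates = [two, first]
    for symbol in candidates:
        if symbol is not None and symbol in ATOMIC_MASS:
            return symbol
    return None


def atomic_mass(element: str) -> float:
    try:
        return ATOMIC_MASS[element]
    except KeyError:
        raise ValidationError(
            f"unknown element {element!r}; known: {sorted(ATOMIC_MASS)}"
        ) from None


def electron_count(element: str) -> int:
    try:
        return ATOMIC_NUMBER[element]
    except KeyError:
        raise ValidationError(
            f"unknown element {element!r}; known: {sorted(ATOMIC_NUMBER)}"
        ) from None
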