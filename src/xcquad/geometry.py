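"""Molecular geometry: atoms, element data, and XYZ input.

All internal lengths are Bohr; XYZ files are read in Angstrom per the format
convention.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ANGSTROM_TO_BOHR = 1.8897259886

_SYMBOLS = (
    "H He "
    "Li Be B C N O F Ne "
    "Na Mg Al Si P S Cl Ar "
    "K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr "
    "Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe"
).split()

SYMBOL_TO_Z = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}

#: Atomic numbers of group-1/2 (alkali and alkaline-earth) elements up to Xe.
GROUP_12_Z = frozenset({1, 3, 4, 11, 12, 19, 20, 37, 38, 55, 56}) - {1}


@dataclass(frozen=True)
class Atom:
    """A nucleus: element symbol, atomic number, position in Bohr."""

    symbol: str
    Z: int
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")


class XYZParseError(ValueError):
    """Raised for malformed XYZ content; message names the offending line."""


def read_xyz(text: str) -> list[Atom]:
    """Parse XYZ-format content (Angstrom) into a list of atoms (Bohr).

    The first line holds the atom count, the second is a free comment, and
    each subsequent line is ``Symbol x y z``.
    """
    lines = text.splitlines()
    if not lines:
        raise XYZParseError("empty XYZ content")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise XYZParseError(f"line 1: cannot parse atom count from "
                            f"{lines[0]!r}") from exc
    if len(lines) < natoms + 2:
        raise XYZParseError(
            f"expected {natoms} coordinate lines, file has "
            f"{max(0, len(lines) - 2)}")
    atoms = []
    for i in range(natoms):
        lineno = i + 3
        raw = lines[i + 2]
        parts = raw.split()
        if len(parts) < 4:
            raise XYZParseError(f"line {lineno}: expected 'Sym x y z', "
                                f"got {raw!r}")
        sym = parts[0].capitalize()
        if sym not in SYMBOL_TO_Z:
            raise XYZParseError(f"line {lineno}: unknown element symbol "
                                f"{parts[0]!r}")
        try:
            xyz = np.array([float(p) for p in parts[1:4]])
        except ValueError as exc:
            raise XYZParseError(f"line {lineno}: bad coordinate in "
                                f"{raw!r}") from exc
        atoms.append(Atom(sym, SYMBOL_TO_Z[sym], xyz * ANGSTROM_TO_BOHR))
    return atoms
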