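"""Atomic structures with per-atom radii and partial charges.

PQR is the native input format: PDB-like ATOM/HETATM records whose last
two numeric columns are the partial charge (e) and radius (Å).  Columns
are split on whitespace (the APBS dialect) rather than by fixed position,
because fixed-column PQR variants are inconsistent in the wild.  Bare PDB
files can be read and parameterized from a bundled radius/charge table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "ParameterTable",
    "read_pqr",
    "write_pqr",
    "read_pdb",
    "assign_parameters",
    "default_parameter_table",
]


@dataclass(frozen=True)
class Atom:
    """One atom: position (Å), radius (Å), partial charge (e)."""

    name: str
    position: tuple[float, float, float]
    radius: float
    charge: float
    residue: str = "UNK"
    chain: str = "A"
    residue_number: int = 1

    def __post_init__(self) -> None:
        if not all(math.isfinite(x) for x in self.position):
            raise ValueError(f"atom {self.name}: non-finite position {self.position}")
        if not (self.radius > 0):
            raise ValueError(f"atom {self.name}: radius must be > 0, got {self.radius}")
        object.__setattr__(self, "position", tuple(float(x) for x in self.position))


@dataclass
class Structure:
    """Ordered atom collection; the unit of I/O and rigid motion."""

    atoms: list[Atom] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum()) if self.atoms else 0.0

    def geometric_center(self) -> np.ndarray:
        """Unweighted mean of atomic coordinates (no mass weighting)."""
        if not self.atoms:
            raise ValueError("geometric center of an empty structure is undefined")
        return self.positions.mean(axis=0)

    def translated(self, shift: np.ndarray) -> "Structure":
        """Rigidly translated copy; atom order and internal geometry kept."""
        shift = np.asarray(shift, dtype=float)
        atoms = [replace(a, position=tuple(np.asarray(a.position) + shift)) for a in self.atoms]
        return Structure(atoms=atoms, label=self.label)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Bounding box of atom centers inflated by atomic radii."""
        if not self.atoms:
            raise ValueError("bounds of an empty structure are undefined")
        pos, rad = self.positions, self.radii[:, None]
        return (pos - rad).min(axis=0), (pos + rad).max(axis=0)

    def require_nonempty(self, operation: str) -> None:
        if not self.atoms:
            raise ValueError(f"{operation} requires a non-empty structure")


class PQRParseError(ValueError):
    """Malformed PQR/PDB record; message names the offending line."""


def _parse_record(line: str, lineno: int) -> Atom:
    tokens = line.split()
    # ATOM serial name resname [chain] resnum x y z charge radius
    if len(tokens) < 10:
        raise PQRParseError(f"line {lineno}: too few fields in record: {line.rstrip()!r}")
    try:
        x, y, z, charge, radius = (float(t) for t in tokens[-5:])
    except ValueError as exc:
        raise PQRParseError(f"line {lineno}: non-numeric coordinate/charge/radius: {exc}") from None
    name = tokens[2]
    resname = tokens[3]
    if len(tokens) >= 11:  # chain identifier present
        chain, resnum_tok = tokens[4], tokens[5]
    else:
        chain, resnum_tok = "A", tokens[4]
    try:
        resnum = int(resnum_tok)
    except ValueError:
        raise PQRParseError(f"line {lineno}: bad residue number {resnum_tok!r}") from None
    try:
        return Atom(
            name=name, position=(x, y, z), radius=radius, charge=charge,
            residue=resname, chain=chain, residue_number=resnum,
        )
    except ValueError as exc:
        raise PQRParseError(f"line {lineno}: {exc}") from None


def read_pqr(path: str | Path) -> Structure:
    """Read a whitespace-delimited PQR file (APBS dialect).

    One :class:`Atom` per ATOM/HETATM record, in file order; charges and
    radii taken verbatim.  Raises on malformed records (naming the line)
    and on files with zero atom records.
    """
    path = Path(path)
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                atoms.append(_parse_record(line, lineno))
    if not atoms:
        raise PQRParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms=atoms, label=path.stem)


def write_pqr(structure: Structure, path: str | Path) -> None:
    """Write a structure in the whitespace-delimited PQR dialect."""
    structure.require_nonempty("write_pqr")
    with open(path, "w") as fh:
        for serial, a in enumerate(structure.atoms, start=1):
            x, y, z = a.position
            fh.write(
                f"ATOM  {serial:>5d} {a.name:<4s} {a.residue:<4s}{a.chain:>1s} "
                f"{a.residue_number:>4d}    {x:>10.4f} {y:>10.4f} {z:>10.4f} "
                f"{a.charge:>8.4f} {a.radius:>7.4f}\n"
            )
        fh.write("END\n")


def read_pdb(path: str | Path) -> Structure:
    """Read ATOM/HETATM records from a plain PDB file (fixed columns).

    Radii and charges are filled with placeholders (radius 1.0, charge 0)
    and must be assigned via :func:`assign_parameters` before any
    field-building operation.  Alternate locations beyond the first are
    skipped; no protonation is performed.
    """
    path = Path(path)
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            altloc = line[16:17].strip()
            if altloc and altloc != "A":
                continue
            try:
                atoms.append(
                    Atom(
                        name=line[12:16].strip(),
                        position=(float(line[30:38]), float(line[38:46]), float(line[46:54])),
                        radius=1.0,
                        charge=0.0,
                        residue=line[17:20].strip(),
                        chain=line[21:22].strip() or "A",
                        residue_number=int(line[22:26]),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise PQRParseError(f"line {lineno}: malformed PDB record: {exc}") from None
    if not atoms:
        raise PQRParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms=atoms, label=path.stem)


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------

#: van der Waals radii (Å) used as element fallbacks; H uses the compact
#: value common in continuum-electrostatics parameter sets.
ELEMENT_RADII: dict[str, float] = {
    "H": 1.00, "C": 1.70, "N": 1.50, "O": 1.40, "S": 1.85, "P": 1.90,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 1.85, "K": 2.27, "MG": 1.73, "CA": 2.00, "ZN": 1.39, "FE": 1.40,
}

_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE"}

#: Backbone partial charges (e); the N-H and C=O dipoles sum to zero.
_BACKBONE_CHARGES = {"N": -0.40, "H": 0.40, "HN": 0.40, "CA": 0.0, "C": 0.55, "O": -0.55}

#: Side-chain charges carrying the formal charge of ionizable residues,
#: split over the equivalent terminal atoms.  All other side-chain atoms
#: are neutral.  This is a deliberately minimal convention, not a force
#: field.
_SIDECHAIN_CHARGES: dict[str, dict[str, float]] = {
    "ASP": {"OD1": -0.50, "OD2": -0.50},
    "GLU": {"OE1": -0.50, "OE2": -0.50},
    "LYS": {"NZ": 1.00},
    "ARG": {"NH1": 0.50, "NH2": 0.50},
}


def _element_of(atom: Atom) -> str | None:
    name = atom.name.strip().upper()
    if name[:2] in _TWO_LETTER_ELEMENTS and (len(name) == 2 or atom.residue.upper() == name[:2]):
        return name[:2]
    stripped = name.lstrip("0123456789")
    if not stripped:
        return None
    first = stripped[0]
    return first if first in ELEMENT_RADII else None


@dataclass
class ParameterTable:
    """Mapping (residue, atom name) -> (radius Å, charge e), with element
    fallback radii for atoms not listed explicitly."""

    entries: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    element_radii: dict[str, float] = field(default_factory=lambda: dict(ELEMENT_RADII))

    def __post_init__(self) -> None:
        for key, (radius, _q) in self.entries.items():
            if radius <= 0:
                raise ValueError(f"table entry {key}: radius must be > 0")

    def lookup(self, atom: Atom) -> tuple[float, float] | None:
        key = (atom.residue.upper(), atom.name.upper())
        if key in self.entries:
            return self.entries[key]
        elem = _element_of(atom)
        if elem is not None:
            charge = _BACKBONE_CHARGES.get(atom.name.upper(), 0.0)
            return (self.element_radii[elem], charge)
        return None

    def residue_net_charge(self, residue: str) -> float:
        """Net charge of a residue implied by this table's explicit entries."""
        return sum(q for (res, _), (_, q) in self.entries.items() if res == residue.upper())


def default_parameter_table() -> ParameterTable:
    """Bundled minimal radius/charge set for the 20 standard amino acids.

    Backbone atoms carry the standard peptide-dipole charges; ionizable
    side chains carry their formal charge split over equivalent terminal
    atoms; everything else is neutral with element-based radii.  A
    convenience for bare PDB input, not a published force field.
    """
    sidechains: dict[str, list[str]] = {
        "GLY": [], "ALA": ["CB"], "VAL": ["CB", "CG1", "CG2"],
        "LEU": ["CB", "CG", "CD1", "CD2"], "ILE": ["CB", "CG1", "CG2", "CD1"],
        "PRO": ["CB", "CG", "CD"], "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
        "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
        "MET": ["CB", "CG", "SD", "CE"], "SER": ["CB", "OG"], "THR": ["CB", "OG1", "CG2"],
        "CYS": ["CB", "SG"], "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
        "ASN": ["CB", "CG", "OD1", "ND2"], "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
        "ASP": ["CB", "CG", "OD1", "OD2"], "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
        "LYS": ["CB", "CG", "CD", "CE", "NZ"],
        "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
        "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    }
    entries: dict[tuple[str, str], tuple[float, float]] = {}
    for res, names in sidechains.items():
        for atom_name, q in _BACKBONE_CHARGES.items():
            elem = atom_name[0] if atom_name[0] in ELEMENT_RADII else "C"
            entries[(res, atom_name)] = (ELEMENT_RADII[elem], q)
        overrides = _SIDECHAIN_CHARGES.get(res, {})
        for atom_name in names:
            elem = atom_name[0]
            entries[(res, atom_name)] = (ELEMENT_RADII[elem], overrides.get(atom_name, 0.0))
    return ParameterTable(entries=entries)


def assign_parameters(structure: Structure, table: ParameterTable | None = None) -> Structure:
    """Populate radii and charges from a parameter table.

    Existing values are overwritten by the table.  Atoms that resolve
    neither by (residue, atom name) nor by element raise a single error
    listing all offenders.
    """
    structure.require_nonempty("assign_parameters")
    if table is None:
        table = default_parameter_table()
    assigned: list[Atom] = []
    unresolved: list[str] = []
    for a in structure.atoms:
        found = table.lookup(a)
        if found is None:
            unresolved.append(f"{a.residue}:{a.name}")
            continue
        radius, charge = found
        assigned.append(replace(a, radius=radius, charge=charge))
    if unresolved:
        raise ValueError(
            "cannot assign parameters to atoms (unknown element, no table entry): "
            + ", ".join(sorted(set(unresolved)))
        )
    return Structure(atoms=assigned, label=structure.label)
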