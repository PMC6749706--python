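"""Reading and writing protein/ligand structures (PDB and PDBQT).

PDBQT is AutoDock's PDB dialect: standard ATOM/HETATM columns up to 66, the
partial charge in columns 71–76 and the AutoDock atom type in columns 78–79.
Plain PDB input gets zero charges and element-derived atom types.  Parsing is
order-preserving; the first alternate location of an atom is kept and
hydrogens are retained (they are needed for hydrogen-bond typing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParseError, TypingError
from .forcefield import ForceFieldTable, default_forcefield

logger = logging.getLogger(__name__)

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class Atom:
    """A single atomic record.

    ``partial_charge`` is in elementary charge units; it is zero for plain PDB
    input, which carries no charge column.  ``vdw_radius`` (Å) comes from the
    force-field table entry for ``atom_type``.
    """

    serial: int
    name: str
    element: str
    position: np.ndarray  # (3,) Å
    partial_charge: float = 0.0
    vdw_radius: float = 1.5
    atom_type: str = "C"
    resname: str = "UNK"
    resseq: int = 1
    chain: str = "A"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")


@dataclass
class ProteinStructure:
    """An ordered list of atoms with an identifier."""

    atoms: list[Atom]
    id: str = "protein"

    def __post_init__(self):
        if not self.atoms:
            raise ParseError("no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])


@dataclass
class LigandStructure:
    """A bound ligand; its unweighted atom centroid defines the actual site center."""

    atoms: list[Atom]

    def __post_init__(self):
        if not self.atoms:
            raise ParseError("no atoms")

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def site_center(self) -> np.ndarray:
        return site_center(self)


def site_center(ligand: LigandStructure) -> np.ndarray:
    """Unweighted geometric mean of the ligand atom positions (Å)."""
    return ligand.positions.mean(axis=0)


def _parse_atom_line(
    line: str,
    lineno: int,
    *,
    pdbqt: bool,
    forcefield: ForceFieldTable,
) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        resseq = int(line[22:26]) if line[22:26].strip() else 1
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError):
        # whitespace-separated fallback (some generators do not pad columns)
        fields = line.split()
        try:
            serial = int(fields[1])
            name = fields[2]
            resname = fields[3] if len(fields) > 3 else "UNK"
            chain, resseq = "A", 1
            x, y, z = (float(v) for v in fields[-7:-4]) if pdbqt else (
                float(v) for v in fields[5:8]
            )
        except (ValueError, IndexError):
            raise ParseError(f"malformed ATOM/HETATM record: {line.rstrip()!r}", lineno)
        logger.warning("line %d: fixed columns failed, used whitespace fallback", lineno)

    element = line[76:78].strip() if len(line) >= 78 and not pdbqt else ""
    charge = 0.0
    if pdbqt:
        try:
            charge = float(line[70:76])
        except (ValueError, IndexError):
            raise ParseError("missing/invalid partial charge column", lineno)
        atom_type = line[77:79].strip()
        if not atom_type:
            raise ParseError("missing atom type column", lineno)
        if atom_type not in forcefield:
            raise TypingError(f"line {lineno}: unknown atom type {atom_type!r}")
        if not element:
            element = atom_type[0]
    else:
        if not element:
            element = name[:1]
        atom_type = forcefield.type_for_element(element)

    return Atom(
        serial=serial,
        name=name,
        element=element,
        position=np.array([x, y, z]),
        partial_charge=charge,
        vdw_radius=forcefield.get(atom_type).radius,
        atom_type=atom_type,
        resname=resname,
        resseq=resseq,
        chain=chain,
    )


def _parse_structure(
    path: str | Path,
    *,
    pdbqt: bool,
    forcefield: ForceFieldTable | None,
    skip_waters: bool,
) -> list[Atom]:
    ff = forcefield or default_forcefield()
    atoms: list[Atom] = []
    seen_altloc: set[tuple[str, int, str]] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        resname = line[17:20].strip()
        if skip_waters and resname in _WATER_RESNAMES:
            continue
        altloc = line[16:17] if len(line) > 16 else " "
        if altloc not in (" ", ""):
            key = (line[21:22], int(line[22:26] or 0), line[12:16].strip())
            if key in seen_altloc:
                continue
            seen_altloc.add(key)
        atoms.append(_parse_atom_line(line, lineno, pdbqt=pdbqt, forcefield=ff))
    if not atoms:
        raise ParseError("no atoms")
    return atoms


def parse_pdbqt(
    path: str | Path,
    forcefield: ForceFieldTable | None = None,
    skip_waters: bool = False,
) -> ProteinStructure:
    """Parse a PDBQT file into a :class:`ProteinStructure` with partial charges."""
    atoms = _parse_structure(path, pdbqt=True, forcefield=forcefield, skip_waters=skip_waters)
    return ProteinStructure(atoms=atoms, id=Path(path).stem)


def parse_pdb(
    path: str | Path,
    forcefield: ForceFieldTable | None = None,
    skip_waters: bool = False,
) -> ProteinStructure:
    """Parse a plain PDB file; charges default to zero, types from the element."""
    atoms = _parse_structure(path, pdbqt=False, forcefield=forcefield, skip_waters=skip_waters)
    return ProteinStructure(atoms=atoms, id=Path(path).stem)


def parse_ligand(path: str | Path, forcefield: ForceFieldTable | None = None) -> LigandStructure:
    """Parse a ligand from PDB(QT) ATOM/HETATM records."""
    text = Path(path).read_text()
    pdbqt = str(path).endswith(".pdbqt")
    atoms = _parse_structure(path, pdbqt=pdbqt, forcefield=forcefield, skip_waters=False)
    return LigandStructure(atoms=atoms)


def write_pdbqt(structure: ProteinStructure | LigandStructure, path: str | Path) -> None:
    """Write fixed-column PDBQT (charge cols 71–76, type cols 78–79)."""
    lines = []
    for atom in structure.atoms:
        x, y, z = atom.position
        lines.append(
            f"ATOM  {atom.serial:5d} {atom.name:<4.4s} {atom.resname:<3.3s} "
            f"{atom.chain:1.1s}{atom.resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}    "
            f"{atom.partial_charge:6.3f} {atom.atom_type:<2.2s}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
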