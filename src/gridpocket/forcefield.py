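"""Force-field parameter table in the AutoDock4 convention.

Each atom type carries a Lennard-Jones well depth ``epsilon`` (kcal/mol), a
per-atom well radius ``r0`` (Å, half the like-pair well position) and a van der
Waals ``radius`` (Å) used for grid occupancy.  Pair parameters follow the Amber
combining rules used by AutoDock: ε_ij = sqrt(ε_i ε_j), r0_ij = r0_i + r0_j.

Hydrogen-bond 12-10 wells are tabulated per donor–acceptor pair class rather
than combined: a polar hydrogen (HD) against an N/O acceptor has a well of
5 kcal/mol at 1.9 Å, and 1 kcal/mol at 2.5 Å against a sulfur acceptor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import TypingError

_DEFAULT_RESOURCE = "autodock4_params.json"

# element -> AutoDock type, used when the input (plain PDB) carries no type column
ELEMENT_TO_TYPE = {
    "C": "C", "N": "N", "O": "OA", "S": "SA", "H": "HD", "P": "P",
    "F": "F", "CL": "Cl", "BR": "Br", "I": "I",
    "ZN": "Zn", "MG": "Mg", "MN": "Mn", "CA": "Ca", "FE": "Fe",
}


@dataclass(frozen=True)
class AtomTypeParams:
    """Per-type (ε, r0, radius) triple; units kcal/mol, Å, Å."""

    epsilon: float
    r0: float
    radius: float

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.r0 <= 0 or self.radius <= 0:
            raise ValueError("r0 and radius must be > 0")


@dataclass(frozen=True)
class ForceFieldTable:
    """Mapping atom type -> parameters, plus hydrogen-bond typing sets."""

    types: dict[str, AtomTypeParams]
    hbond_capable: frozenset[str]
    hbond_acceptors: frozenset[str]
    hbond_donor_h: frozenset[str]
    hbond_wells: dict[str, tuple[float, float]]  # acceptor type -> (epsilon, r0 of the pair)
    version: str = "custom"

    def get(self, atom_type: str) -> AtomTypeParams:
        try:
            return self.types[atom_type]
        except KeyError:
            raise TypingError(
                f"unknown atom type {atom_type!r}; known: {sorted(self.types)}"
            ) from None

    def __contains__(self, atom_type: str) -> bool:
        return atom_type in self.types

    def type_for_element(self, element: str) -> str:
        key = element.strip().upper()
        if key not in ELEMENT_TO_TYPE:
            raise TypingError(f"no atom type mapping for element {element!r}")
        return ELEMENT_TO_TYPE[key]

    def hbond_pair(self, type_a: str, type_b: str) -> tuple[float, float] | None:
        """12-10 well (ε, r0) for a donor-H/acceptor pair, or None if the two
        types cannot form a hydrogen bond."""
        for h, other in ((type_a, type_b), (type_b, type_a)):
            if h in self.hbond_donor_h and other in self.hbond_acceptors:
                return self.hbond_wells[other]
        return None

    @classmethod
    def from_json(cls, path: str | Path | None = None) -> "ForceFieldTable":
        if path is None:
            text = (resources.files("gridpocket.data") / _DEFAULT_RESOURCE).read_text()
        else:
            text = Path(path).read_text()
        raw = json.loads(text)
        types = {
            name: AtomTypeParams(p["epsilon"], p["r0"], p["radius"])
            for name, p in raw["types"].items()
        }
        wells = {a: (w["epsilon"], w["r0"]) for a, w in raw["hbond_wells"].items()}
        return cls(
            types=types,
            hbond_capable=frozenset(raw["hbond_capable"]),
            hbond_acceptors=frozenset(raw["hbond_acceptors"]),
            hbond_donor_h=frozenset(raw["hbond_donor_h"]),
            hbond_wells=wells,
            version=raw.get("version", "custom"),
        )


_default_table: ForceFieldTable | None = None


def default_forcefield() -> ForceFieldTable:
    """The packaged AutoDock4 parameter subset (cached)."""
    global _default_table
    if _default_table is None:
        _default_table = ForceFieldTable.from_json()
    return _default_table
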