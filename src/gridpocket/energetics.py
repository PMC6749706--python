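"""Probe-energy channels: van der Waals, hydrogen bond and Coulomb grids.

A chemical probe is placed at every voxel center and its non-bonded
interaction with the protein is accumulated:

* van der Waals — a united-atom −CH₃ probe (AutoDock type C) with the 12-6
  Lennard-Jones potential  A/r¹² − B/r⁶,  A = ε r₀¹²,  B = 2ε r₀⁶, summed over
  protein atoms.
* hydrogen bond — an −OH probe (OA at the voxel center, HD 0.96 Å along +x)
  with the 12-10 potential  C/r¹² − D/r¹⁰,  C = 5ε r₀¹²,  D = 6ε r₀¹⁰.
  Hydrogen bonds saturate, so instead of a sum the single candidate energy of
  largest magnitude is kept.
* Coulomb — a unit positive point charge; value Σ K q₁ q₂ / r² with q₁ = +1
  and q₂ the protein partial charges (the inverse-square form is deliberate
  and configurable to 1/r).

All pairwise terms are cut off at 8 Å by center distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forcefield import AtomTypeParams, ForceFieldTable, default_forcefield
from .grid import ChannelGrid, GridSpec
from .structures import ProteinStructure

logger = logging.getLogger(__name__)

#: Coulomb constant, kcal·Å/(mol·e²)
COULOMB_K = 332.0636

#: O–H bond length of the hydroxyl probe, Å
OH_BOND_LENGTH = 0.96


@dataclass(frozen=True)
class Probe:
    """A probe: named atoms at fixed offsets (Å) from the voxel center."""

    name: str
    atoms: tuple[tuple[str, tuple[float, float, float], float], ...]  # (type, offset, charge)


PROBE_CH3 = Probe("CH3", ((("C"), (0.0, 0.0, 0.0), 0.0),))
PROBE_OH = Probe(
    "OH",
    (
        ("OA", (0.0, 0.0, 0.0), 0.0),
        ("HD", (OH_BOND_LENGTH, 0.0, 0.0), 0.0),
    ),
)
PROBE_UNIT_CHARGE = Probe("unit_charge", ((("C"), (0.0, 0.0, 0.0), +1.0),))


@dataclass(frozen=True)
class PairParams:
    """Combined pair well (ε, r₀) with the derived 12-6 and 12-10 coefficients."""

    epsilon: float  # kcal/mol
    r0: float  # Å

    @property
    def A(self) -> float:
        return self.epsilon * self.r0**12

    @property
    def B(self) -> float:
        return 2.0 * self.epsilon * self.r0**6

    @property
    def C(self) -> float:
        return 5.0 * self.epsilon * self.r0**12

    @property
    def D(self) -> float:
        return 6.0 * self.epsilon * self.r0**10


@dataclass(frozen=True)
class EnergyParams:
    """Tunables of the energy channels.

    ``coulomb_exponent`` is 2 for the inverse-square form used by the
    descriptor; set 1 for a physical 1/r potential.  ``min_distance`` floors
    pair distances so voxels that sit on top of an atom stay finite.
    """

    cutoff: float = 8.0  # Å
    coulomb_k: float = COULOMB_K
    coulomb_exponent: int = 2
    min_distance: float = 0.05  # Å

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.coulomb_exponent not in (1, 2):
            raise ValueError("coulomb_exponent must be 1 or 2")


def combine_pair(p_i: AtomTypeParams, p_j: AtomTypeParams) -> PairParams:
    """Amber/AutoDock combining rules: ε = sqrt(ε_i ε_j), r₀ = r_i + r_j."""
    return PairParams(
        epsilon=float(np.sqrt(p_i.epsilon * p_j.epsilon)),
        r0=p_i.r0 + p_j.r0,
    )


def _check_r(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be > 0")
    return r


def lj_12_6(r, p: PairParams, cutoff: float = 8.0):
    """12-6 Lennard-Jones energy (kcal/mol); 0 beyond the cutoff; minimum −ε at r₀."""
    r = _check_r(r)
    e = np.where(r <= cutoff, p.A / r**12 - p.B / r**6, 0.0)
    return float(e) if e.ndim == 0 else e


def lj_12_10(r, p: PairParams, cutoff: float = 8.0):
    """12-10 Lennard-Jones energy (kcal/mol); 0 beyond the cutoff; minimum −ε at r₀."""
    r = _check_r(r)
    e = np.where(r <= cutoff, p.C / r**12 - p.D / r**10, 0.0)
    return float(e) if e.ndim == 0 else e


def _local_box(spec: GridSpec, center: np.ndarray, reach: float):
    """Voxel sub-box whose centers may lie within ``reach`` Å of ``center``.

    Returns (slices, squared-distance array from voxel centers to center),
    or None when the box is empty.
    """
    axes = spec.axis_centers()
    sl, local = [], []
    for a in range(3):
        c = axes[a]
        lo = int(np.searchsorted(c, center[a] - reach))
        hi = int(np.searchsorted(c, center[a] + reach, side="right"))
        if lo >= hi:
            return None
        sl.append(slice(lo, hi))
        local.append(c[lo:hi] - center[a])
    d2 = (
        local[0][:, None, None] ** 2
        + local[1][None, :, None] ** 2
        + local[2][None, None, :] ** 2
    )
    return tuple(sl), d2


def vdw_channel(
    protein: ProteinStructure,
    spec: GridSpec,
    params: EnergyParams | None = None,
    forcefield: ForceFieldTable | None = None,
    probe: Probe = PROBE_CH3,
) -> ChannelGrid:
    """Σ 12-6 energies between the probe atoms and all protein atoms in range."""
    params = params or EnergyParams()
    ff = forcefield or default_forcefield()
    values = np.zeros(spec.shape)
    for probe_type, offset, _q in probe.atoms:
        p_probe = ff.get(probe_type)
        offset = np.asarray(offset)
        for atom in protein.atoms:
            pair = combine_pair(p_probe, ff.get(atom.atom_type))
            if pair.epsilon == 0.0:
                continue
            box = _local_box(spec, atom.position - offset, params.cutoff)
            if box is None:
                continue
            sl, d2 = box
            mask = d2 <= params.cutoff**2
            inv = 1.0 / np.maximum(d2[mask], params.min_distance**2)
            r6i = inv * inv * inv
            sub = values[sl]
            sub[mask] += pair.A * r6i * r6i - pair.B * r6i
    return ChannelGrid(spec=spec, values=values, channel_name="vdw")


def hbond_channel(
    protein: ProteinStructure,
    spec: GridSpec,
    params: EnergyParams | None = None,
    forcefield: ForceFieldTable | None = None,
    probe: Probe = PROBE_OH,
) -> ChannelGrid:
    """Per voxel, the candidate 12-10 energy of maximum magnitude.

    Candidates are donor-H/acceptor pairs between the probe atoms and the
    hydrogen-bond-capable protein atoms within the cutoff; a voxel with no
    candidate in range is 0.
    """
    params = params or EnergyParams()
    ff = forcefield or default_forcefield()
    best = np.zeros(spec.shape)
    for probe_type, offset, _q in probe.atoms:
        offset = np.asarray(offset)
        for atom in protein.atoms:
            if atom.atom_type not in ff.hbond_capable:
                continue
            well = ff.hbond_pair(probe_type, atom.atom_type)
            if well is None:
                continue
            pair = PairParams(epsilon=well[0], r0=well[1])
            box = _local_box(spec, atom.position - offset, params.cutoff)
            if box is None:
                continue
            sl, d2 = box
            mask = d2 <= params.cutoff**2
            inv = 1.0 / np.maximum(d2[mask], params.min_distance**2)
            r6i = inv * inv * inv
            e = pair.C * r6i * r6i - pair.D * r6i * inv * inv
            sub = best[sl]
            cur = sub[mask]
            sub[mask] = np.where(np.abs(e) > np.abs(cur), e, cur)
    return ChannelGrid(spec=spec, values=best, channel_name="hbond")


def coulomb_channel(
    protein: ProteinStructure,
    spec: GridSpec,
    params: EnergyParams | None = None,
) -> ChannelGrid:
    """Σ K q₁ q₂ / r^exp with a +1 probe charge, over atoms within the cutoff."""
    params = params or EnergyParams()
    values = np.zeros(spec.shape)
    if not np.any(protein.charges):
        logger.warning("all partial charges are zero; Coulomb channel is identically 0")
        return ChannelGrid(spec=spec, values=values, channel_name="coulomb")
    exp = params.coulomb_exponent
    for atom in protein.atoms:
        q2 = atom.partial_charge
        if q2 == 0.0:
            continue
        box = _local_box(spec, atom.position, params.cutoff)
        if box is None:
            continue
        sl, d2 = box
        mask = d2 <= params.cutoff**2
        inv = 1.0 / np.maximum(d2[mask], params.min_distance**2)
        sub = values[sl]
        sub[mask] += params.coulomb_k * q2 * (inv if exp == 2 else np.sqrt(inv))
    return ChannelGrid(spec=spec, values=values, channel_name="coulomb")
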