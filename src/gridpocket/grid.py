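"""Voxel lattice construction, protein occupancy, and the shape channel.

The descriptor lattice has 1 Å cubic voxels and an 8 Å solvent buffer around
the protein bounding box.  The shape channel is a lightly modified LIGSITE:
the occupancy mask is scanned along the three axes and four cube diagonals,
and every solvent voxel inside a protein-solvent-protein (PSP) run gains one
count per direction, so values range from 0 to 7.  A run that reaches the grid
boundary is open to bulk solvent and does not count.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .structures import ProteinStructure

BUFFER = 8.0  # Å of solvent padding around the protein bounding box
SPACING = 1.0  # Å voxel edge

#: scan directions: 3 axes + 4 cube diagonals, pairwise non-antiparallel
SCAN_DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (-1, 1, 1),
)

CHANNEL_NAMES = ("shape", "vdw", "hbond", "coulomb")


@dataclass(frozen=True)
class GridSpec:
    """A 1 Å voxel lattice; voxel center (i,j,k) sits at origin + (i,j,k) + 0.5."""

    origin: tuple[float, float, float]
    shape: tuple[int, int, int]
    spacing: float = SPACING

    def __post_init__(self):
        if self.spacing != SPACING:
            raise ValueError("grid spacing is fixed at 1 Å")
        if any(s < 1 for s in self.shape):
            raise ValueError("grid shape components must be >= 1")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    def axis_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates (Å)."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing
            for a in range(3)
        )

    def voxel_center(self, index) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(index) + 0.5) * self.spacing

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class ChannelGrid:
    """One scalar per voxel for a named descriptor channel."""

    spec: GridSpec
    values: np.ndarray
    channel_name: str

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise ValueError("values shape does not match GridSpec")
        if self.channel_name not in CHANNEL_NAMES:
            raise ValueError(f"channel_name must be one of {CHANNEL_NAMES}")


@dataclass
class OccupancyMask:
    """Boolean per voxel: True where the voxel center lies inside some atom."""

    spec: GridSpec
    flags: np.ndarray

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.shape != self.spec.shape:
            raise ValueError("flags shape does not match GridSpec")


def make_grid(protein: ProteinStructure, buffer: float = BUFFER) -> GridSpec:
    """Bounding box of the protein plus an 8 Å buffer, in whole 1 Å voxels."""
    pos = protein.positions
    lo = pos.min(axis=0)
    extent = pos.max(axis=0) - lo
    # round() guards against ceil(10 + 1e-12) -> 11 from float noise
    shape = tuple(int(ceil(round(e, 9))) + 2 * int(buffer) for e in extent)
    return GridSpec(origin=tuple(lo - buffer), shape=shape)


def mark_occupancy(protein: ProteinStructure, spec: GridSpec) -> OccupancyMask:
    """Flag voxels whose center is within an atom's van der Waals radius."""
    flags = np.zeros(spec.shape, dtype=bool)
    axes = spec.axis_centers()
    for atom in protein.atoms:
        r = atom.vdw_radius
        sl, local = [], []
        for a in range(3):
            c = axes[a]
            lo = int(np.searchsorted(c, atom.position[a] - r))
            hi = int(np.searchsorted(c, atom.position[a] + r, side="right"))
            if lo >= hi:
                break
            sl.append(slice(lo, hi))
            local.append(c[lo:hi] - atom.position[a])
        else:
            d2 = (
                local[0][:, None, None] ** 2
                + local[1][None, :, None] ** 2
                + local[2][None, None, :] ** 2
            )
            flags[tuple(sl)] |= d2 <= r * r
    return OccupancyMask(spec=spec, flags=flags)


def _shift(a: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """Shift a boolean volume by one voxel along direction d, filling False."""
    out = np.zeros_like(a)
    dst, src = [], []
    for da in d:
        if da == 1:
            dst.append(slice(1, None))
            src.append(slice(None, -1))
        elif da == -1:
            dst.append(slice(None, -1))
            src.append(slice(1, None))
        else:
            dst.append(slice(None))
            src.append(slice(None))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _reachable(protein: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """True where some protein voxel lies at v - t*d for t >= 1 (within grid)."""
    reach = np.zeros_like(protein)
    for _ in range(max(protein.shape)):
        new = _shift(reach | protein, d)
        if np.array_equal(new, reach):
            break
        reach = new
    return reach


def psp_scan(mask: OccupancyMask) -> ChannelGrid:
    """Count, per solvent voxel, the scan directions along which it lies in a
    protein-solvent-protein run.  Protein voxels stay at 0; the maximum is 7."""
    protein = mask.flags
    solvent = ~protein
    counts = np.zeros(mask.spec.shape, dtype=np.uint8)
    for d in SCAN_DIRECTIONS:
        neg = tuple(-c for c in d)
        inside = solvent & _reachable(protein, d) & _reachable(protein, neg)
        counts += inside
    return ChannelGrid(spec=mask.spec, values=counts, channel_name="shape")
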