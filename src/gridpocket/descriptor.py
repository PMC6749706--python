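"""Descriptor assembly, arctangent normalization and 16³ block sampling.

The four channels (shape, vdw, hbond, coulomb) live on one shared lattice.
Before any learning the voxel values are mapped to (−1, 1) with
v ← (2/π)·arctan(v).  Training blocks are 16³×4 sub-grids: 64 positives whose
centers sit on the voxel lattice within [−2, +2) Å of the site center per axis
(a 20 Å envelope, 4×4×4 = 64 blocks), and stride-4 negatives outside every
site envelope, down-sampled to 64 per protein (128 blocks in total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .energetics import EnergyParams, coulomb_channel, hbond_channel, vdw_channel
from .errors import GridPocketError
from .forcefield import ForceFieldTable, default_forcefield
from .grid import CHANNEL_NAMES, ChannelGrid, GridSpec, make_grid, mark_occupancy, psp_scan
from .structures import ProteinStructure

logger = logging.getLogger(__name__)

BLOCK_SIZE = 16  # voxels per axis
POSITIVE_OFFSETS = (-2, -1, 0, 1)  # Å per axis, the 4 offsets inside [-2, +2)
ENVELOPE_HALF_WIDTH = 10.0  # Å, half the 20 Å positive envelope
NEGATIVE_STRIDE = 4  # Å
N_NEGATIVES = 64

# |energy| above this is clipped before arctan so normalized values stay
# strictly inside (-1, 1) in float64 even for voxels essentially on an atom
_NORMALIZE_CLIP = 1e15


@dataclass
class DescriptorGrid:
    """The 4-channel voxel descriptor of one protein."""

    spec: GridSpec
    channels: dict[str, ChannelGrid]
    normalized: bool = False

    def __post_init__(self):
        if tuple(self.channels) != CHANNEL_NAMES:
            raise ValueError(f"channels must be exactly {CHANNEL_NAMES} in order")
        for ch in self.channels.values():
            if ch.spec != self.spec:
                raise ValueError("all channels must share the descriptor GridSpec")

    def as_array(self) -> np.ndarray:
        """(D, H, W, 4) float array, channel order shape/vdw/hbond/coulomb."""
        return np.stack([np.asarray(self.channels[n].values, dtype=float) for n in CHANNEL_NAMES], axis=-1)


@dataclass
class SampleBlock:
    """A 16³×4 sub-grid; ``label`` is 0/1 for training or a probability."""

    origin_index: tuple[int, int, int]
    values: np.ndarray  # (16, 16, 16, 4)
    center: np.ndarray  # (3,) Å
    label: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != (BLOCK_SIZE, BLOCK_SIZE, BLOCK_SIZE, len(CHANNEL_NAMES)):
            raise ValueError("block must be 16x16x16x4")
        self.center = np.asarray(self.center, dtype=float)


def compute_descriptor(
    protein: ProteinStructure,
    forcefield: ForceFieldTable | None = None,
    energy_params: EnergyParams | None = None,
) -> DescriptorGrid:
    """Build all four raw (un-normalized) channels for a protein."""
    ff = forcefield or default_forcefield()
    params = energy_params or EnergyParams()
    spec = make_grid(protein)
    mask = mark_occupancy(protein, spec)
    channels = {
        "shape": psp_scan(mask),
        "vdw": vdw_channel(protein, spec, params, ff),
        "hbond": hbond_channel(protein, spec, params, ff),
        "coulomb": coulomb_channel(protein, spec, params),
    }
    return DescriptorGrid(spec=spec, channels=channels, normalized=False)


def normalize(grid: DescriptorGrid) -> DescriptorGrid:
    """Map every voxel value to (−1, 1) via v ← (2/π)·arctan(v), all channels."""
    if grid.normalized:
        raise GridPocketError("descriptor is already normalized")
    channels = {}
    for name, ch in grid.channels.items():
        v = np.clip(np.asarray(ch.values, dtype=float), -_NORMALIZE_CLIP, _NORMALIZE_CLIP)
        channels[name] = ChannelGrid(
            spec=ch.spec, values=(2.0 / np.pi) * np.arctan(v), channel_name=name
        )
    return DescriptorGrid(spec=grid.spec, channels=channels, normalized=True)


def _block_center(spec: GridSpec, corner: np.ndarray) -> np.ndarray:
    return np.asarray(spec.origin) + corner + BLOCK_SIZE / 2.0


def _snap_to_block_lattice(spec: GridSpec, point: np.ndarray) -> np.ndarray:
    """Corner index of the reference block for the positive cloud.

    The 4 per-axis offsets {-2,-1,0,+1} place the cloud's centroid half a
    voxel below the reference center, so the reference is chosen half a voxel
    above the site to keep the 64-block cloud centered on it.
    """
    return np.rint(np.asarray(point) - np.asarray(spec.origin) - BLOCK_SIZE / 2.0 + 0.5).astype(int)


def _extract(grid: DescriptorGrid, array: np.ndarray, corner: np.ndarray, label) -> SampleBlock:
    i, j, k = corner
    return SampleBlock(
        origin_index=(int(i), int(j), int(k)),
        values=array[i : i + BLOCK_SIZE, j : j + BLOCK_SIZE, k : k + BLOCK_SIZE, :],
        center=_block_center(grid.spec, corner),
        label=label,
    )


def _inside(spec: GridSpec, corner: np.ndarray) -> bool:
    return bool(np.all(corner >= 0) and np.all(corner + BLOCK_SIZE <= np.asarray(spec.shape)))


def positive_blocks(grid: DescriptorGrid, site_center) -> list[SampleBlock]:
    """The 4×4×4 = 64 blocks whose centers lie within [−2, +2) Å of the site
    center (snapped to the voxel lattice); fewer near the grid boundary."""
    site_center = np.asarray(site_center, dtype=float)
    snapped = _snap_to_block_lattice(grid.spec, site_center)
    array = grid.as_array()
    blocks = []
    for di in POSITIVE_OFFSETS:
        for dj in POSITIVE_OFFSETS:
            for dk in POSITIVE_OFFSETS:
                corner = snapped + (di, dj, dk)
                if _inside(grid.spec, corner):
                    blocks.append(_extract(grid, array, corner, label=1.0))
    if len(blocks) < len(POSITIVE_OFFSETS) ** 3:
        logger.warning(
            "site at %s is near the grid boundary: only %d positive blocks",
            site_center, len(blocks),
        )
    return blocks


def negative_blocks(
    grid: DescriptorGrid,
    site_centers,
    seed: int,
    n_samples: int = N_NEGATIVES,
    stride: int = NEGATIVE_STRIDE,
) -> list[SampleBlock]:
    """Stride-4 blocks outside every site's 20 Å envelope, down-sampled to 64.

    ``site_centers`` may be a single 3-vector or a sequence of them.
    """
    if not grid.normalized:
        raise GridPocketError("negative sampling expects a normalized descriptor")
    centers = np.atleast_2d(np.asarray(site_centers, dtype=float))
    snapped = [_snap_to_block_lattice(grid.spec, c) for c in centers]
    array = grid.as_array()
    shape = np.asarray(grid.spec.shape)
    candidates = []
    for i in range(0, shape[0] - BLOCK_SIZE + 1, stride):
        for j in range(0, shape[1] - BLOCK_SIZE + 1, stride):
            for k in range(0, shape[2] - BLOCK_SIZE + 1, stride):
                corner = np.array([i, j, k])
                # centers are on the same 1 Å lattice, so Chebyshev distance of
                # corners equals Chebyshev distance of block centers
                if all(
                    np.max(np.abs(corner - s)) > ENVELOPE_HALF_WIDTH for s in snapped
                ):
                    candidates.append(corner)
    if len(candidates) < n_samples:
        logger.warning(
            "only %d negative candidates (< %d); keeping all", len(candidates), n_samples
        )
        chosen = candidates
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(candidates), size=n_samples, replace=False)
        chosen = [candidates[i] for i in sorted(idx)]
    return [_extract(grid, array, corner, label=0.0) for corner in chosen]


def save_descriptor(path, grid: DescriptorGrid) -> None:
    """Persist the 4 named channels plus GridSpec metadata to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["origin"] = grid.spec.origin
        f.attrs["shape"] = grid.spec.shape
        f.attrs["spacing"] = grid.spec.spacing
        f.attrs["normalized"] = grid.normalized
        g = f.create_group("channels")
        for name in CHANNEL_NAMES:
            g.create_dataset(name, data=grid.channels[name].values)


def load_descriptor(path) -> DescriptorGrid:
    with h5py.File(path, "r") as f:
        spec = GridSpec(
            origin=tuple(f.attrs["origin"]),
            shape=tuple(int(s) for s in f.attrs["shape"]),
            spacing=float(f.attrs["spacing"]),
        )
        channels = {
            name: ChannelGrid(spec=spec, values=f["channels"][name][...], channel_name=name)
            for name in CHANNEL_NAMES
        }
        return DescriptorGrid(spec=spec, channels=channels, normalized=bool(f.attrs["normalized"]))
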