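"""Synthetic protein-like fixtures with planted cavities.

Real training corpora for pocket prediction are large curated databases; this
module generates deterministic stand-ins: hollow atom shells whose sealed
interior cavity is the planted binding site.  Atoms are placed on two
concentric Fibonacci-sphere layers ~1.8 Å apart with ~1.5 Å in-layer spacing,
so the shell is contiguous under van der Waals occupancy and at least two
voxels thick — the cavity is enclosed along all seven scan directions.
Generation is a pure function of the spec; every file this module writes is
synthetic and labeled as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .descriptor import (
    DescriptorGrid,
    SampleBlock,
    compute_descriptor,
    negative_blocks,
    normalize,
    positive_blocks,
)
from .forcefield import default_forcefield
from .structures import Atom, ProteinStructure, write_pdbqt

_LAYER_GAP = 1.8  # Å between the two shell layers
_TARGET_SPACING = 1.55  # Å in-layer atom spacing
_TYPE_CYCLE = ("C", "C", "N", "C", "OA", "C", "N", "C", "OA", "C")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one hollow-shell fixture.

    ``n_atoms`` of None means "enough atoms to seal the shell" (computed from
    the shell area and the target spacing).  ``charge_scheme`` is one of
    zero / alternating / random.  A solid decoy lobe of protein mass is placed
    ``decoy_distance`` Å from the cavity center (0 disables it): real proteins
    are much larger than one pocket, and the lobe both extends the bounding
    box so negative blocks exist and supplies cavity-free protein interior as
    informative negatives.
    """

    n_atoms: int | None = None
    cavity_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cavity_radius: float = 6.5
    shell_radius: float = 9.0
    charge_scheme: str = "alternating"
    seed: int = 0
    decoy_distance: float = 24.0
    decoy_radius: float = 5.0
    aperture_angle: float = 0.0  # degrees; >0 opens a mouth in the shell

    def __post_init__(self):
        if not self.cavity_radius < self.shell_radius:
            raise ValueError("cavity_radius must be < shell_radius")
        if self.charge_scheme not in ("zero", "alternating", "random"):
            raise ValueError(f"unknown charge scheme {self.charge_scheme!r}")

    def resolved_n_atoms(self) -> int:
        """Number of shell atoms (the decoy lobe is counted separately)."""
        if self.n_atoms is not None:
            return self.n_atoms
        r1, r2 = self.shell_radius, self.shell_radius + _LAYER_GAP
        area = 4.0 * np.pi * (r1**2 + r2**2)
        return int(np.ceil(area / _TARGET_SPACING**2))

    def n_decoy_atoms(self) -> int:
        return 0 if self.decoy_distance == 0 else len(_ball_offsets(self.decoy_radius))

    def total_atoms(self) -> int:
        return self.resolved_n_atoms() + self.n_decoy_atoms()


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistant unit vectors."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5.0)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _ball_offsets(radius: float, spacing: float = 1.7) -> np.ndarray:
    """Cubic-lattice points filling a ball of the given radius."""
    m = int(np.floor(radius / spacing))
    axis = np.arange(-m, m + 1) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    return pts[np.linalg.norm(pts, axis=1) <= radius]


def fixture_charges(spec: FixtureSpec, n: int | None = None) -> np.ndarray:
    """The per-atom charges the generator assigns (bookkeeping helper).

    ``n`` defaults to the spec's atom count; an aperture removes shell atoms,
    in which case the generator passes the surviving count.
    """
    if n is None:
        n = spec.total_atoms()
    if spec.charge_scheme == "zero":
        return np.zeros(n)
    if spec.charge_scheme == "alternating":
        q = np.full(n, 0.2)
        q[1::2] = -0.2
        return q
    rng = np.random.default_rng(spec.seed + 7919)
    return rng.normal(0.0, 0.15, n)


def make_hollow_shell(spec: FixtureSpec) -> tuple[ProteinStructure, np.ndarray]:
    """Build the fixture; returns (structure, planted site center)."""
    ff = default_forcefield()
    n = spec.resolved_n_atoms()
    if n < 4:
        raise ValueError("cannot pack a shell with fewer than 4 atoms")
    r1, r2 = spec.shell_radius, spec.shell_radius + _LAYER_GAP
    n1 = max(4, int(round(n * r1**2 / (r1**2 + r2**2))))
    n2 = n - n1
    rng = np.random.default_rng(spec.seed)
    center = np.asarray(spec.cavity_center, dtype=float)
    mouth_axis = rng.normal(size=3)
    mouth_axis /= np.linalg.norm(mouth_axis)
    cos_aperture = np.cos(np.deg2rad(spec.aperture_angle))
    points = []
    for radius, count in ((r1, n1), (r2, n2)):
        if count <= 0:
            continue
        unit = _fibonacci_sphere(count)
        jitter = rng.normal(0.0, 0.12, size=(count, 3))
        layer = center + unit * radius + jitter
        if spec.aperture_angle > 0:
            # open a pocket mouth: drop atoms inside the spherical cap
            layer = layer[unit @ mouth_axis < cos_aperture]
        points.append(layer)
    if spec.decoy_distance > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        decoy_center = center + direction * spec.decoy_distance
        offsets = _ball_offsets(spec.decoy_radius)
        jitter = rng.normal(0.0, 0.12, size=offsets.shape)
        points.append(decoy_center + offsets + jitter)
    positions = np.concatenate(points)
    charges = fixture_charges(spec, len(positions))
    atoms = []
    for i, pos in enumerate(positions):
        atom_type = _TYPE_CYCLE[i % len(_TYPE_CYCLE)]
        atoms.append(
            Atom(
                serial=i + 1,
                name=atom_type[:1],
                element=atom_type[:1],
                position=pos,
                partial_charge=float(charges[i]),
                vdw_radius=ff.get(atom_type).radius,
                atom_type=atom_type,
                resname="SYN",
                resseq=i // 10 + 1,
            )
        )
    structure = ProteinStructure(atoms=atoms, id=f"synthetic-shell-{spec.seed}")
    return structure, center.copy()


def random_fixture_spec(rng: np.random.Generator) -> FixtureSpec:
    """A random fixture sized like a large substrate-binding cleft (~15 Å wide).

    The cavity must stay wider than the 4 Å prediction stride: pocket calling
    needs the classifier to keep scoring blocks positively ~6 Å off-center,
    which requires the cavity to still cover those block centers.
    """
    cavity_radius = float(rng.uniform(7.2, 8.2))
    return FixtureSpec(
        cavity_center=tuple(rng.uniform(-3.0, 3.0, size=3)),
        cavity_radius=cavity_radius,
        shell_radius=cavity_radius + 2.5,
        charge_scheme=str(rng.choice(["alternating", "random"])),
        seed=int(rng.integers(0, 2**31 - 1)),
        aperture_angle=float(rng.uniform(0.0, 35.0)),
    )


@dataclass
class LabeledCorpus:
    """Fixtures plus their labeled 16³ blocks and a train/val/test split."""

    specs: list[FixtureSpec]
    proteins: list[ProteinStructure]
    site_centers: list[np.ndarray]
    grids: list[DescriptorGrid]  # normalized descriptors
    blocks: list[list[SampleBlock]]  # per protein, positives then negatives
    split: dict[str, list[int]]

    def protein_blocks(self, indices) -> list[SampleBlock]:
        return [b for i in indices for b in self.blocks[i]]

    def split_blocks(self, name: str) -> list[SampleBlock]:
        return self.protein_blocks(self.split[name])


def make_labeled_corpus(
    n_proteins: int,
    seed: int,
    n_val: int = 0,
    n_test: int = 0,
) -> LabeledCorpus:
    """Generate fixtures and their 64+64 labeled blocks, bit-reproducibly.

    The split assigns the last ``n_test`` proteins to test and the ``n_val``
    before them to validation; splits are disjoint by construction.
    """
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    if n_val + n_test >= n_proteins:
        raise ValueError("split leaves no training proteins")
    rng = np.random.default_rng(seed)
    specs = [random_fixture_spec(rng) for _ in range(n_proteins)]
    neg_seeds = rng.integers(0, 2**31 - 1, size=n_proteins)
    proteins, centers, grids, blocks = [], [], [], []
    for spec_i, neg_seed in zip(specs, neg_seeds):
        protein, site = make_hollow_shell(spec_i)
        grid = normalize(compute_descriptor(protein))
        pos = positive_blocks(grid, site)
        neg = negative_blocks(grid, site, seed=int(neg_seed))
        proteins.append(protein)
        centers.append(site)
        grids.append(grid)
        blocks.append(pos + neg)
    n_train = n_proteins - n_val - n_test
    split = {
        "train": list(range(n_train)),
        "val": list(range(n_train, n_train + n_val)),
        "test": list(range(n_train + n_val, n_proteins)),
    }
    return LabeledCorpus(
        specs=specs,
        proteins=proteins,
        site_centers=centers,
        grids=grids,
        blocks=blocks,
        split=split,
    )


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the fixture PDBQT plus a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protein, site = make_hollow_shell(spec)
    pdbqt = out / f"{protein.id}.pdbqt"
    meta = out / f"{protein.id}.json"
    write_pdbqt(protein, pdbqt)
    meta.write_text(
        json.dumps(
            {
                "synthetic": True,
                "spec": asdict(spec),
                "site_center": [float(v) for v in site],
                "n_atoms": len(protein),
            },
            indent=2,
        )
        + "\n"
    )
    return pdbqt, meta
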