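"""Pocket calling: stride-4 block scan, thresholding, DBSCAN, scoring.

A trained classifier scores every fully contained 16³ block on a 4 Å lattice.
Blocks with probability ≥ 0.5 are clustered with DBSCAN on their center
coordinates (Eps = step + 1 = 5 Å, MinPts = 7); each cluster becomes one
pocket whose center is the unweighted mean of member block centers and whose
score is the mean member probability.  Noise blocks are discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import DBSCAN

from .descriptor import BLOCK_SIZE, DescriptorGrid, SampleBlock, _block_center
from .errors import GridPocketError
from .network import Network, predict_blocks


@dataclass(frozen=True)
class ClusteringParams:
    """DBSCAN and scan parameters; Eps defaults to step + 1."""

    step: int = 4  # Å sampling stride
    eps: float | None = None  # Å; None -> step + 1
    min_pts: int = 7
    threshold: float = 0.5

    def __post_init__(self):
        if self.eps is None:
            object.__setattr__(self, "eps", float(self.step + 1))
        if self.eps <= 0 or self.min_pts < 1 or not (0 < self.threshold < 1):
            raise ValueError("invalid clustering parameters")


@dataclass
class PocketPrediction:
    """One predicted pocket: mean member-block center and mean probability."""

    center: np.ndarray
    score: float
    member_blocks: list[SampleBlock]

    @property
    def n_blocks(self) -> int:
        return len(self.member_blocks)


def scan_protein(
    grid: DescriptorGrid,
    model: Network,
    params: ClusteringParams | None = None,
) -> list[tuple[SampleBlock, float]]:
    """Score all fully contained 16³ blocks on the stride-step lattice."""
    params = params or ClusteringParams()
    if not grid.normalized:
        raise GridPocketError("scan requires a normalized descriptor")
    shape = grid.spec.shape
    if any(s < BLOCK_SIZE for s in shape):
        raise GridPocketError(f"grid {shape} is smaller than one {BLOCK_SIZE}^3 block")
    array = grid.as_array()
    blocks = []
    for i in range(0, shape[0] - BLOCK_SIZE + 1, params.step):
        for j in range(0, shape[1] - BLOCK_SIZE + 1, params.step):
            for k in range(0, shape[2] - BLOCK_SIZE + 1, params.step):
                corner = np.array([i, j, k])
                blocks.append(
                    SampleBlock(
                        origin_index=(i, j, k),
                        values=array[i : i + BLOCK_SIZE, j : j + BLOCK_SIZE, k : k + BLOCK_SIZE, :],
                        center=_block_center(grid.spec, corner),
                    )
                )
    probs = predict_blocks(model, blocks)
    for b, p in zip(blocks, probs):
        b.label = float(p)
    return list(zip(blocks, (float(p) for p in probs)))


def cluster_positive_blocks(
    scored: list[tuple[SampleBlock, float]],
    params: ClusteringParams | None = None,
) -> list[PocketPrediction]:
    """DBSCAN the blocks passing the threshold into scored pockets (desc. order)."""
    params = params or ClusteringParams()
    passing = [(b, p) for b, p in scored if p >= params.threshold]
    if not passing:
        return []
    centers = np.array([b.center for b, _ in passing])
    labels = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit_predict(centers)
    pockets = []
    for lab in sorted(set(labels) - {-1}):
        members = [pb for pb, l in zip(passing, labels) if l == lab]
        blocks = [b for b, _ in members]
        probs = np.array([p for _, p in members])
        pockets.append(
            PocketPrediction(
                center=np.mean([b.center for b in blocks], axis=0),
                score=float(probs.mean()),
                member_blocks=blocks,
            )
        )
    return top_n(pockets, len(pockets))


def top_n(pockets: list[PocketPrediction], n: int) -> list[PocketPrediction]:
    """Highest-scoring pockets first; ties broken by size, then center order."""
    ordered = sorted(
        pockets,
        key=lambda p: (-p.score, -p.n_blocks, tuple(np.round(p.center, 6))),
    )
    return ordered[: max(n, 0)]


def predict_pockets(
    grid: DescriptorGrid,
    model: Network,
    params: ClusteringParams | None = None,
) -> list[PocketPrediction]:
    """Scan + threshold + cluster in one call."""
    params = params or ClusteringParams()
    return cluster_positive_blocks(scan_protein(grid, model, params), params)


def pockets_to_records(pockets: list[PocketPrediction]) -> list[dict]:
    return [
        {
            "rank": i + 1,
            "x": float(p.center[0]),
            "y": float(p.center[1]),
            "z": float(p.center[2]),
            "score": p.score,
            "n_blocks": p.n_blocks,
        }
        for i, p in enumerate(pockets)
    ]


def write_pockets_json(pockets: list[PocketPrediction], path) -> None:
    Path(path).write_text(json.dumps(pockets_to_records(pockets), indent=2) + "\n")


def write_pockets_tsv(pockets: list[PocketPrediction], path) -> None:
    rows = ["rank\tx\ty\tz\tscore\tn_blocks"]
    for r in pockets_to_records(pockets):
        rows.append(
            f"{r['rank']}\t{r['x']:.3f}\t{r['y']:.3f}\t{r['z']:.3f}"
            f"\t{r['score']:.4f}\t{r['n_blocks']}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def write_pockets_pdb(pockets: list[PocketPrediction], path) -> None:
    """One pseudo-atom HETATM per pocket center, for visualization."""
    lines = []
    for i, p in enumerate(pockets, start=1):
        x, y, z = p.center
        lines.append(
            f"HETATM{i:5d}  C   PKT A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{p.score:6.2f}{0.0:6.2f}           C"
        )
    Path(path).write_text("\n".join(lines) + "\n")
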