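"""Center-offset evaluation of pocket predictions.

The quality measure is the Euclidean distance (offset, Å) between a predicted
pocket center and the actual site center (the ligand atom centroid).  Top-N
evaluation keeps the N highest-scoring pockets and reports the smallest
offset among them; a prediction is a 4 Å hit when some evaluated pocket
center lies within 4 Å of any ligand atom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pockets import PocketPrediction, top_n
from .structures import LigandStructure

NO_PREDICTION = math.inf  #: sentinel offset when a protein has no pockets


def offset(predicted, actual) -> float:
    """Euclidean distance between two centers, Å."""
    return float(np.linalg.norm(np.asarray(predicted, float) - np.asarray(actual, float)))


def topN_offset(pockets: list[PocketPrediction], actual, n: int) -> float:
    """Min offset over the n highest-ranked pockets; inf when there are none."""
    best = top_n(pockets, n)
    if not best:
        return NO_PREDICTION
    return min(offset(p.center, actual) for p in best)


def hit_within(
    pockets: list[PocketPrediction],
    ligand: LigandStructure,
    radius: float = 4.0,
    n: int | None = None,
) -> bool:
    """True iff some evaluated pocket center is within ``radius`` of any ligand atom."""
    evaluated = pockets if n is None else top_n(pockets, n)
    if not evaluated:
        return False
    lig = ligand.positions
    return any(
        float(np.min(np.linalg.norm(lig - p.center, axis=1))) <= radius for p in evaluated
    )


@dataclass
class EvaluationRecord:
    """Per-protein evaluation: ranked pockets against one actual site center."""

    protein_id: str
    actual_center: np.ndarray
    pockets: list[PocketPrediction]
    offset_top1: float = field(init=False)
    offset_top3: float = field(init=False)
    offset_top5: float = field(init=False)
    hit_4A: bool = field(init=False)

    def __post_init__(self):
        self.actual_center = np.asarray(self.actual_center, dtype=float)
        self.offset_top1 = topN_offset(self.pockets, self.actual_center, 1)
        self.offset_top3 = topN_offset(self.pockets, self.actual_center, 3)
        self.offset_top5 = topN_offset(self.pockets, self.actual_center, 5)
        self.hit_4A = bool(self.offset_top3 <= 4.0)


def evaluate_protein(
    protein_id: str,
    pockets: list[PocketPrediction],
    actual_centers,
) -> EvaluationRecord:
    """Evaluate against one or more actual site centers; best site reported."""
    centers = np.atleast_2d(np.asarray(actual_centers, dtype=float))
    records = [EvaluationRecord(protein_id, c, pockets) for c in centers]
    return min(records, key=lambda r: r.offset_top3)


def summarize(
    records: list[EvaluationRecord],
    bin_edges,
    which: str = "offset_top3",
) -> dict:
    """Offset distribution and error totals over a set of evaluated proteins.

    Returns per-bin proportions (over proteins with a prediction), the error
    sum Σ offsets, the mean offset, the mean pocket count per protein and the
    number of proteins with no prediction (reported separately, not dropped).
    """
    if not records:
        raise ValueError("no records to summarize")
    offsets = np.array([getattr(r, which) for r in records])
    predicted = offsets[np.isfinite(offsets)]
    edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(predicted, bins=edges)
    proportions = counts / len(predicted) if len(predicted) else counts.astype(float)
    table = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
            "proportion": proportions,
        }
    )
    return {
        "bins": table,
        "error_sum": float(predicted.sum()),
        "mean_offset": float(predicted.mean()) if len(predicted) else math.nan,
        "mean_pocket_count": float(np.mean([len(r.pockets) for r in records])),
        "n_no_prediction": int(np.sum(~np.isfinite(offsets))),
        "n_hit_4A": int(sum(r.hit_4A for r in records)),
    }
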