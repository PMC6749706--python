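"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: the PSP oracle walks scan
lines in pure Python, the energy oracles are all-pairs double loops without
spatial indexing, and the DBSCAN oracle is a textbook queue implementation.
"""

from __future__ import annotations

import numpy as np

DIRECTIONS = [
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (-1, 1, 1),
]


def psp_counts_bruteforce(protein_mask: np.ndarray) -> np.ndarray:
    """Walk every scan line in every direction; mark solvent runs bounded by
    protein on both ends.  Runs touching the boundary do not count."""
    shape = protein_mask.shape
    counts = np.zeros(shape, dtype=int)
    for d in DIRECTIONS:
        starts = _line_starts(shape, d)
        for start in starts:
            line = []
            v = np.array(start)
            while all(0 <= v[a] < shape[a] for a in range(3)):
                line.append(tuple(v))
                v = v + d
            _mark_runs(line, protein_mask, counts)
    return counts


def _line_starts(shape, d):
    """All voxels with no in-grid predecessor along d."""
    starts = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                prev = (i - d[0], j - d[1], k - d[2])
                if not all(0 <= prev[a] < shape[a] for a in range(3)):
                    starts.append((i, j, k))
    return starts


def _mark_runs(line, mask, counts):
    run = []
    seen_protein = False
    for v in line:
        if mask[v]:
            if seen_protein:
                for s in run:
                    counts[s] += 1
            run, seen_protein = [], True
        elif seen_protein:
            run.append(v)
    # a trailing run ends at the boundary: not a PSP event


def voxel_centers(origin, shape):
    centers = np.empty(tuple(shape) + (3,))
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                centers[i, j, k] = np.asarray(origin) + np.array([i, j, k]) + 0.5
    return centers


def vdw_bruteforce(positions, pair_params, origin, shape, cutoff=8.0, min_r=0.05):
    """All-pairs 12-6 sum; pair_params[j] = (A, B) for protein atom j."""
    centers = voxel_centers(origin, shape)
    values = np.zeros(shape)
    for idx in np.ndindex(*shape):
        c = centers[idx]
        for pos, (a_coef, b_coef) in zip(positions, pair_params):
            r = max(float(np.linalg.norm(c - pos)), min_r)
            if r <= cutoff:
                values[idx] += a_coef / r**12 - b_coef / r**6
    return values


def hbond_bruteforce(probe_offsets, atom_entries, origin, shape, cutoff=8.0, min_r=0.05):
    """Max-|E| 12-10 candidate per voxel.

    atom_entries: list of (position, {probe_index: (C, D)}) giving, per protein
    atom, the 12-10 coefficients against each probe atom it can pair with.
    """
    centers = voxel_centers(origin, shape)
    values = np.zeros(shape)
    for idx in np.ndindex(*shape):
        best = 0.0
        for pos, per_probe in atom_entries:
            for pi, (c_coef, d_coef) in per_probe.items():
                site = centers[idx] + np.asarray(probe_offsets[pi])
                r = max(float(np.linalg.norm(site - pos)), min_r)
                if r <= cutoff:
                    e = c_coef / r**12 - d_coef / r**10
                    if abs(e) > abs(best):
                        best = e
        values[idx] = best
    return values


def coulomb_bruteforce(positions, charges, origin, shape, k_const, exponent=2,
                       cutoff=8.0, min_r=0.05):
    centers = voxel_centers(origin, shape)
    values = np.zeros(shape)
    for idx in np.ndindex(*shape):
        c = centers[idx]
        for pos, q in zip(positions, charges):
            r = max(float(np.linalg.norm(c - pos)), min_r)
            if r <= cutoff:
                values[idx] += k_const * q / r**exponent
    return values


def dbscan_bruteforce(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Classic DBSCAN; neighborhoods include the point itself.  Returns labels
    with -1 for noise; cluster numbering follows discovery order."""
    n = len(points)
    labels = np.full(n, -2)  # -2 unvisited
    neighbors = [
        [j for j in range(n) if np.linalg.norm(points[i] - points[j]) <= eps]
        for i in range(n)
    ]
    cluster = -1
    for i in range(n):
        if labels[i] != -2:
            continue
        if len(neighbors[i]) < min_pts:
            labels[i] = -1
            continue
        cluster += 1
        labels[i] = cluster
        queue = list(neighbors[i])
        while queue:
            j = queue.pop()
            if labels[j] == -1:
                labels[j] = cluster
            if labels[j] != -2:
                continue
            labels[j] = cluster
            if len(neighbors[j]) >= min_pts:
                queue.extend(neighbors[j])
    return labels
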