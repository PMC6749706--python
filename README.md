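# gridpocket

Drug discovery starts with finding where on a protein a small molecule can
bind. `gridpocket` predicts such binding pockets from a protein structure by
combining the two classic families of pocket detectors — geometry-based cavity
scanning and energy-based probe mapping — into one voxel descriptor that a
small 3D convolutional network classifies.

It is a library plus a CLI for structural bioinformaticians who want a
self-contained, CPU-only implementation of the grid-descriptor approach:
parsing PDB/PDBQT, building the descriptor channels, training the block
classifier, calling pockets, and scoring predictions.

## Method

A protein is placed in a 1 Å cubic voxel grid with an 8 Å solvent buffer.
Four channels are computed per voxel:

1. **shape** — a lightly modified LIGSITE scan. Voxels within a van der Waals
   radius of an atom are protein, the rest solvent. The grid is scanned along
   x, y, z and the four cube diagonals; every solvent voxel inside a
   protein–solvent–protein run gains one count per direction, so values lie in
   0–7 (7 = enclosed from all directions, i.e. deep cavity).
2. **vdw** — a united-atom −CH₃ probe at each voxel;
   E = Σᵢⱼ (A/r¹² − B/r⁶) with A = εr₀¹², B = 2εr₀⁶, AutoDock/Amber combining
   rules ε = √(εᵢεⱼ), r₀ = rᵢ + rⱼ.
3. **hbond** — an −OH probe with the 12-10 potential E = C/r¹² − D/r¹⁰,
   C = 5εr₀¹², D = 6εr₀¹⁰ (e.g. a 5 kcal/mol well at 1.9 Å against oxygen).
   Hydrogen bonds saturate, so the single candidate with the largest |E| is
   kept instead of a sum.
4. **coulomb** — a unit positive charge probe; E = Σ K·q₁q₂/r² using the
   partial charges of the PDBQT file.

All pairwise terms cut off at 8 Å. Voxel values are normalized to (−1, 1) by
v ← (2/π)·arctan(v). Training samples are 16³ blocks: 64 positives whose
centers lie within 2 Å of the site center (a 20 Å envelope, 4×4×4 = 64) and
stride-4 negatives outside every envelope, down-sampled to 64 — 128 blocks
per protein. The classifier is a 6-conv 3D CNN (2→4→8→16→32→64 filters,
kernels 8³/8³/4³/4³/2³/2³, two 2³ max-pools, dropout 0.25/0.25/0.5, dense 128,
sigmoid output; the flattened feature length is 64·4³ = 4096).

At prediction time every 16³ block on a 4 Å lattice is scored; blocks with
probability ≥ 0.5 are clustered with DBSCAN (Eps = step + 1 = 5 Å,
MinPts = 7). Each cluster is a pocket: center = mean of member block centers,
score = mean member probability. Predictions are ranked by score and judged
by the offset (Å) between the predicted and actual site center (Top-1/3/5).

No external database is needed: `gridpocket.synthetic` generates sealed
hollow-shell "proteins" with planted cavities (plus a decoy lobe of solid
protein mass) and writes valid PDBQT, so the whole pipeline is testable
offline.

## Worked example

```bash
gridpocket simulate --n 1 --seed 3 --out fixtures/
gridpocket train --n-proteins 20 --seed 11 --out model.npz
gridpocket predict --in fixtures/synthetic-shell-202139719.pdbqt \
    --model model.npz --out pockets.json
```

A library session with the same machinery:

```python
>>> import gridpocket as gp
>>> corpus = gp.make_labeled_corpus(20, seed=11, n_val=2, n_test=4)
>>> cfg = gp.NetworkConfig(seed=5)
>>> model = gp.build_model(cfg)
>>> gp.train_model(model, corpus.split_blocks("train"), corpus.split_blocks("val"), cfg)
>>> i = corpus.split["test"][0]
>>> pockets = gp.predict_pockets(corpus.grids[i], model)
>>> [(p.center.round(1).tolist(), round(p.score, 3), p.n_blocks) for p in pockets]
[([0.5, -1.8, -0.2], 0.996, 23)]
>>> round(gp.offset(pockets[0].center, corpus.site_centers[i]), 2)
2.31
```

The held-out fixture yields one pocket of 23 blocks with mean block
probability 0.996; its center lies 2.31 Å from the planted cavity center —
within the 4 Å radius conventionally counted as a correct site prediction.

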