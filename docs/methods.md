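# Methods notes

## Descriptor model

A protein structure (PDBQT for charges and AutoDock atom types, plain PDB
accepted with zero charges and element-derived types) is embedded in a 1 Å
cubic lattice. The lattice origin is the per-axis coordinate minimum minus an
8 Å buffer; each axis length is ⌈extent⌉ + 16 voxels, and the voxel center of
index (i,j,k) is origin + (i,j,k) + 0.5 (the center convention is a choice;
any fixed convention works as the whole pipeline shares it).

**Shape channel.** Occupancy: a voxel is protein if its center lies within
the van der Waals radius of any atom. The occupancy mask is scanned along
x, y, z and the four pairwise non-antiparallel cube diagonals
(1,1,1), (1,1,−1), (1,−1,1), (−1,1,1), stepping one voxel per move. Every
maximal solvent run bounded by protein voxels at both ends contributes +1 to
each of its voxels; a run touching the grid boundary is open to bulk solvent
and contributes nothing, and protein voxels always stay 0. Values are
integers in [0, 7]. The implementation propagates "protein seen behind me"
masks by repeated shifted ORs (O(L) vectorized passes per direction); it is
validated against a pure-Python line-walking oracle on random masks.

**Energy channels.** A probe is placed at every voxel center:

* van der Waals: united-atom −CH₃ (AutoDock type C). Summed 12-6 terms over
  all protein atoms within the cutoff. The probe is modeled as one united
  atom because a multi-atom rigid probe would need an orientation convention
  that nothing in the method constrains; a single-atom probe keeps the sum
  orientation-free.
* hydrogen bond: −OH modeled as OA at the voxel center and HD displaced
  0.96 Å along +x (a fixed, documented orientation chosen for determinism).
  Candidate pairs are donor-H/acceptor combinations only — probe HD against
  protein N/NA/OA/SA, probe OA against protein HD — with tabulated pair
  wells (5 kcal/mol at 1.9 Å for N/O acceptors, 1 kcal/mol at 2.5 Å for
  sulfur) in the AutoDock convention. Because hydrogen bonding saturates,
  the voxel value is the single candidate energy of maximum magnitude, not a
  sum; a voxel with no candidate in range is 0.
* Coulomb: unit positive point charge; value Σ K·q₁q₂/r² with q₁ = +1,
  K = 332.0636 kcal·Å/(mol·e²). The inverse-square form is the descriptor's
  definition and is kept as such; `EnergyParams(coulomb_exponent=1)` gives
  the physical 1/r potential for users who want it.

All pairwise terms are cut off sharply at 8 Å center distance (no switching
function). Pair parameters ship as a versioned AutoDock4-style JSON table
(per-type ε, per-atom well radius r₀ = Rii/2, occupancy radius); users can
load their own table.

## Normalization

Every voxel value v in all four channels is mapped to (2/π)·arctan(v), which
compresses the unbounded energy ranges into (−1, 1) while preserving sign and
monotonicity. Numerical guards: pair distances are floored at 0.05 Å and
energies clipped to ±1e15 before the arctan, so voxels that sit essentially
on top of an atom normalize to values strictly inside (−1, 1) in float64
instead of rounding to ±1. Double normalization is an error, and
normalization happens before block extraction so overlapping blocks share
voxel values.

## Block sampling

Positive blocks: the site center (ligand atom centroid) is snapped to a
lattice-aligned reference block center; block-center offsets of
{−2, −1, 0, +1} Å per axis give 4³ = 64 positives spanning a 20 Å envelope
(16 + 2 + 2). The half-open interval [−2, +2) is the only integer-lattice
reading that yields exactly 64. Because those four offsets average −0.5, the
reference is taken half a voxel above the site so the 64-block cloud is
centered on it; with a plain nearest-center snap one side of every axis ends
up systematically 1 Å farther from the training envelope, and the trained
classifier's probability cliffs all land on that side. Negative blocks: the stride-4 block lattice,
keeping blocks whose center is outside the 20 Å envelope of every annotated
site (Chebyshev distance > 10 Å), uniformly down-sampled without replacement
to 64 with a recorded seed — 128 blocks per protein. Blocks are always fully
contained in the grid; a site near the boundary yields fewer positives with
a warning. For multi-site proteins each site contributes its own positives
and the negative cap stays per protein.

## Classifier

Channel-first 4×16³ input; Conv3D(2, 8³) → Conv3D(4, 8³) → MaxPool 2³ →
Dropout 0.25 → Conv3D(8, 4³) → Conv3D(16, 4³) → MaxPool 2³ → Conv3D(32, 2³)
→ Conv3D(64, 2³) → Dropout 0.25 → Flatten (4096) → Dense 128 → Dropout 0.5 →
Dense 1 + sigmoid; all convolutions ReLU with 'same' padding. The published
layer table lists inconsistent tensor shapes around the flatten stage (a
32-channel input to a layer that follows a 64-filter convolution); the stack
here resolves them in the only way consistent with the printed dense input of
4096 = 64·4³.

Training uses binary cross-entropy with Adam (lr 1e−3), batch 32, and
Keras-style early stopping monitored on validation accuracy (patience 1,
weights of the first best epoch restored); loss, optimizer and schedule are
configuration, not architecture. Accuracy-monitored stopping matters here:
block labels are defined only at site offsets ≤ 2 Å (positive) and > 10 Å
(negative), while pocket calling needs graded probabilities at the
intermediate offsets the stride-4 scan actually visits. On a cleanly
separable corpus validation accuracy saturates within an epoch, and training
past that point sharpens the decision boundary until intermediate-offset
blocks all score near zero and no MinPts = 7 cluster can form — stopping at
the first accuracy plateau keeps the classifier's generalization gradual, as
the pocket-calling stage presumes. The network is
implemented in numpy: convolutions and both of their gradients are evaluated
as zero-padded real-FFT products with a per-axis transform length
≥ max(2D−1, D+k−1), which makes forward, input-gradient and weight-gradient
linear convolutions wrap-around free while sharing one cached input spectrum.
Keras-style 'same' padding for even kernels pads (k−1)//2 left and k//2
right. Max-pool gradients route to the first argmax of each 2³ window.
Everything is float32 and deterministic given the config seed (weights,
shuffling and dropout all derive from it).

## Pocket calling and evaluation

All fully contained 16³ blocks on the stride-4 lattice are scored; blocks
with probability ≥ 0.5 go to DBSCAN on block-center coordinates with
Eps = step + 1 = 5 Å and MinPts = 7. With this geometry face-adjacent lattice
blocks (4 Å) are neighbors and diagonal ones (4√2 ≈ 5.66 Å) are not. Noise
blocks are discarded, not merged. A pocket's center is the unweighted mean of
member block centers and its score the mean member probability; ties in the
score ranking break by cluster size, then lexicographic center. Evaluation
reports the Euclidean offset to the actual site center for Top-1/3/5
selections (proteins with no prediction carry an infinite-offset sentinel and
are counted separately, never dropped), the 4 Å hit criterion against ligand
atoms, binned offset proportions, error sums and mean pocket counts.

## Synthetic fixtures

`gridpocket.synthetic` generates the study conditions: hollow atom shells
whose sealed interior is the planted site. Two concentric Fibonacci-sphere
layers 1.8 Å apart with ~1.55 Å in-layer spacing and 0.12 Å positional
jitter make the shell contiguous under occupancy and ≥ 2 voxels thick, so a
sealed cavity is enclosed along all seven scan directions. Corpus cavities
are drawn with radii 7.2–8.2 Å (a large substrate-binding cleft, ~15 Å
across) with the shell 2.5 Å outside; pocket calling constrains this size
from below, since a MinPts = 7 cluster on the 4 Å scan lattice requires the
classifier to keep passing blocks whose centers sit ~6 Å off the site, which
in turn requires the cavity to still cover those centers. An optional
spherical-cap aperture (up to 35° in the corpus) opens a pocket mouth in the
shell, making the positive class heterogeneous the way real, partially open
pockets are. A solid decoy lobe of lattice-packed atoms (radius 5 Å) sits
24 Å from the cavity center: real proteins are far larger than one pocket,
and without that extra mass the bounding box is so tight that no stride-4
block lies outside the 20 Å positive envelope — the lobe both makes negative
blocks exist and supplies cavity-free protein interior as informative
negatives. Charges follow a zero / alternating ±0.2 e / seeded-random
N(0, 0.15 e) scheme. Generation is a pure function of the spec; all
randomness is seeded.

What the fixtures do not emulate: real secondary structure, rotamers, partial
solvent exposure of pockets (the planted cavity is fully sealed, which real
pockets are not), realistic charge distributions, and crystallographic noise.
Passing the recovery tests therefore shows the pipeline is implemented
coherently end to end — descriptor, sampling, training, scanning, clustering
— not that the trained toy model transfers to real proteins; training at
database scale is out of scope here.

## Problem sizes and defaults

Desk-scale defaults keep everything single-CPU friendly: corpora of tens of
fixtures (~1100 atoms, ~40–58 voxel grids each), 128 blocks per protein,
5 epochs with early stopping. The end-to-end recovery test trains on 30
fixtures (3840 blocks), validates on 4 and holds out 10; its pass criterion
is the top-ranked pocket landing within 4 Å of the planted center on at
least 8 of the 10 held-out fixtures. Oracle-equality tests run on ≤ 50-atom
proteins and ≤ 20³ grids at 1e−9 relative tolerance; the PSP scan is checked
against its line-walking oracle on 100 random 12³ masks.

## Known limitations

* The inverse-square Coulomb form and the fixed −OH probe orientation are
  definitional choices of the descriptor, not physical claims.
* Energy probes are evaluated at protein-interior voxels; values there are
  large and positive and are tamed by the arctan map rather than masked.
* DBSCAN with MinPts = 7 marks sparse but genuine block chains as noise; a
  pocket must produce a locally dense cluster of passing blocks to be
  reported.
* The PDBQT reader supports the fixed-column dialect with a logged
  whitespace-separated fallback; mmCIF, protonation and charge assignment
  are out of scope (inputs are assumed prepared).
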