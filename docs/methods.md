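# Methods

## Problem and representation

The package classifies individual driving trips as *normal* or
*abnormal* from GPS alone.  The motivating application is mobility-based
screening of older drivers: disorientation associated with mild
cognitive impairment shows up in everyday driving as repeated path
selections, cyclic routes, and long unnecessary U-turns.  These
behaviors are properties of a trip's overall spatial structure, not of
any single GPS fix, and trips vary freely in length, location and
shape — which is awkward for models that want fixed-size input.

The core idea is a trip-specific binary occupancy grid.  For a trip
with points (φ_t, λ_t):

1. compute the trip's bounding box [min φ, max φ] × [min λ, max λ];
2. divide it into H × W equal cells (default 128 × 128; 64 × 64 in the
   scaled-down experiments);
3. set G[i, j] = 1 iff at least one point falls in cell (i, j).

Because the box is the trip's own, the encoding is invariant to
translation and to uniform scaling about the trip centroid, and the
binary matrix discards point order and sampling density.  Cells are
half-open intervals with the final cell closed; row 0 is the
southernmost row, and PNG export flips vertically so north is up.
Latitude and longitude are scaled independently to fill the grid, so
aspect ratio is *not* preserved — a deliberate simplification that the
classifier has to tolerate (and that amplifies lateral structure in
elongated trips).  Degenerate axes (single points, exact east–west
tracks) are widened to a 1e-9-degree span by lowering the axis minimum,
pinning such points to the last cell — an exact operation in floating
point, so the invariances above hold bit-for-bit even for degenerate
trips.  Cells between consecutive points are *not* painted:
the grid marks visited cells only, with no line interpolation.

## Synthetic cohorts

The real cohort behind this problem is private clinical data, so the
package ships a simulator whose abnormal class realizes the behavior
taxonomy explicitly:

* **normal** — a correlated random walk: piecewise-constant heading with
  Gaussian drift (σ = 0.08 rad/step) and occasional ±90° turns
  (p = 0.01/step), emulating road-following without deliberate
  revisiting;
* **cycle** — `n_loops` (default 3) noisy closed circuits whose radius
  consumes the point budget;
* **repeated_segment** — the same sub-path traversed out, back, and out
  again; return passes ride one lane over;
* **long_uturn** — a forward leg, a reversal, and a retrace of ~40% of
  the trip one lane over.

Two numerical choices matter and are worth stating plainly.  First,
trips default to 600 points at a step of 1e-4 degrees (~11 m, i.e. a
~10-minute trip at 1 Hz urban speeds); much sparser trips paint
disconnected dot textures at 64×64 that no real 1 Hz recording
resembles.  Second, retraced passes carry a lateral *lane offset*
(default 2 steps): an exact retrace revisits exactly the same cells and
would be invisible in a binary grid, whereas real return traffic uses
the opposite lane and paints a parallel track.  The forward passes of
`repeated_segment` stay on the original lane, so repetition also
registers as genuine cell revisitation.

A `cell_revisit_ratio` statistic summarizes revisitation: the fraction
of visited cells entered in two or more distinct *visit runs* (maximal
blocks of consecutive indices in one cell).  Under default conditions
it is ≈0.01 for normal trips versus ≈0.2 (cycle) and ≈0.4
(repeated_segment), which is the separation the Monte-Carlo tests
assert.

Cohorts derive per-trip seeds from the master seed with a counter-keyed
`SeedSequence`, so cohorts are reproducible and extending one never
reshuffles existing trips; origins are jittered so every trip has its
own bounding box.  `hardened_config()` (heading noise 0.25, turn
probability 0.05, 2 loops) degrades — but does not erase — the abnormal
structure; beyond roughly twice that noise the U-turn class collapses
into the same scribbles as normal driving and the labels become
irreducibly ambiguous, which is why the hardened preset stops where it
does.

What the simulator does *not* model: road networks, speed and
acceleration profiles, GPS dropout and multipath noise, driver identity
across trips, or any longitudinal progression.  Passing tests on these
cohorts show that the pipeline can learn the stated spatial signatures
when they are present; they say nothing about the clinical
discriminability of real MCI driving data.

## Classifiers

All three models take (B, 1, H, W) input and emit two logits.

* **ViT** — convolutional 8×8/8 patch embedding into a 128-dimensional
  token space (256 patches at 128×128), a learnable class token, learnable
  positional embeddings over all tokens, six pre-norm transformer
  encoder layers (8 heads, 4× GELU MLP), final layer norm, linear head
  on the class token.  Head count and MLP ratio follow the standard ViT
  recipe; the tabulated design leaves them open.  Class token and
  positional embeddings initialize from N(0, 0.02²).
* **CNN** — three conv(3×3, same)+ReLU+maxpool(2×2) blocks at 16/32/64
  filters, flatten (16 384 features at 128×128), FC 256+ReLU, FC 2.
* **ResNet** — 7×7/2 stem to 16 channels (BN+ReLU), 3×3/2 max pool, four
  stages of two residual blocks at 16/32/64/128 channels with stride-2
  transitions and 1×1-projection shortcuts, global average pool, FC 2.

The layers live in `gridtraj.nn`, a small numpy library with
hand-derived backward passes (validated against finite differences in
the test suite) and no hidden randomness — no dropout, float32
throughout, all initialization drawn from a caller-supplied generator.
Forward cost depends only on (H, W, patch size), never on trip length.

Training uses Adam (lr 0.001), softmax cross-entropy, 50 epochs — the
same protocol for all three architectures so comparisons isolate the
representation — with batch size 32 and seeded shuffling.  No weight
decay, schedule or early stopping.  Prediction is the softmax argmax
with ties resolved toward class 0 (normal).

## Imbalance handling and evaluation

The abnormal class is the clinically relevant minority.  Minority-class
grids are augmented by exact lattice rotations (90°/180°/270°),
materialized at dataset-build time and applied to the training split
only; rotated copies inherit their source's trip id and always follow
it through the stratified split, so no augmented view of a test trip
can reach training.  When class counts tie, "minority" resolves to
abnormal.

Evaluation reports per-class precision, recall and F1 (0/0 defined as 0
with a warning), macro F1 (unweighted class mean — sensitive to the
minority) and weighted F1 (support-weighted mean).  The implementation
is plain arithmetic from confusion counts; the test suite checks it
against scikit-learn on 1 000 random prediction vectors.

## Experiments at desk scale

Two ablations mirror the questions asked of the real system: the effect
of data volume and of rotational augmentation.  Both run the entire
pipeline per cell, fully seeded.  Paired augmentation conditions share
cohort, split and model initialization bit-for-bit (the harness asserts
the test-split fingerprints match), so metric deltas are attributable
to training data alone.  Direction, not magnitude, is the quantity of
interest.

Problem sizes are chosen for a desktop CPU: the end-to-end
classification check uses 600-trip cohorts at 64×64 (CNN macro F1
≈ 0.96 held out, three seeds), and the augmentation experiment uses
hardened 400-trip cohorts at 10% minority and 32×32 — below 400 trips a
10% minority leaves so few abnormal test trips that macro F1 moves in
±0.1 quanta and the paired delta is dominated by seed noise.  At these
sizes a full paired ablation is a few CPU-minutes per model.  The
reduced two-layer ViT used in experiments is a speed concession; the
full six-layer tabulated ViT is the default elsewhere.

### A negative result on rotational augmentation

On these synthetic cohorts, minority rotation augmentation reliably
improves the CNN (mean paired macro-F1 delta ≈ +0.09, positive on every
seed) but consistently *degrades* the ViT and ResNet (deltas ≈ −0.03 to
−0.17 across hardened and clean cohorts, two and six encoder layers
alike).  The diagnosis: the simulator draws every trip's initial
heading uniformly at random, so the grid distribution is already
rotation-invariant — a plain ViT scores as well on a 90°-rotated test
set as on the original.  Rotating minority grids therefore adds no
orientation information; it only re-weights ~30 minority trips by 4×
with exactly-correlated copies.  The CNN's pooling bias lets it profit
from the re-balancing, while the higher-capacity ViT/ResNet overfit the
duplicates (training accuracy 1.0, worse minority precision *and*
recall held out).  Rotation augmentation earns its keep when the data
has orientation anisotropy — as real road-network trips do, aligned to
street grids and geography — and that anisotropy is precisely what this
simulator does not model.  The experiment harness reports the per-model
deltas either way.

## Known limitations

* The binary grid is blind to visit counts and timing; behaviors that
  revisit identical cells with no lateral separation are invisible by
  construction.
* Aspect-ratio distortion makes nearly-collinear trips fill the grid
  with amplified lateral noise.
* The numpy training loop is single-threaded and CPU-bound; it is meant
  for desk-scale cohorts (hundreds to low thousands of trips), not the
  72-million-record scale of production telematics.
* Synthetic separability is a property of the simulator's geometry
  programs; real-data F1 cannot be inferred from it.
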