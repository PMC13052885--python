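# Methods

This note documents the modeling choices behind `cloudshape`: what each
component assumes, which defaults matter and why, and what the synthetic
benchmark does and does not establish.

## The question and the experimental logic

A point-cloud classifier receives an object as an unordered set of 3D
surface samples. Two families dominate the field and embody different
inductive biases. **DGCNN** aggregates local edge features over neighbors
defined in *feature space* and keeps full spatial resolution throughout, so
nothing forces it to integrate information beyond local geometry.
The **Point Transformer** attends over neighbors in *3D space*, injects
relative-position information into every layer, and — crucially —
progressively collapses the point set through Transition Down stages, so
late layers necessarily summarize large object regions.

The pipeline asks which of these mechanisms produces *human-like*
robustness: people recognize objects from sparse dot displays almost
unimpaired, tolerate moderate local deformation, and are badly hurt when an
object's parts are spatially rearranged. The three stimulus families
operationalize exactly these contrasts, and the ablation/intervention
machinery isolates the responsible mechanism (the downsampling hierarchy).

## Synthetic stimuli

The generator replaces external CAD datasets. Each category is a fixed
assembly of surface primitives (box, cylinder, cone, sphere cap, torus
segment), each primitive assigned to a named part; the shipped roster
covers the ten recognition categories plus a car template for the
scrambling pool, with 3–12 parts per category.

Assumptions and choices:

* **Area-uniform sampling.** Points are allocated to primitives by exact
  surface area (largest-remainder rounding, so a 9:1 area ratio yields a
  9:1 point ratio up to ±1 point) and sampled uniformly on each surface via
  area-preserving parameterizations (e.g. √u radial sampling on disks,
  rejection sampling in the torus tube angle). This reproduces the
  "uniform surface samples" statistics that the density manipulation
  presupposes.
* **Instance variation.** Every size parameter is jittered uniformly by
  ±20% per instance, plus one global layout scale; real datasets vary
  within category in unspecified ways, and ±20% gives visibly distinct yet
  reliably recognizable instances. Opening/arc angles are treated as shape,
  not size, and are left un-jittered.
* **Frame conventions.** y is vertical everywhere; objects are centered on
  their centroid and scaled so the farthest point has norm 1. Inversion is
  the proper rotation (x, y, z) → (x, −y, −z) — a reflection would flip
  chirality, which physically turning an object upside down does not.
* **Determinism.** An instance is a pure function of
  (template, instance seed, point count); dataset manifests are
  byte-identical across runs with the same seed.

What the generator does *not* emulate: mesh topology, texture, realistic
within-category covariance of proportions, or the shape statistics of any
specific CAD corpus. Conclusions from the test suite are therefore about
the *mechanisms* (e.g. "downsampling confers density robustness on these
well-separated categories"), not about absolute accuracies on real data.

## Perturbation families

* **Density**: a uniformly random subset without replacement of size
  floor(p·N) (minimum 1) for p ∈ {0.2, 0.3, 0.4, 0.5, 0.6, 0.8, 1.0}; the
  rounding rule is pinned because 20% of 1024 is deliberately 204, not 205.
* **Lego voxelization**: occupancy grid with cubic cells of side v
  (grid anchored at the bounding-box minimum corner), faces not shared by
  two occupied cells enumerated, and n_out points (default: the input
  count) sampled uniformly over those *exposed* faces — interior faces are
  invisible in a rendered stimulus. Every pre-normalization sample lies
  exactly on a face plane; the result is re-normalized to the unit sphere.
  The grid sizes {0 (identity), 0.01, 0.05, 0.1, 0.2} form the condition
  grid, applied to already-normalized clouds.
* **Scrambling**: parts holding more than 30% of the points are first
  split by spectral clustering (3 clusters) on a symmetrized k = 10
  nearest-neighbor connectivity graph (k is a choice; only
  "nearest-neighbor affinity" is inherent to the method). A uniformly
  chosen anchor part is centered at the origin; every other part is
  centered and offset componentwise from Uniform(−0.6, 0.6); the whole
  cloud is then re-normalized, so each part's internal distance matrix is
  preserved up to one shared global scale.
* **Training augmentation** (applied every epoch, in this order): point
  dropout with ratio ~ Uniform[0, 0.875], the floor(ratio·N) dropped points
  replaced by the first point's coordinates (the count never changes);
  global scale from [0.8, 1.25]; per-axis shift from [−0.1, 0.1].

## Classifiers

Both networks are implemented on a small reverse-mode autodiff engine over
NumPy (`cloudshape._tensor`, `cloudshape.nn`); layers use channel-last
layout, batch normalization with running statistics, and Kaiming-uniform
initialization.

* **DGCNN** (default spec): four EdgeConv stages of widths 64/64/128/256
  with k = 20 neighbors recomputed in feature space per stage (self
  excluded — a zero edge difference is uninformative; ties break to the
  lowest index), multi-scale concatenation, a 1024-d embedding, global
  max+mean pooling, and a 512/256/40 head with LeakyReLU(0.2) and dropout
  0.5. Total: 1,809,576 trainable parameters.
* **Point Transformer** (default spec): a 3→32→32 MLP embedding, then five
  vector self-attention blocks (d_model = 512, k = 16 spatial neighbors,
  self included) alternating with four Transition Down stages that double
  the width (64→512) and shrink the point count along
  [N, N/4, N/16, N/64, N/256] (floor, minimum 1, for N not divisible by
  256). Attention weights are per-channel vectors, softmax-normalized over
  the k neighbors of each point; the positional term θ(p_i − p_j) enters
  both the attention logits and the values. Global mean pooling feeds a
  256/64/40 head. Total: 9,584,040 trainable parameters.
* **Farthest point sampling** is greedy max–min with ties to the lowest
  index. The default start point is the point farthest from the centroid:
  a canonical, order-independent choice that makes the full forward pass
  permutation invariant (a fixed start *index* would not be). When a stage
  holds fewer points than k, neighbors repeat the nearest available points
  so the forward pass stays total.

### Ablations and the intervention

* **NoAttn** replaces the attention weights with a fixed uniform 1/k (mean
  over the neighbors' value terms). The query/key and weight-generating
  maps are not instantiated — they would be dead parameters. This is one
  defensible reading of "remove attention"; it is isolated behind
  `ablate()` so alternatives can be plugged in.
* **NoPE** sets the positional term to zero and omits its map; the
  parameter layout is otherwise identical to the original. Note the *input
  embedding* still consumes raw coordinates (as in the reference design),
  so the full network is not translation invariant under NoPE — only the
  attention blocks themselves are; the tests check the block-level
  property.
* **NoDS** keeps every Transition Down at full resolution (pure local
  re-embedding): reduction is index selection, so the parameter count is
  exactly unchanged, which cleanly isolates the resolution hierarchy.
* **DGCNN + DS** inserts a Transition Down stage (reduction ratio 4,
  k = 16, width-preserving) after every EdgeConv. Because the stage outputs
  then live on shrinking point sets, the multi-scale concatenation gathers
  each earlier stage's features at the surviving points (every survivor
  existed at every earlier stage), leaving the head design unchanged.

## Training and evaluation

Adam at 1e-3 with a step schedule ×0.3 every 50 epochs (200 epochs at full
scale). The **desk profile** used by the test suite compresses this to 25
epochs (decay every 10), batch size 8, on 5 categories × 16 training
instances of 128-point clouds, with width-reduced specs
(DGCNN 16/16/32/32, embedding 64; Point Transformer widths 16/32/64,
d_model = 32, two Transition Down stages). These sizes were chosen so the
full behavioral battery — four model variants × three seeds — trains on a
single CPU core in a few minutes while leaving the mechanisms under study
intact; they are the package's benchmark conditions, not tuned quantities.

Evaluation restricts a classifier's logits to the categories shown in an
experiment (argmax over the subset, ties to the lowest class index). The
part-scrambling experiment additionally applies the *model-agreement
filter*: a scrambled stimulus is kept only if the source model assigns it
the same label as the intact original, regenerating with fresh seeds until
a per-category quota (default 10) is met, with a retry cap (default 200 per
original) to guarantee termination.

## Behavioral statistics

Confusion matrices are **row-normalized to proportions before the
off-diagonal correlation** (raw-count mode is available): humans and models
contribute unequal trial counts per category, and raw counts would confound
the error-pattern comparison. The p-value uses the t transform with
C(C−1)−2 degrees of freedom. Accuracy-pattern correlations are plain
Pearson correlations over aligned condition lists; the pooled list is
14 density×orientation conditions + 5 voxel levels + the intact/scrambled
conditions. Two dependent correlations sharing the human profile are
compared with Steiger's (1980) Z₁* statistic using the pooled estimate
r̄ = (r₁+r₂)/2; the sample size n is an explicit argument because
condition-level and stimulus-level pairings are both legitimate readings.

## Numerical choices and degenerate inputs

* Unit-sphere normalization leaves single-point (or fully coincident)
  clouds centered but unscaled.
* Neighbor searches break distance ties toward the lower index
  (stable sort), making every index-space operation deterministic.
* The max-pool gradient splits equally among exact ties.
* Forward computation is float32; permutation invariance of the logits
  holds to 1e-5, limited only by floating-point reduction order.
* Spectral subdivision of a part with exactly 3 points returns the trivial
  partition; fewer points than clusters is an error, as is scrambling a
  single-part cloud or voxelizing with non-positive cell size.

## Known limitations

* Absolute accuracies on real CAD datasets (and hence the published
  human–model correlation magnitudes) are out of reach without the external
  data and GPU-scale training; the package reproduces the architecture
  sizes exactly and the behavioral *orderings* at desk scale.
* The NoAttn/NoPE substitutions are documented conventions, not recovered
  authorial intent.
* Training determinism is exact for this NumPy backend given a seed;
  across BLAS builds, bit-level identity is not guaranteed.
* The OFF/PLY/XYZ readers implement the dialects the pipeline touches;
  they are not general-purpose mesh repair tools.
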