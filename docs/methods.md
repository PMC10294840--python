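# Methods

## Model and procedure

The package treats corneal-ulcer detection as binary classification of
per-layer CNN channel descriptors. A fixed ResNet-18 backbone (never
trained or fine-tuned here) maps an image to an `a_i x b_i x w_i`
activation tensor at layer *i*; each of the `w_i` feature maps is
reduced to its arithmetic mean over the `a_i x b_i` spatial positions.
The resulting `w_i`-vector per image feeds a linear-kernel SVM. Because
most maps are redundant for a narrow task, a genetic algorithm searches
over fixed-cardinality subsets of map indices, with subset fitness
defined as the SVM's held-out accuracy on exactly those columns.

### Layer enumeration

The enumeration lists every tensor-producing operation from the first
convolution through the final global pooling: convolutions, batch
norms, ReLUs, poolings and element-wise residual sums; the input and
the classification head (fully-connected, softmax, output) are
excluded. For the 224x224x3 reference input this gives 67 layers with
the shape census

| output shape | layers | activations |
|---|---|---|
| 112x112x64 | 3 | 2,408,448 |
| 56x56x64 | 15 | 3,010,560 |
| 28x28x128 | 16 | 1,605,632 |
| 14x14x256 | 16 | 802,816 |
| 7x7x512 | 16 | 401,408 |
| 1x1x512 | 1 | 512 |

(total 8,229,376). Naming follows the conventional
`res<stage><block>_<branch>` scheme; in downsampling blocks the
projection shortcut (`res3a_branch1`, `bn3a_branch1`) is enumerated
immediately after the block's first convolution, which is the order the
per-layer sweep indices assume (e.g. `res5b_branch2a` = 60,
`pool5` = 67).

### Backbone implementation

The forward pass is a NumPy inference graph: im2col convolutions
(`sliding_window_view` + `tensordot`), inference-mode batch norm
(eps 1e-5), 3x3/stride-2 max pooling, and global average pooling.
Weights default to seeded random draws (He-scaled convolutions, mildly
randomized batch-norm affine parameters with identity running
statistics); an `.npz` of named arrays can be supplied for real
pretrained parameters. Random weights are sufficient for everything the
test-suite verifies — pooling arithmetic, shapes, determinism, and the
selection machinery — which is weight-agnostic; classification quality
on real photographs of course requires pretrained weights.
Preprocessing is fixed: bilinear resize to the square input size,
scaling to [0, 1], grayscale replicated to 3 channels, and
normalization by the ImageNet channel statistics (mean
0.485/0.456/0.406, SD 0.229/0.224/0.225) that canonical ResNet-18
weights assume. `input_size` defaults to 224 (the reference layer
shapes); tests use smaller inputs for speed, which changes only the
spatial extent of each map, not the channel counts.

## Genetic algorithm

A chromosome is a set of `L` distinct channel indices encoded as an
ordered list. Control-parameter defaults: population 40, `L = 192`,
crossover rate CR = 0.5, mutation rate MR = 0.1, 1000 generations.

* **Selection** — fitness-proportionate by default (probability
  proportional to accuracy); rank selection is provided because
  proportionate selection degenerates when accuracies cluster in a
  narrow band. An all-zero fitness vector falls back to uniform
  sampling with a logged warning.
* **Uniform crossover** — per position, a uniform draw below CR routes
  parent 1's gene to child 1 and parent 2's to child 2, else swapped.
  Routing distinct parents positionwise can duplicate a gene within a
  child; duplicates are repaired by uniform draws from the indices
  absent from that child, which preserves the set encoding with minimal
  bias.
* **Mutation** — each gene is replaced, with probability MR, by a
  uniformly chosen index not currently in the chromosome. When the
  chromosome spans all channels no foreign index exists and the gene is
  left unchanged.
* **Replacement** — each generation produces `population_size`
  offspring; the combined parent+offspring pool is truncated to the
  population size by fitness, ties broken by lexicographic order of the
  sorted gene tuple for determinism. Truncation of the combined pool
  simultaneously replaces the least fit and keeps the best in memory,
  so best-so-far fitness is non-decreasing.
* **Determinism** — one seeded `numpy` generator per run; all
  stochastic stages draw from it in a fixed order, so a fixed seed
  replays the run bit-for-bit. Fitness values are memoized on the
  sorted gene set (the encoding is a set; order carries no meaning).
* **Stopping** — exactly `max_generations` steps; an optional plateau
  stop (`early_stop_patience`) is off by default.

### Fitness partition

Fitness is the SVM's accuracy on an internal stratified validation
split (default 70/30 within the data handed to the GA), fixed once per
run. `multirun_ga` hands the GA only the training partition of each
run's 70/30 split, so selection never sees test labels;
`fitness_on_test=True` reproduces the literal protocol in which fitness
is computed against the held-out set — useful for replication, but it
leaks test information and is not the default.

## Classification

Linear-kernel SVM (`C = 1.0`, exposed) with train-estimated feature
standardization on by default: SVM margins are scale-sensitive and
channel means at different layers differ by orders of magnitude.
Splits are stratified 70/30 with the training size floored
(712 samples -> 498 train / 214 test). Class 1 ("ulcer present") is the
positive class in the confusion counts; accuracy is
`(TP + TN) / (TP + TN + FP + FN)`.

## Evaluation protocol

* **Layer sweep** — per layer, the all-channels baseline accuracy over
  `n_runs` (default 20) independent re-drawn splits
  (seed = base + run); mean/max/min/median/std per layer, ranked by
  mean with name tie-break. Re-drawing the split each run is what makes
  the run-to-run std nonzero. Sample std (ddof 1); a single run reports
  std 0 by convention.
* **Gain** — `difference = AR_proposed - AR_baseline` and
  `gain% = 100 * difference / baseline`, reported to 4 and 2 decimals
  respectively. Recomputing the published table's rows from its printed
  mean columns reproduces its difference and gain columns exactly at
  that precision (25.28 down to 19.73).
* **Wilcoxon signed-rank** — zero differences are excluded before
  ranking (the plain "exclusion" reading; with all differences zero the
  samples are indistinguishable and p = 1 by convention, matching the
  published matrix diagonal). For up to 25 nonzero pairs the two-sided
  p-value is computed from the exact null: a subset-sum dynamic program
  over doubled midranks enumerates the distribution of W+ under the
  2^n equiprobable sign assignments (ties handled via midranks);
  p = min(1, 2 min(P(W+ <= w), P(W+ >= w))). Larger samples use the
  normal approximation with tie and continuity corrections. The exact
  branch is validated against an independent library implementation on
  tie-free samples, and its type-I error at alpha = 0.05 is 0.04–0.06
  at 20 pairs — the protocol's per-layer run count. At much smaller
  sample sizes (n ~ 12) the exact test is conservative (size ~ 0.039)
  purely because the discrete null cannot attain 0.05; this is a
  property of the statistic, not the implementation. No multiplicity
  correction is applied across the pairwise layer comparisons by
  default, mirroring the published matrix; `holm=True` enables a Holm
  step-down correction.
* **Computational time** — `CT = T1 / T0` where `T0` is the wall-clock
  time of a bundled fixed floating-point multiply-add loop timed on the
  same host in the same session. CT values are comparable within this
  artifact, not across publications; the ratio is invariant to a
  uniform host slowdown.

## Synthetic data

`generate_planted_features` draws `n x w` Gaussian channel means
(`noise_sd`, default 1) and adds a `effect_size * noise_sd` shift to
`k` uniformly drawn informative channels for class-1 rows; labels are
Bernoulli(`class_balance`), resampled until both classes appear, and
the informative indices are returned so selection recovery can be
scored. `generate_toy_images` draws grayscale images of a textured
bright disc (the stained cornea) with, for class 1, a brighter circular
lesion planted uniformly inside the disc; images are written as PNG in
`class_0`/`class_1` subfolders, the same layout the real-data loader
expects. What the generators do **not** emulate: spatial correlation
between CNN channels, heavy-tailed or correlated feature noise,
photographic artefacts (reflections, eyelashes, illumination gradients)
and staining variability. Passing tests therefore demonstrate the
correctness of the selection/evaluation machinery under known ground
truth, not clinical performance.

### When does the GA recover the planted channels?

Accuracy-fitness subset search recovers the informative support only
while accuracy still increases with each added informative channel. At
a 1-SD per-channel effect (single-channel accuracy ~ 0.69, all-eight
~ 0.95) the GA's best chromosome recovers most planted channels
(recall 0.6–0.75 over seeds vs 0.125 for a random subset). At very
strong per-channel effects (e.g. 5 SD) a subset containing one or two
planted channels already classifies the validation fold perfectly: the
fitness surface is flat at its maximum over an enormous family of
subsets, no estimator of accuracy on a few hundred samples can resolve
the ~1e-5 error differences between partially and fully informative
subsets, and the best chromosome stalls at the first subset reaching
accuracy 1.0 (measured recall ~ 0.2, identical with single-split and
5-fold-CV fitness). This is not a defect of the optimizer — it
optimizes its stated objective exactly — but an identifiability limit
of wrapper selection: accuracy optimization and support recovery
coincide only below fitness saturation.

A related caveat applies to the baseline-vs-selection gain on this
synthetic design: under dense independent Gaussian noise, a
standardized linear SVM already acts as an effective shrinkage
estimator over the uninformative channels, so the all-channel baseline
is strong and the measured selection gain is modest and varies with
the design draw (it can be negative when the wrapper's small
validation fold overfits). Real CNN feature maps are strongly
correlated and redundant in ways this Gaussian design does not
emulate, which is where selection has the most to remove.

## Numerical and design choices

* 0-based channel ids internally; serialized 1-based with an explicit
  `index_base` field, matching the 1-based published tables.
* Feature tables are TSV with a JSON metadata comment line (layer name,
  index, shape); chromosomes and provenance are JSON. Every CLI output
  directory carries a provenance sidecar (config hash, seed, version).
* Degenerate inputs are rejected early with specific errors: designs
  whose lesion cannot fit the image, single-class training sets,
  chromosome length exceeding the channel count, non-positive times in
  the CT ratio.
* Test problem sizes (hundreds of samples, tens of channels, tens of
  generations) are chosen so the full suite exercises every stage —
  including multi-run GA experiments — at desk scale; the defaults
  (40 x 192 x 1000) remain those of the published protocol.

## Known limitations

* Random-weight features are not discriminative for real photographs;
  replication on the public corneal-ulcer image set additionally needs
  pretrained ImageNet parameters supplied as `.npz`.
* The NumPy forward pass is single-image and CPU-bound (~ seconds per
  image at 224x224); it favours transparency and zero heavy
  dependencies over throughput.
* Binary classification only; no probability calibration; nonlinear
  kernels are deliberately out of scope.
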