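# Methods

`semipatch` implements a five-stage semi-supervised, interpretable pipeline
for binary classification of small histopathology patches (IDC-positive vs
IDC-negative): GAN-based augmentation, deep feature extraction, co-training
pseudo-labelling, a compact CNN classifier, and global interpretability via
regression concept vectors. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic data can and
cannot show.

## Neural-network engine

No deep-learning framework is a dependency: the convolutional components
run on a small numpy engine (`semipatch.nn`) with explicit forward/backward
passes for dense, convolution, transposed-convolution, batch-normalisation,
pooling and activation layers, plain SGD with per-step learning-rate decay
(`lr_t = lr_0 / (1 + decay·t)`), and a `Sequential` container that exposes
intermediate activations, partial forward passes from a named layer, and
gradients of the output with respect to any layer's activation. Every
layer's backward pass is verified against central finite differences in the
test suite (relative error ≲ 1e-9 on random inputs). All computation is
float64 except the VGG backbone (float32 for speed); all randomness flows
through `numpy.random.Generator` objects seeded from explicit config seeds,
so identical configs give bit-identical results.

## Synthetic data

`synthio` emulates the two datasets the pipeline consumes.

*Two-class patches.* Each patch is a pink, smoothly textured background
(Gaussian random field, amplitude 0.04) on which dark elliptical blobs are
painted; Gaussian pixel noise (sd 0.03) is added last and intensities are
clipped to [0, 1]. Class 1 plants more blobs at higher contrast than class 0
(defaults: density 9 vs 3 blobs per 32 px patch, contrast 0.45 vs 0.22), so
class 1 is darker and more textured — a cartoon of nuclei-dense invasive
tissue. The contrast gap controls task difficulty; classifier CV accuracy is
monotone in it (tested).

*Concept patches.* Image/mask pairs with 1–6 non-overlapping axis-aligned
elliptical nuclei per 32 px patch (major semi-axis 2–4.5 px, eccentricity
0–0.8), placed by rejection sampling (error after 200 failed placements).
Because nuclei never touch, morphology ground truth is exact: the mask area
equals the sum of the per-nucleus drawn pixel sets, which are recorded
together with semi-axes, eccentricities and the per-patch texture amplitude
(0.05–0.40) painted inside nuclei. The texture amplitude plants the
GLCM-contrast concept.

What the generator does **not** emulate: H&E stain variation, nuclear
chromatin structure, overlapping/touching nuclei, tissue architecture, scanner
artefacts. Passing tests therefore demonstrate the correctness and the
qualitative behaviour of the machinery, not clinical-grade performance on
real slides (real-data layouts are supported by `patchio`, but acquisition
is the user's task).

## DCGAN augmentation

One generator/discriminator pair is trained per class. The generator
projects 100-dimensional uniform noise through a fully connected layer into
a 256-channel spatial seed and three stride-2 transposed convolutions of
128, 64 and 32 channels (5×5 kernels), ReLU activations and batch
normalisation everywhere except the tanh output layer; patches are scaled
to [−1, 1] for training and de-scaled on sampling. The discriminator
mirrors this capacity: four stride-2 5×5 convolutions of 32/64/128/256
filters with LeakyReLU(0.2). Both use SGD (default lr 3e-4, momentum 0) on
the binary cross-entropy objective.

Two deliberate choices:

* **No batch normalisation in the discriminator by default** (flag
  available). On low-diversity pools — the extreme case being identical
  patches — batch statistics of the real batches are degenerate and BN
  destabilised training; without it the generator's mean image converges on
  the degenerate benchmark. The generator keeps BN as described.
* **Desk-scale epochs.** Default 50 epochs; a full-scale setting of 1200
  epochs at batch size 16 is documented in the config. The degenerate
  convergence test runs 200 epochs at lr 1e-2 on a tiny filter stack.

Because training is per class, the class label is constant within a run; a
flag can append a constant label channel to the discriminator input.

## Feature extraction

The labelling stage represents every patch by the VGG-16 GAP concatenation:
the 13-convolution VGG-16 stack is run (fully connected head never built),
channel-wise global average pooling is applied at the final convolutions of
blocks 2–5 (128, 256, 512, 512 channels — the unique layers with those
widths directly before each pooling), and the four pooled vectors are
concatenated in network order to 1408 dimensions. The backbone loads
pretrained weights from an `.npz` archive when provided; otherwise it is
randomly initialised from a fixed seed. Every dimensionality, determinism
and pipeline contract is weight-independent, and random deep projections
still separate the synthetic classes well; with pretrained weights the
features simply become semantically richer. Inputs are bilinearly resized
to 224 px by default (canonical VGG preprocessing) or processed fully
convolutionally at native size (minimum 16 px), which is what the tests and
the desk-scale pipeline use.

Features are standardised (zero mean, unit variance per column, fit on the
labelled rows) before the classical learners, which are scale-sensitive.
PCA (fit on all extracted rows, components configurable, default 50 in the
pipeline) reduces the 1408-vector before tree fitting to keep gradient
boosting fast on one CPU; PCA and LDA are also exposed directly for the
feature-comparison experiments (LDA is capped at one dimension for binary
labels).

## Co-training pseudo-labelling

Pools: `D_train` (labelled), `D_GAN` (synthetic), `D_unlabelled`. Each
round, both pools are shuffled into two equal halves `k` times (default 5);
pairing the i-th train half with the i-th GAN half yields `2k` subsets on
which `2k` fresh base learners are fitted (gradient boosting with 100
depth-3 trees at learning rate 0.1 by default; random forest, decision
tree, naive Bayes and SVM are selectable). An unlabelled row is confidently
labelled `c` when at least `agreement_threshold` (default 5) learners give
class `c` probability ≥ `confidence_cutoff` (default 0.90, inclusive) *and*
no learner gives the opposite class probability ≥ the cutoff. Confident
rows join both pools with provenance `pseudo` and the loop repeats until a
round labels nothing (or `max_rounds`). Never-labelled rows are treated as
noise. The final training pool is `D_train ∪ D_conf`; GAN-provenance rows
are excluded by tag.

The probability cutoff is a package parameter: with binary labels a bare
5-of-10 majority vote would label almost everything, so agreement is only
counted among individually confident learners. Re-shuffling the halves
every round (rather than freezing the round-1 split) is the package's
reading of the iterated procedure. Base-learner seeds are derived
deterministically from (config seed, round, model index).

A single-classifier self-training baseline shares the stopping rule:
decision tree (≥ 2 items per leaf), Gaussian naive Bayes, or a degree-1
polynomial SVM (C = 1, tol 1e-3) with logistic probability fitting; the
most confident predictions (max probability ≥ cutoff) are appended each
round. `sweep_labelling` reruns the co-trainer over `k ∈ {1..6}` (with the
agreement threshold set to `k`) and over the five base learners, emitting
an ablation table.

## CNN classifier

Fixed ladder for square inputs divisible by 8 (default 32 px): BN →
conv(64 kernels, 3×3, same padding) at 32×32 → 2×2 max-pool → ReLU, repeated
at 16×16 and 8×8 (the third pooling output, 4×4, takes no ReLU), then global
average pooling → dropout (0.5) → FC(256) → ReLU → FC(2) → softmax
memberships. Training: SGD, lr 0.01, batch 32, 80 epochs, per-step
learning-rate decay 1e-5 (a weight-decay interpretation is available via
`decay_mode`). The 3×3 kernel, the 0.5 dropout and the 256-wide hidden layer
are package defaults where the source architecture leaves them open; the
feature-map ladder is asserted at build time.

Desk-scale runs (tests, acceptance script, examples) use a 16-kernel,
(64, 2)-FC variant at 20 epochs: with batch-normalisation statistics
accumulated at momentum 0.9, ~20 epochs of updates are needed before
evaluation-mode statistics are representative, and the narrow variant keeps
a full study under a minute per CNN on one CPU.

Evaluation computes accuracy, balanced accuracy ((sensitivity +
specificity)/2), F-measure (harmonic precision/recall mean) and AUC as a
rank statistic over the class-1 membership scores. On a single-class test
set the AUC is reported as `None` with a warning, the other metrics remain.
Paired systems are compared with a two-sided Wilcoxon signed-rank test
(exact null for ≤ 25 non-zero differences, normal approximation with tie
handling otherwise; all-zero differences raise).

## Global interpretability

Concept measures on the nuclei dataset: mean nucleus area (px²), perimeter
(px), major-axis length (px) and eccentricity over connected components,
the whole-mask Euler number, and three Haralick statistics — angular second
moment, contrast, correlation — from a symmetric, normalised grey-level
co-occurrence matrix (grayscale quantised to 32 levels, distance 1,
offsets 0°/45°/90°/135°, features averaged over offsets; all configurable).
A constant image makes correlation undefined (error); an empty mask makes
morphology undefined (error).

For a concept `C` and layer `l`, activations are channel-wise globally
averaged (full spatial flattening available) and the concept measure is
regressed on them by ordinary least squares; the **regression concept
vector** `v` is the unit-normalised coefficient vector, with the fit's R².
Rank-deficient designs fall back to a ridge penalty of 1e-6. The layer at
which a concept is best learnt is located by 10-fold cross-validated R²
with re-shuffled folds, averaged over repeated runs. The per-patch
**sensitivity** is the directional derivative of the class-1 membership
along `v`, with the gradient averaged over spatial positions per channel to
live in the same pooled space as `v`; an independent central-difference
oracle (perturb the activation uniformly by ±εv, re-run only the layers
above, divide by the spatial extent) is part of the public API and of the
acceptance checks. The **bidirectional relevance** of a concept is

    Br = R² × (σ / μ)

over the test-set sensitivities, with the sample (n−1) standard deviation;
μ = 0 raises. Per-concept raw scores are min-max mapped onto [−1, 1] (the
extreme concepts land exactly at ±1, and rescaling a scaled vector is the
identity). Significance is a two-tailed one-sample t-test of the per-patch
sensitivities against zero mean — the null of a randomly oriented
direction; applying the test to the sensitivity distribution (rather than
to a distribution of Br values over reruns) is the package's documented
reading. Concepts are screened first by the Pearson correlation between the
measure and the network prediction.

## Desk-scale study sizes

The end-to-end study (`pipeline.run_semisupervised_study`) uses, per class:
20 labelled, 180 unlabelled and 100 test patches at 32 px (10% of the
training pool labelled), VGG-GAP features reduced to 50 PCA components, the
default co-training configuration, and the 16-kernel CNN at 20 epochs.
These sizes are the package's chosen desk-scale study conditions; the full
pipeline at these sizes runs in well under a minute per repetition on one
CPU, and the semi-supervised benefit check repeats it over five seeds.

## Known limitations

* Random-weight VGG features are generic projections, not semantic
  descriptors; conclusions about *which* concept matters on real tissue
  require pretrained weights and real data.
* The DCGAN at desk scale shows convergence diagnostics, not photorealistic
  synthesis; no FID/IS quality metrics are computed.
* Pseudo-labelling is binary-only; the classical two-view co-training with
  explicit feature splits is out of scope.
* The Br ratio σ/μ is unstable for concepts whose mean sensitivity is near
  zero — exactly the concepts the Pearson screen is meant to discard first.
* `evaluate` thresholds memberships at 0.5; operating-point tuning is out of
  scope.
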