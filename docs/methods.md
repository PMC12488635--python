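# Methods

## Model

A phage–host pair is represented by three feature blocks: a 26-wide
statistics vector (20 amino-acid frequencies in alphabetical one-letter
order, 5 atomic fractions in the fixed order C, H, N, O, S, and one
molecular weight) and two expert embedding vectors of shared width d.
Phage and host entity features are combined per block by element-wise
mean (default), which keeps the single-entity widths that define the
reference dimensionalities (26, d, d+26); a concatenation mode doubling
the widths is available, and every downstream shape derives from
configuration.

The gating network is a two-layer perceptron (26 → 64 → 2) over the
statistics block with ReLU and a max-shifted softmax, producing per-sample
weights (α₁, α₂) on the probability simplex. Fusion is the convex
combination α₁X₁ + α₂X₂, so every fused value lies within the element-wise
envelope of the two experts; the combined vector appends the statistics
block. The classifier reshapes the combined vector into a one-channel 1-D
signal and applies conv(k=3, same-padding) → ReLU → batch-norm →
max-pool(2) blocks with channels (32, 64), a global average pool, a
64-unit fully connected layer with dropout 0.3, and two logits. The
positive probability is the softmax of the logits and predictions use the
0.5 threshold, with the boundary itself called positive.

Gate and CNN are optimized jointly: the gradient of the mean binary
cross-entropy flows through the CNN into the fused block, then through
the fusion weights into the gate parameters, and one Adam step updates
everything. The loss is computed from probabilities clamped at 1e-12, a
literal probability-space definition; the fused log-softmax form is
numerically preferable in general and the two are asserted equivalent in
tests away from the clamp region.

### Labeling, normalization and resampling

Measured infection scores strictly above 1.5 are positive; a score of
exactly 1.5 is negative because the rule is strict-greater (the boundary
is otherwise unspecified, and the choice is documented rather than
silent). Missing matrix cells are skipped and counted, never imputed as
zero. Min–max normalization maps each feature to [0, 1] using statistics
of the designated fit set; constant features map to 0 and out-of-range
values are not clipped. Oversampling duplicates random minority samples
with replacement until counts are equal; undersampling removes random
majority samples without replacement. Stratified k-fold splitting
preserves class ratios to within one sample per fold.

By default folds are split first, then the training portion is resampled
and the scalers are fit on it alone, so no test-fold identity can appear
in training. A `paper_mode` option instead balances and normalizes the
full dataset before splitting, mimicking protocols that report perfect
sensitivity on duplicated positives spanning the split; it exists for
comparability and is not the recommended default. The gate consumes the
same normalized statistics block that the classifier sees, keeping gate
logits scale-stable; feeding raw statistics would make the gate sensitive
to the molecular-weight scale (thousands of daltons against unit-scale
fractions).

## Implementation of the neural core

No automatic-differentiation framework is used: the layers (1-D
convolution, batch normalization, max pooling, global average pooling,
dense, inverted dropout) carry hand-written analytic backward passes, and
Adam updates a flat parameter list in place. The test suite checks the
complete joint gradient — loss → CNN → fusion → gate — against central
finite differences at 1e-6 step. All randomness (initialization, batch
shuffling, dropout masks) flows from generators seeded by the
configuration, making training bit-reproducible on one device. Batch
normalization uses batch statistics in training and running averages
(momentum 0.1, eps 1e-5) at inference, so batched and one-by-one
prediction agree exactly.

## Evaluation dialects

Threshold metrics follow the standard confusion-matrix formulas. A metric
with a zero denominator is reported as NA with a reason, never coerced to
0: degenerate folds with few or no positives genuinely occur under heavy
imbalance, and coercion would silently bias fold averages. AUC is the
tie-aware rank statistic (Mann–Whitney formulation: the probability that
a random positive outscores a random negative, ties counting one half);
AUPR is the step-wise non-interpolated area over recall in a
descending-score sweep (the "average precision" dialect, computed via
scikit-learn). Both dialects are verified against exhaustive brute-force
oracles in the tests. Fold aggregation is the unweighted mean over folds
where the metric is defined, with the count of undefined folds reported.

## Synthetic data: what it does and does not emulate

The fixture generator emulates the *structure* of the study inputs:
multi-protein entities with random sequences over the 20-residue
alphabet, and a continuous infection-score matrix whose values straddle
the 1.5 threshold. Scores are drawn as `1.5 + σ(z + q)` with z standard
normal and q the normal quantile of the requested positive fraction
(default 0.15, a typical prevalence for measured panels; σ = 0.5), so
binarization yields that fraction in expectation. These scores are
independent of the protein content, so pipeline runs on this fixture
demonstrate mechanics (labeling, fold hygiene, resampling, training,
reporting) at chance-level metrics — they do not, and are not meant to,
demonstrate biological signal. Embeddings for fixtures come from the
content-addressed synthetic provider at small width (default 16) to keep
tests fast; widths are always configuration-driven.

Two benchmark scenarios carry known ground truth instead:

- a **separable set** (default 200 samples) whose positive class has its
  expert features mean-shifted, used for learnability checks;
- a **specialization set** (default 400 samples) whose label rule follows
  `step(w·X₁)` when a designated flag feature in the statistics vector is
  1 and `step(w·X₂)` when it is 0. The default signal weights w are
  uniform, so the rule thresholds the mean activation of the active
  expert. This choice is deliberate: the convolutional head with global
  average pooling is translation invariant along the feature axis and
  cannot represent an arbitrary position-dependent linear rule, so a
  planted rule must live in the function class for routing recovery to be
  measurable. Weights remain configurable and are recorded as ground
  truth alongside the flag column.

Passing on these fixtures shows the optimization recovers planted
structure; it says nothing about accuracy on real proteomes, which depend
on embedding quality and assay noise the generator does not model.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| `threshold` | 1.5 | infection-score cut for a positive label (strict >) |
| `d` | 1024 reference / 16 in fixtures | expert embedding width, shared by both streams |
| `gate_hidden` | 64 | gate hidden width |
| `channels` | (32, 64) | conv channels per block (kernel 3, pool 2) |
| `fc_width`, `dropout` | 64, 0.3 | fully connected head |
| `learning_rate` | 1e-3 | Adam step size |
| `batch_size`, `epochs` | 32, 50 | training schedule |
| `k_folds` | 5 | stratified cross-validation folds |
| `regime` | raw | raw / over / under resampling of training data |
| `pair_mode` | mean | phage+host block combination (mean keeps widths) |

The architecture beyond "conv blocks with kernel 3 and varying channels"
is a design choice of this package: two blocks of (32, 64) channels with
a 64-unit head are small enough to train on a CPU in seconds at fixture
scale yet deep enough for the benchmark scenarios; all of it is
configurable. Tests and the reproduction script use reduced sizes
(channels (8, 16), fc 16, d 8–16, panels of 20×25 entities) chosen so the
whole suite runs in seconds while leaving every contract intact.

Multi-protein entities are reduced to one vector per block by pooling:
descriptor fractions are computed over the pooled residues, molecular
weight is the mean per-protein weight (keeping the feature on a
single-protein scale regardless of proteome size), and embedding
providers mean-pool per-protein vectors (max-pooling is available). The
synthetic provider hashes the sorted sequence content with the seed, so
it is a pure function of (seed, content) and record order never matters.

## Degenerate inputs and numerical choices

Softmax is always computed max-shifted. Sequences are uppercased and
stripped of ambiguity codes (X, B, Z, J), rare residues (U, O), gaps and
stops before counting, with a logged count of what was dropped; a record
with nothing left is an error naming the record. Residue masses are
derived from the molecular formulas of the free amino acids with IUPAC
standard atomic weights, so the mass and atom-count tables are mutually
consistent and the molecular-weight sum matches its formula literally (no
peptide-bond water correction). Descriptor sums iterate residues in fixed
alphabetical order so results are exactly permutation invariant. Constant
features under min–max map to 0. A non-finite training loss aborts with a
diagnostic rather than continuing. Max pooling drops a trailing remainder
shorter than the pool width; building a model whose pooling stack would
reduce the signal below length 1 fails naming the offending block.

## Known limitations

- Real protein-language-model adapters are optional hooks behind the
  provider contract; the package never downloads or bundles model
  weights, so reference-configuration runs (d = 1024) use stored tables
  or synthetic streams.
- Exactly two experts in the public API; the internals operate on a
  weight vector, so a K-expert generalization is a configuration change,
  but no top-k routing or load-balancing objectives are provided.
- The fixture matrix carries no sequence-dependent signal (see above);
  quantitative (non-binary) infection prediction is out of scope.
- Training is single-threaded numpy; it is sized for desk-scale panels,
  not for datasets orders of magnitude larger.
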