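# phagegate

Phage–host interaction prediction with gated mixture-of-experts fusion of
protein descriptors and embedding streams.

## The problem

Bacteriophage therapy against antibiotic-resistant infections needs fast,
trustworthy answers to one question: *does this phage infect this bacterial
strain?* Wet-lab immersion assays record a continuous infection score for
each (host, phage) pair; scores above 1.5 are treated as productive
infection. In-silico predictors built on a single protein representation
tend to be either interpretable but weak (simple sequence statistics) or
strong but opaque (pre-trained protein language-model embeddings), and they
degrade badly under class imbalance.

`phagegate` combines both worlds. For every phage–host pair it builds

- **X_stats ∈ ℝ²⁶** — interpretable descriptors of the pair's proteins:
  20 amino-acid frequencies `AAC_i = n_i / L`, 5 atomic fractions
  `AC_j = a_j / Σ_k a_k` over C, H, N, O, S, and the molecular weight
  `MW = Σ_i n_i · M(A_i)` (free amino-acid masses);
- **X₁, X₂ ∈ ℝᵈ** — two high-dimensional "expert" embedding streams in the
  role of pre-trained protein language models (d = 1024 in the reference
  configuration), consumed through a provider contract with a
  deterministic synthetic provider for desk-scale work.

A small gating network routes between the experts *per sample*:

```
H = ReLU(X_stats W₁ + b₁)          H ∈ ℝ⁶⁴
G = H W₂ + b₂                      G ∈ ℝ²
α = softmax(G)                     α₁ + α₂ = 1, α ≥ 0
X_fused   = α₁ X₁ + α₂ X₂          ∈ ℝᵈ
X_combined = [X_fused, X_stats]    ∈ ℝ^(d+s)   (1050 for d=1024, s=26)
```

`X_combined` feeds a 1D-CNN binary classifier (conv → ReLU → batch-norm →
max-pool blocks, global average pool, fully connected head, two logits);
gate and CNN are trained **jointly** with Adam on mean binary
cross-entropy, so the routing adapts to what helps classification. The
learned α pair is the model's built-in explanation of which expert drove
each prediction.

Robustness under class imbalance is evaluated under three regimes — the
raw distribution, oversampling (minority duplicated until balanced) and
undersampling (majority reduced until balanced) — with min–max
normalization `x′ = (x − min)/(max − min)` and stratified k-fold
cross-validation. By default folds are split first and resampling and
normalization are fit on the training portion only, so no test identity
leaks into training.

The neural-network core (layers, backpropagation, Adam) is implemented in
numpy with analytic gradients that the test suite verifies against finite
differences.

## Worked example

Recover a planted routing structure (`examples/04_gating_specialization.py`):
400 samples carry a binary flag in their statistics vector; labels follow
expert 1's features when the flag is 1 and expert 2's when it is 0.

```bash
$ python examples/04_gating_specialization.py
mean alpha1 | flag=1 samples: 0.978  (rule uses expert 1)
mean alpha1 | flag=0 samples: 0.124  (rule uses expert 2)
routing gap: 0.854, training accuracy: 0.993
```

After joint training the gate gives expert 1 a weight of 0.98 exactly on
the samples whose labels are governed by expert 1, and 0.12 elsewhere: the
routing ground truth is recovered, and the per-sample weights explain each
prediction. The other examples cover descriptors, the fusion algebra, the
full simulated pipeline and the interpretability exports; each prints what
its numbers mean.

A thin CLI mirrors the pipeline stages:

```bash
phagegate simulate --n-hosts 20 --n-phages 25 --seed 1 --out data/
phagegate run --data data/ --out run/ --regime over --seed 1
phagegate explain --checkpoint run/checkpoint_fold0.npz --dataset run/dataset --out explain/
```

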