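"""Route two expert embedding streams through the gating network.

A two-layer gate maps each sample's statistics vector to softmax weights
(alpha1, alpha2); the fused embedding is the per-sample convex combination
of the two expert vectors, then concatenated with the statistics.
"""

import numpy as np

from phagegate import concat_combined, fuse, gate_forward, init_gate

rng = np.random.default_rng(0)
s, d, n = 26, 1024, 4

gate = init_gate(s=s, seed=1)
stats = rng.random((n, s))
expert1 = rng.normal(size=(n, d))
expert2 = rng.normal(size=(n, d))

out = gate_forward(gate, stats)
fused = fuse(out.alpha, expert1, expert2)
combined = concat_combined(fused, stats)

for i in range(n):
    print(f"sample {i}: alpha = ({out.alpha[i, 0]:.3f}, {out.alpha[i, 1]:.3f})")
print(f"fused width {fused.shape[1]}, combined width {combined.shape[1]}")

# Each weight pair sums to 1 (softmax), so the fused vector always lies
# between the two experts element-wise; with d=1024 and s=26 the combined
# representation has the reference width 1050.
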