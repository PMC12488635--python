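"""Export gate weights, entropies and feature heatmap matrices.

The gate entropy quantifies how decisively a sample was routed:
0 nats = one expert dominates, ln 2 = 0.693 nats = indifferent.
"""

from pathlib import Path

from phagegate import FixtureSpec, ModelConfig, MoEClassifier
from phagegate.interpret import export_gate_weights, export_heatmaps
from phagegate.simulate import gen_specialization_dataset

ds, _ = gen_specialization_dataset(FixtureSpec(n_samples=200, seed=3), s=6, d=12)
model = MoEClassifier(s=6, d=12, config=ModelConfig(
    channels=(8, 16), fc_width=16, epochs=40, seed=2))
model.fit(ds.stats, ds.expert1, ds.expert2, ds.labels)

report = export_gate_weights(model, ds)
print(report.table.head().to_string(index=False))
print("\nmean weights by label:")
print(report.group_means.round(3).to_string())

out = Path("scratch/example_explain")
written = export_heatmaps(model, ds, out, blocks=("fused", "combined"))
for block, path in written.items():
    print(f"heatmap matrix for {block!r}: {path}")
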