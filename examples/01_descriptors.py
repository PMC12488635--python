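"""Compute the interpretable protein descriptors for two sequences.

The 26-feature statistics vector is 20 amino-acid frequencies
(alphabetical), 5 atomic fractions (C, H, N, O, S) and the summed free
amino-acid molecular weight in daltons.
"""

from phagegate import build_stats_vector, sanitize_sequence

for raw in ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", "gghhkkllxx**ppqq"):
    seq = sanitize_sequence("demo", raw)
    sv = build_stats_vector(seq)
    print(f"input {raw!r} -> {len(seq)} standard residues")
    print(f"  top residue frequency : {sv.aac.max():.3f}")
    print(f"  atomic fractions CHNOS: {[round(float(x), 3) for x in sv.ac]}")
    print(f"  molecular weight      : {sv.mw:.1f} Da")

# The atomic fractions always sum to 1; carbon and hydrogen dominate
# because every residue contributes several of each.
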