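"""Seeded synthetic-data generators.

Desk-scale stand-ins for the study inputs: multi-protein entities (phages
and host strains) as FASTA, a continuous infection-score matrix whose
values straddle the 1.5 labeling threshold at a configurable positive
fraction, and two benchmark scenarios with known ground truth — a
linearly separable set for learnability checks and a gating
specialization set where the label rule depends on expert 1's features
for one group of samples and on expert 2's for the other.  Every
generator is a pure function of its spec (including the seed), so output
is bit-reproducible across processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import norm

from .descriptors import ProteinSequence
from .residue_tables import AMINO_ACIDS
from .pairs import InteractionMatrix, PairDataset


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and seed of one synthetic dataset.

    Defaults emulate the study scale at desk size: on the order of a
    hundred hosts and phages would be realistic, but tests use smaller
    counts; the positive fraction defaults to 0.15, a typical infection
    prevalence for a measured host-phage panel.
    """

    n_hosts: int = 20
    n_phages: int = 25
    proteins_per_entity: tuple[int, int] = (1, 4)
    sequence_length: tuple[int, int] = (60, 200)
    positive_fraction: float = 0.15
    score_noise: float = 0.5
    missing_fraction: float = 0.0
    seed: int = 0
    # specialization scenario
    n_samples: int = 400
    flag_index: int = 0
    signal_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_hosts < 1 or self.n_phages < 1:
            raise ValueError("entity counts must be >= 1")
        if not 0.01 < self.positive_fraction < 0.99:
            raise ValueError("positive fraction must lie strictly inside (0.01, 0.99)")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing fraction must be in [0, 1)")
        lo, hi = self.proteins_per_entity
        if lo < 1 or hi < lo:
            raise ValueError("proteins_per_entity must be a valid range with lo >= 1")
        lo, hi = self.sequence_length
        if lo < 1 or hi < lo:
            raise ValueError("sequence_length must be a valid range with lo >= 1")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gen_entities(spec: FixtureSpec) -> tuple[dict[str, list[ProteinSequence]],
                                             dict[str, list[ProteinSequence]]]:
    """Random host and phage proteomes over the 20-letter alphabet.

    Returns ``(hosts, phages)`` mapping entity id to its protein records.
    """
    rng = np.random.default_rng(spec.seed)
    lo_p, hi_p = spec.proteins_per_entity
    lo_l, hi_l = spec.sequence_length

    def make(prefix: str, n: int) -> dict[str, list[ProteinSequence]]:
        out = {}
        for i in range(n):
            eid = f"{prefix}{i + 1:03d}"
            n_prot = int(rng.integers(lo_p, hi_p + 1))
            out[eid] = [
                ProteinSequence(
                    id=f"{eid}_p{j + 1}",
                    residues=_random_sequence(rng, int(rng.integers(lo_l, hi_l + 1))),
                )
                for j in range(n_prot)
            ]
        return out

    return make("host", spec.n_hosts), make("phage", spec.n_phages)


def write_entities_fasta(entities: dict[str, list[ProteinSequence]],
                         path: str | Path) -> None:
    """Write all proteins of all entities to one multi-FASTA file."""
    with open(path, "w") as fh:
        for eid in entities:
            for seq in entities[eid]:
                fh.write(f">{seq.id} entity={eid}\n")
                for start in range(0, len(seq.residues), 60):
                    fh.write(seq.residues[start:start + 60] + "\n")


def gen_interaction_matrix(spec: FixtureSpec, threshold: float = 1.5) -> InteractionMatrix:
    """Continuous infection scores whose binarization at ``threshold``
    yields the requested positive fraction in expectation.

    Scores are Gaussian around a shifted center: score = threshold +
    noise * (z + q) with z ~ N(0,1) and q the standard-normal quantile of
    the positive fraction, so P(score > threshold) equals the requested
    fraction and values straddle the threshold continuously.
    """
    rng = np.random.default_rng(spec.seed + 1)
    shape = (spec.n_hosts, spec.n_phages)
    q = float(norm.ppf(spec.positive_fraction))
    scores = threshold + spec.score_noise * (rng.standard_normal(shape) + q)
    if spec.missing_fraction > 0:
        mask = rng.random(shape) < spec.missing_fraction
        scores = np.where(mask, np.nan, scores)
    return InteractionMatrix(
        host_ids=tuple(f"host{i + 1:03d}" for i in range(spec.n_hosts)),
        phage_ids=tuple(f"phage{j + 1:03d}" for j in range(spec.n_phages)),
        scores=scores,
    )


def simulate_run_directory(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit a ready-to-train directory: FASTA files, matrix CSV and config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hosts, phages = gen_entities(spec)
    matrix = gen_interaction_matrix(spec)
    paths = {
        "hosts_fasta": out_dir / "hosts.faa",
        "phages_fasta": out_dir / "phages.faa",
        "matrix_csv": out_dir / "interactions.csv",
        "config_yaml": out_dir / "fixture.yaml",
    }
    write_entities_fasta(hosts, paths["hosts_fasta"])
    write_entities_fasta(phages, paths["phages_fasta"])
    matrix.to_csv(paths["matrix_csv"])
    cfg = {
        "n_hosts": spec.n_hosts, "n_phages": spec.n_phages,
        "proteins_per_entity": list(spec.proteins_per_entity),
        "sequence_length": list(spec.sequence_length),
        "positive_fraction": spec.positive_fraction,
        "score_noise": spec.score_noise,
        "missing_fraction": spec.missing_fraction,
        "seed": spec.seed,
    }
    paths["config_yaml"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths


def gen_separable_dataset(n: int = 200, s: int = 6, d: int = 12,
                          seed: int = 0, shift: float = 1.0) -> PairDataset:
    """A linearly separable benchmark set (balanced classes).

    Positive samples have their expert features shifted upward by
    ``shift`` on average, so the class signal lives in the mean activation
    of the expert blocks — a rule the translation-invariant convolutional
    head can represent.
    """
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    rng.shuffle(labels)
    stats = rng.uniform(0, 1, size=(n, s))
    offset = shift * labels[:, None]
    e1 = rng.normal(0, 0.5, size=(n, d)) + offset
    e2 = rng.normal(0, 0.5, size=(n, d)) + offset
    return PairDataset(
        sample_ids=[f"sep_{i:04d}" for i in range(n)],
        stats=stats, expert1=e1, expert2=e2, labels=labels,
    )


@dataclass(frozen=True)
class SpecializationTruth:
    """Ground truth of the gating scenario: which expert rules which group."""

    flag_index: int
    weights: np.ndarray
    flags: np.ndarray


def gen_specialization_dataset(spec: FixtureSpec, s: int = 6, d: int = 12,
                               ) -> tuple[PairDataset, SpecializationTruth]:
    """Samples whose label rule switches expert with a flag in the stats.

    When the flag feature is 1 the label is ``step(w . expert1)``; when it
    is 0 the label is ``step(w . expert2)``.  The default weights are
    uniform (the rule thresholds the mean activation of the active
    expert), which keeps the rule representable by the convolutional
    head; custom weights may be supplied through ``spec.signal_weights``.
    A gate that routes flag-1 samples to expert 1 and flag-0 samples to
    expert 2 makes the task solvable, so recovering that routing is the
    scenario's measurable ground truth.
    """
    rng = np.random.default_rng(spec.seed + 2)
    n = spec.n_samples
    if not 0 <= spec.flag_index < s:
        raise ValueError("flag_index out of range for stats width")
    w = (np.asarray(spec.signal_weights, dtype=float)
         if spec.signal_weights is not None else np.ones(d))
    if w.shape != (d,):
        raise ValueError(f"signal weights must have length d={d}")

    flags = rng.integers(0, 2, size=n)
    stats = rng.uniform(0, 1, size=(n, s))
    stats[:, spec.flag_index] = flags
    e1 = rng.uniform(-1, 1, size=(n, d))
    e2 = rng.uniform(-1, 1, size=(n, d))
    score = np.where(flags == 1, e1 @ w, e2 @ w)
    labels = (score > 0).astype(int)
    ds = PairDataset(
        sample_ids=[f"spc_{i:04d}" for i in range(n)],
        stats=stats, expert1=e1, expert2=e2, labels=labels,
        flags=flags,
    )
    return ds, SpecializationTruth(flag_index=spec.flag_index, weights=w, flags=flags)


def specialization_oracle_accuracy(ds: PairDataset, truth: SpecializationTruth) -> float:
    """Accuracy of the true generating rule on the dataset (1.0 by construction)."""
    score = np.where(truth.flags == 1,
                     ds.expert1 @ truth.weights, ds.expert2 @ truth.weights)
    return float(np.mean((score > 0).astype(int) == ds.labels))
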