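"""Assembling labeled phage-host samples.

An immersion assay records a continuous infection score for (host, phage)
pairs in a host x phage matrix.  Scores strictly above 1.5 become positive
labels (1), everything else measured becomes negative (0); the exact value
1.5 is negative because the rule is strict-greater (the boundary is
otherwise undefined).  Each labeled pair carries three feature blocks: the
26-wide statistics vector and the two expert embedding vectors, combined
across phage and host either by element-wise mean (default, keeps the
single-entity widths) or by concatenation (doubles them).

The module also implements min-max normalization to [0, 1] fit on a
designated training subset, seeded over/under-sampling to equalize class
counts, and stratified k-fold splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

DEFAULT_THRESHOLD = 1.5

BLOCKS = ("stats", "expert1", "expert2")


@dataclass(frozen=True)
class InteractionMatrix:
    """Host x phage continuous infection scores; NaN marks unmeasured cells."""

    host_ids: tuple[str, ...]
    phage_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.host_ids), len(self.phage_ids)):
            raise ValueError("score matrix shape must be (n_hosts, n_phages)")
        if len(set(self.host_ids)) != len(self.host_ids):
            raise ValueError("host ids must be unique")
        if len(set(self.phage_ids)) != len(self.phage_ids):
            raise ValueError("phage ids must be unique")
        if np.isinf(scores).any():
            raise ValueError("scores must be finite where present")
        object.__setattr__(self, "scores", scores)

    @classmethod
    def from_csv(cls, path) -> "InteractionMatrix":
        """Read a CSV with host ids in the first column and phage ids in the
        header; empty cells become missing values, never zero."""
        df = pd.read_csv(path, index_col=0)
        return cls(
            host_ids=tuple(str(h) for h in df.index),
            phage_ids=tuple(str(p) for p in df.columns),
            scores=df.to_numpy(dtype=float),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.scores, index=list(self.host_ids),
                     columns=list(self.phage_ids)).to_csv(path)


def binarize_labels(
    matrix: InteractionMatrix, threshold: float = DEFAULT_THRESHOLD
) -> tuple[list[tuple[str, str, int]], int]:
    """Label every measured cell: score > threshold -> 1, else 0.

    Returns the (host, phage, label) triples in row-major matrix order and
    the number of missing cells skipped.
    """
    measured = ~np.isnan(matrix.scores)
    if not measured.any():
        raise ValueError("interaction matrix has no measured cells")
    triples = []
    for i, host in enumerate(matrix.host_ids):
        for j, phage in enumerate(matrix.phage_ids):
            if measured[i, j]:
                triples.append((host, phage, int(matrix.scores[i, j] > threshold)))
    n_missing = int((~measured).sum())
    return triples, n_missing


def assemble_pair(
    phage_block: np.ndarray,
    host_block: np.ndarray,
    mode: Literal["mean", "concat"] = "mean",
) -> np.ndarray:
    """Combine one feature block of a phage and a host into a pair block."""
    phage_block = np.asarray(phage_block, dtype=float)
    host_block = np.asarray(host_block, dtype=float)
    if phage_block.shape != host_block.shape:
        raise ValueError(
            f"block width mismatch: phage {phage_block.shape} vs host {host_block.shape}"
        )
    if mode == "mean":
        return 0.5 * (phage_block + host_block)
    if mode == "concat":
        return np.concatenate([phage_block, host_block])
    raise ValueError(f"unknown pair mode {mode!r}")


@dataclass(frozen=True)
class LabeledPair:
    """One phage-host sample with its assembled feature blocks."""

    phage_id: str
    host_id: str
    stats: np.ndarray
    expert1: np.ndarray
    expert2: np.ndarray
    label: int

    @property
    def sample_id(self) -> str:
        return f"{self.host_id}__{self.phage_id}"


@dataclass
class PairDataset:
    """Column-oriented container for a set of labeled pairs.

    ``stats`` is (N, s); ``expert1`` and ``expert2`` are (N, d) with a
    shared d; ``labels`` is (N,) in {0, 1}.
    """

    sample_ids: list[str]
    stats: np.ndarray
    expert1: np.ndarray
    expert2: np.ndarray
    labels: np.ndarray
    flags: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.stats = np.asarray(self.stats, dtype=float)
        self.expert1 = np.asarray(self.expert1, dtype=float)
        self.expert2 = np.asarray(self.expert2, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        for name in BLOCKS:
            block = getattr(self, name)
            if block.ndim != 2 or block.shape[0] != n:
                raise ValueError(f"{name} must be 2-D with {n} rows")
        if self.expert1.shape[1] != self.expert2.shape[1]:
            raise ValueError(
                "expert streams must share one width: "
                f"{self.expert1.shape[1]} vs {self.expert2.shape[1]}"
            )
        if self.labels.shape != (n,) or not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be a length-N binary vector")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def s(self) -> int:
        return self.stats.shape[1]

    @property
    def d(self) -> int:
        return self.expert1.shape[1]

    def subset(self, idx: Sequence[int]) -> "PairDataset":
        idx = np.asarray(idx, dtype=int)
        return PairDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            stats=self.stats[idx],
            expert1=self.expert1[idx],
            expert2=self.expert2[idx],
            labels=self.labels[idx],
            flags=None if self.flags is None else self.flags[idx],
        )

    def pairs(self) -> Iterator[LabeledPair]:
        for i, sid in enumerate(self.sample_ids):
            host_id, _, phage_id = sid.partition("__")
            yield LabeledPair(
                phage_id=phage_id, host_id=host_id,
                stats=self.stats[i], expert1=self.expert1[i],
                expert2=self.expert2[i], label=int(self.labels[i]),
            )

    @classmethod
    def from_pairs(cls, pairs: Sequence[LabeledPair]) -> "PairDataset":
        return cls(
            sample_ids=[p.sample_id for p in pairs],
            stats=np.stack([p.stats for p in pairs]),
            expert1=np.stack([p.expert1 for p in pairs]),
            expert2=np.stack([p.expert2 for p in pairs]),
            labels=np.array([p.label for p in pairs]),
        )


def assemble_dataset(
    matrix: InteractionMatrix,
    phage_features: dict[str, dict[str, np.ndarray]],
    host_features: dict[str, dict[str, np.ndarray]],
    mode: Literal["mean", "concat"] = "mean",
    threshold: float = DEFAULT_THRESHOLD,
) -> PairDataset:
    """Build the full labeled dataset from the matrix and per-entity blocks.

    ``phage_features[pid]`` / ``host_features[hid]`` map block name
    ("stats", "expert1", "expert2") to that entity's vector.
    """
    triples, _ = binarize_labels(matrix, threshold)
    rows: dict[str, list] = {b: [] for b in BLOCKS}
    ids, labels = [], []
    for host, phage, label in triples:
        if host not in host_features:
            raise KeyError(f"no features for host {host!r}")
        if phage not in phage_features:
            raise KeyError(f"no features for phage {phage!r}")
        for b in BLOCKS:
            rows[b].append(assemble_pair(phage_features[phage][b], host_features[host][b], mode))
        ids.append(f"{host}__{phage}")
        labels.append(label)
    return PairDataset(
        sample_ids=ids,
        stats=np.stack(rows["stats"]),
        expert1=np.stack(rows["expert1"]),
        expert2=np.stack(rows["expert2"]),
        labels=np.array(labels),
    )


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature min and max learned from a fitted set."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maxs < self.mins):
            raise ValueError("max must be >= min for every feature")


def fit_minmax(X: np.ndarray) -> ScalerParams:
    """Column-wise min/max of the (training) matrix X."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("cannot fit a scaler on an empty set")
    return ScalerParams(mins=X.min(axis=0), maxs=X.max(axis=0))


def apply_minmax(X: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Rescale columns via x' = (x - min) / (max - min).

    Constant features map to 0.  Values outside the fitted range are not
    clipped, so test-set features may fall outside [0, 1].
    """
    span = params.maxs - params.mins
    out = np.zeros_like(np.asarray(X, dtype=float))
    nz = span > 0
    out[:, nz] = (X[:, nz] - params.mins[nz]) / span[nz]
    return out


def fit_dataset_scalers(ds: PairDataset) -> dict[str, ScalerParams]:
    """Fit one min-max scaler per feature block."""
    return {b: fit_minmax(getattr(ds, b)) for b in BLOCKS}


def apply_dataset_scalers(ds: PairDataset, scalers: dict[str, ScalerParams]) -> PairDataset:
    return PairDataset(
        sample_ids=list(ds.sample_ids),
        stats=apply_minmax(ds.stats, scalers["stats"]),
        expert1=apply_minmax(ds.expert1, scalers["expert1"]),
        expert2=apply_minmax(ds.expert2, scalers["expert2"]),
        labels=ds.labels.copy(),
        flags=None if ds.flags is None else ds.flags.copy(),
    )


def _class_indices(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("resampling requires both classes to be present")
    return pos, neg


def oversample(ds: PairDataset, seed: int) -> PairDataset:
    """Duplicate random minority samples (with replacement) until the class
    counts are equal; majority rows are untouched."""
    pos, neg = _class_indices(ds.labels)
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    rng = np.random.default_rng(seed)
    extra = rng.choice(minority, size=len(majority) - len(minority), replace=True)
    idx = np.concatenate([np.arange(len(ds)), extra])
    return ds.subset(idx)


def undersample(ds: PairDataset, seed: int) -> PairDataset:
    """Drop random majority samples (without replacement) until the class
    counts are equal; output rows are a subset of the input."""
    pos, neg = _class_indices(ds.labels)
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(majority, size=len(minority), replace=False)
    idx = np.sort(np.concatenate([minority, kept_majority]))
    return ds.subset(idx)


def resample(ds: PairDataset, regime: Literal["raw", "over", "under"], seed: int) -> PairDataset:
    if regime == "raw":
        return ds
    if regime == "over":
        return oversample(ds, seed)
    if regime == "under":
        return undersample(ds, seed)
    raise ValueError(f"unknown sampling regime {regime!r}")


def split_stratified_folds(
    labels: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold split; returns (train_idx, test_idx) pairs.

    Folds are disjoint, cover every sample, and preserve the class ratio to
    within one sample per fold.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(labels)), labels)]
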