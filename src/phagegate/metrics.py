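"""Confusion-matrix statistics and threshold-free curve metrics.

Threshold metrics follow the standard definitions: ACC = (TP+TN)/total,
Prec = TP/(TP+FP), Sens = TP/(TP+FN), Spec = TN/(TN+FP) and F1 the
harmonic mean of precision and recall.  A metric whose denominator is zero
is reported as undefined (None / NA), never coerced to 0 — degenerate
folds with no positives do occur under heavy imbalance.

AUC is computed as the tie-aware rank statistic (the probability that a
random positive outscores a random negative, ties counting one half),
which is the Mann-Whitney formulation of the area under the ROC curve.
AUPR is the step-wise, non-interpolated area under the precision-recall
curve swept in descending score order (the "average precision" dialect).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

METRIC_NAMES = ("acc", "prec", "sens", "spec", "f1", "auc", "aupr")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvalReport:
    """All seven metrics for one run or fold; undefined metrics are None."""

    counts: ConfusionCounts
    acc: float | None
    prec: float | None
    sens: float | None
    spec: float | None
    f1: float | None
    auc: float | None
    aupr: float | None
    n_pos: int
    n_neg: int
    fold: int | None = None
    undefined: tuple[str, ...] = field(default=())

    def metrics(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _check_binary(arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not set(np.unique(arr)) <= {0, 1}:
        raise ValueError(f"{what} must be binary 0/1")
    return arr.astype(int)


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Standard 2x2 counts from binary labels and binary predictions."""
    y = _check_binary(labels, "labels")
    yhat = _check_binary(predictions, "predictions")
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def threshold_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """ACC, Prec, Sens, Spec, F1; zero-denominator metrics are None."""
    if c.total == 0:
        raise ValueError("cannot evaluate an empty sample set")
    prec = _ratio(c.tp, c.tp + c.fp)
    sens = _ratio(c.tp, c.tp + c.fn)
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    elif prec == sens == 0.0:
        f1 = 0.0
    else:
        f1 = None
    return {
        "acc": (c.tp + c.tn) / c.total,
        "prec": prec,
        "sens": sens,
        "spec": _ratio(c.tn, c.tn + c.fp),
        "f1": f1,
    }


def auc(labels: np.ndarray, scores: np.ndarray) -> float | None:
    """Tie-aware rank AUC; None when only one class is present."""
    y = _check_binary(labels, "labels")
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr(labels: np.ndarray, scores: np.ndarray) -> float | None:
    """Step-wise (non-interpolated) area under the PR curve; None without positives."""
    y = _check_binary(labels, "labels")
    if y.sum() == 0:
        return None
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def evaluate(labels: np.ndarray, scores: np.ndarray,
             predictions: np.ndarray | None = None,
             threshold: float = 0.5, fold: int | None = None) -> EvalReport:
    """Full report from labels, continuous scores and (optionally) hard calls.

    When ``predictions`` is omitted, labels are called positive at
    ``score >= threshold``.
    """
    y = _check_binary(labels, "labels")
    scores = np.asarray(scores, dtype=float)
    if predictions is None:
        predictions = (scores >= threshold).astype(int)
    counts = confusion(y, predictions)
    tm = threshold_metrics(counts)
    report_vals = dict(tm, auc=auc(y, scores), aupr=aupr(y, scores))
    undefined = tuple(k for k, v in report_vals.items() if v is None)
    return EvalReport(
        counts=counts, n_pos=int(y.sum()), n_neg=int(len(y) - y.sum()),
        fold=fold, undefined=undefined, **report_vals,
    )


def aggregate_folds(reports: list[EvalReport]) -> dict[str, dict[str, float | int | None]]:
    """Unweighted mean and sd per metric over folds where it is defined.

    Returns ``{metric: {"mean", "sd", "n_defined", "n_undefined"}}``; a
    metric undefined in every fold has mean and sd None.
    """
    if not reports:
        raise ValueError("need at least one report to aggregate")
    out: dict[str, dict[str, float | int | None]] = {}
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        out[name] = {
            "mean": float(np.mean(vals)) if vals else None,
            "sd": float(np.std(vals, ddof=0)) if vals else None,
            "n_defined": len(vals),
            "n_undefined": len(reports) - len(vals),
        }
    return out


def report_to_dict(report: EvalReport) -> dict:
    return {
        "fold": report.fold,
        "counts": {"tp": report.counts.tp, "fp": report.counts.fp,
                   "tn": report.counts.tn, "fn": report.counts.fn},
        "n_pos": report.n_pos, "n_neg": report.n_neg,
        "metrics": report.metrics(),
        "undefined": list(report.undefined),
    }


def write_report_json(path: str | Path, reports: list[EvalReport]) -> None:
    payload = {
        "folds": [report_to_dict(r) for r in reports],
        "aggregate": aggregate_folds(reports),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def reports_to_markdown(reports: list[EvalReport]) -> str:
    """Human-readable table: one metric per row, one fold per column."""
    agg = aggregate_folds(reports)
    header = "| Metric | " + " | ".join(
        f"fold {r.fold}" if r.fold is not None else f"run {i}"
        for i, r in enumerate(reports)
    ) + " | mean |"
    sep = "|" + "---|" * (len(reports) + 2)
    lines = [header, sep]
    for name in METRIC_NAMES:
        cells = [
            "NA" if getattr(r, name) is None else f"{getattr(r, name):.3f}"
            for r in reports
        ]
        mean = agg[name]["mean"]
        cells.append("NA" if mean is None else f"{mean:.3f}")
        lines.append(f"| {name.upper()} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
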