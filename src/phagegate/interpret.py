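"""Interpretability exports: gate weights, expert utilization, heatmaps.

The gating weights are the model's built-in explanation: for every sample
they state how much each expert embedding stream contributed to the fused
representation.  This module exports them per sample together with the
Shannon entropy of the weight pair (0 = fully specialized on one expert,
ln 2 = indifferent), group summaries, and the samples x features matrices
behind feature heatmaps (raw values, no rescaling beyond the pipeline's
own normalization).  Plotting is a thin optional layer over the CSV
exports; the numeric matrices are the testable surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .classifier import MoEClassifier
from .gating import concat_combined, fuse, gate_forward
from .pairs import PairDataset

LN2 = float(np.log(2.0))

Block = Literal["stats", "expert1", "expert2", "fused", "combined"]


def gate_entropy(alpha: np.ndarray) -> np.ndarray:
    """Shannon entropy of each weight pair, in nats (range [0, ln 2])."""
    a = np.clip(np.atleast_2d(alpha), 1e-300, 1.0)
    return -(a * np.log(a)).sum(axis=1)


@dataclass(frozen=True)
class GateReport:
    """Per-sample gate weights with entropy and label-group summaries."""

    table: pd.DataFrame          # sample_id, alpha1, alpha2, entropy, label
    group_means: pd.DataFrame    # mean alpha1/alpha2 per label group

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")


def export_gate_weights(model: MoEClassifier, ds: PairDataset) -> GateReport:
    """Evaluate the fitted gate on every sample of the dataset."""
    out = gate_forward(model.gate, ds.stats)
    table = pd.DataFrame({
        "sample_id": ds.sample_ids,
        "alpha1": out.alpha[:, 0],
        "alpha2": out.alpha[:, 1],
        "entropy": gate_entropy(out.alpha),
        "label": ds.labels,
    })
    group_means = table.groupby("label")[["alpha1", "alpha2", "entropy"]].mean()
    return GateReport(table=table, group_means=group_means)


def heatmap_matrix(
    model: MoEClassifier,
    ds: PairDataset,
    block: Block = "fused",
    order: Literal["input", "label-grouped"] = "input",
) -> pd.DataFrame:
    """Samples x features matrix of the requested feature block.

    ``fused`` and ``combined`` are the post-fusion (pre-classifier)
    representations produced by the fitted gate; ``label-grouped`` orders
    rows by label (stable within groups), a pure permutation of the input
    order.
    """
    if block in ("stats", "expert1", "expert2"):
        values = getattr(ds, block)
    elif block in ("fused", "combined"):
        alpha = gate_forward(model.gate, ds.stats).alpha
        values = fuse(alpha, ds.expert1, ds.expert2)
        if block == "combined":
            values = concat_combined(values, ds.stats)
    else:
        raise ValueError(f"unknown feature block {block!r}")
    df = pd.DataFrame(values, index=pd.Index(ds.sample_ids, name="sample_id"))
    df.columns = [f"f{j:04d}" for j in range(values.shape[1])]
    if order == "label-grouped":
        perm = np.argsort(ds.labels, kind="stable")
        df = df.iloc[perm]
    elif order != "input":
        raise ValueError(f"unknown row order {order!r}")
    return df


def export_heatmaps(model: MoEClassifier, ds: PairDataset, out_dir: str | Path,
                    blocks: tuple[Block, ...] = ("stats", "expert1", "expert2",
                                                 "fused", "combined"),
                    order: Literal["input", "label-grouped"] = "label-grouped",
                    png: bool = False) -> dict[str, Path]:
    """Write one CSV (and optionally one PNG) per requested block."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for block in blocks:
        df = heatmap_matrix(model, ds, block=block, order=order)
        path = out_dir / f"heatmap_{block}.csv"
        df.to_csv(path, float_format="%.17g")
        written[block] = path
        if png:
            _plot_heatmap(df, out_dir / f"heatmap_{block}.png", title=block)
    return written


def _plot_heatmap(df: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(df.to_numpy(), aspect="auto", interpolation="nearest")
    ax.set_xlabel("feature channel")
    ax.set_ylabel("sample")
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
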