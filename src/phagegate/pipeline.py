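"""End-to-end experiment orchestration.

``run_experiment`` wires the stages together: read proteomes, compute
descriptors and expert embeddings per entity, assemble labeled pairs from
the interaction matrix, split stratified folds, resample and min-max
normalize the training portion, train the gate+CNN jointly, predict,
evaluate and export gate weights.  Every output directory is
self-describing: it contains the configuration snapshot, the seeds, and
per-fold reports.

By default folds are split first and resampling/normalization are fit on
the training portion only, so no test sample (by identity) leaks into
training.  ``paper_mode=True`` instead resamples and normalizes the full
dataset before splitting, mimicking protocols that balance classes
globally; it is provided for comparability, not as the recommended
default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from . import __version__
from .classifier import ModelConfig, MoEClassifier
from .descriptors import entity_stats_vector
from .embeddings import ProviderSpec, embed_entity
from .interpret import export_gate_weights
from .io import read_entity_fasta, save_dataset, write_predictions
from .metrics import EvalReport, evaluate, reports_to_markdown, write_report_json
from .pairs import (InteractionMatrix, PairDataset, apply_dataset_scalers,
                    assemble_dataset, fit_dataset_scalers, resample,
                    split_stratified_folds)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one experiment run."""

    hosts_fasta: str | Path = ""
    phages_fasta: str | Path = ""
    matrix_csv: str | Path = ""
    entity_pattern: str | None = r"entity=(\S+)"
    expert1: ProviderSpec = field(default_factory=lambda: ProviderSpec(name="synthetic", d=16, seed=101))
    expert2: ProviderSpec = field(default_factory=lambda: ProviderSpec(name="synthetic", d=16, seed=202))
    pair_mode: Literal["mean", "concat"] = "mean"
    threshold: float = 1.5
    regime: Literal["raw", "over", "under"] = "raw"
    k_folds: int = 5
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0
    paper_mode: bool = False
    out_dir: str | Path = "runs/run"

    def __post_init__(self) -> None:
        if self.expert1.d != self.expert2.d:
            raise ValueError(
                f"expert streams must share one width: {self.expert1.d} vs {self.expert2.d}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("hosts_fasta", "phages_fasta", "matrix_csv", "out_dir"):
            d[key] = str(d[key])
        for ex in ("expert1", "expert2"):
            d[ex].pop("adapter", None)
            if d[ex]["path"] is not None:
                d[ex]["path"] = str(d[ex]["path"])
        d["package_version"] = __version__
        return d


def extract_entity_features(
    entities: dict[str, list],
    expert1: ProviderSpec,
    expert2: ProviderSpec,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-entity feature blocks: stats (26), expert1 (d), expert2 (d)."""
    features = {}
    for eid, seqs in entities.items():
        features[eid] = {
            "stats": entity_stats_vector(seqs, entity_id=eid).to_array(),
            "expert1": embed_entity(expert1, seqs, entity_id=eid).vector,
            "expert2": embed_entity(expert2, seqs, entity_id=eid).vector,
        }
    return features


def assemble_from_config(config: RunConfig) -> PairDataset:
    """Stages 1-3: read inputs, featurize entities, assemble labeled pairs."""
    t0 = time.perf_counter()
    hosts = read_entity_fasta(config.hosts_fasta, config.entity_pattern)
    phages = read_entity_fasta(config.phages_fasta, config.entity_pattern)
    matrix = InteractionMatrix.from_csv(config.matrix_csv)
    host_features = extract_entity_features(hosts, config.expert1, config.expert2)
    phage_features = extract_entity_features(phages, config.expert1, config.expert2)
    ds = assemble_dataset(matrix, phage_features, host_features,
                          mode=config.pair_mode, threshold=config.threshold)
    logger.info("assembled %d pairs (%d pos / %d neg) in %.2fs",
                len(ds), int(ds.labels.sum()), int((1 - ds.labels).sum()),
                time.perf_counter() - t0)
    return ds


def run_folds(ds: PairDataset, config: RunConfig,
              out_dir: Path | None = None) -> tuple[list[EvalReport], list[MoEClassifier]]:
    """Stages 4-8 on an assembled dataset; optionally writes per-fold artifacts."""
    seeds = np.random.SeedSequence(config.seed).generate_state(3) % (2**31)
    fold_seed, resample_seed, model_seed = (int(x) for x in seeds)

    if config.paper_mode:
        # global protocol: balance and normalize before splitting
        ds = resample(ds, config.regime, resample_seed)
        ds = apply_dataset_scalers(ds, fit_dataset_scalers(ds))

    folds = split_stratified_folds(ds.labels, config.k_folds, fold_seed)
    reports, models = [], []
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        t0 = time.perf_counter()
        train_ds, test_ds = ds.subset(train_idx), ds.subset(test_idx)
        if not config.paper_mode:
            train_ds = resample(train_ds, config.regime, resample_seed + fold_id)
            scalers = fit_dataset_scalers(train_ds)
            train_ds = apply_dataset_scalers(train_ds, scalers)
            test_ds = apply_dataset_scalers(test_ds, scalers)
        counts = np.bincount(train_ds.labels, minlength=2)
        logger.info("fold %d: train %d (neg %d / pos %d), test %d",
                    fold_id, len(train_ds), counts[0], counts[1], len(test_ds))

        model = MoEClassifier(
            s=train_ds.s, d=train_ds.d,
            config=dataclasses.replace(config.model, seed=model_seed + fold_id),
        )
        model.fit(train_ds.stats, train_ds.expert1, train_ds.expert2, train_ds.labels)
        records = model.predict(test_ds.stats, test_ds.expert1, test_ds.expert2,
                                sample_ids=test_ds.sample_ids)
        p_hat = np.array([r.p_hat for r in records])
        y_hat = np.array([r.y_hat for r in records])
        report = evaluate(test_ds.labels, p_hat, predictions=y_hat, fold=fold_id)
        reports.append(report)
        models.append(model)
        logger.info("fold %d done in %.2fs: acc=%s", fold_id,
                    time.perf_counter() - t0, report.acc)

        if out_dir is not None:
            write_predictions(out_dir / f"predictions_fold{fold_id}.tsv", records)
            model.save(out_dir / f"checkpoint_fold{fold_id}.npz",
                       extra_meta={"fold": fold_id, "run_seed": config.seed})
            export_gate_weights(model, test_ds).to_csv(
                out_dir / f"gate_weights_fold{fold_id}.csv")
    return reports, models


def run_experiment(config: RunConfig) -> tuple[list[EvalReport], Path]:
    """Execute the full pipeline and write a self-describing output directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")

    ds = assemble_from_config(config)
    save_dataset(ds, out_dir / "dataset")
    reports, _ = run_folds(ds, config, out_dir=out_dir)

    write_report_json(out_dir / "metrics.json", reports)
    (out_dir / "metrics.md").write_text(reports_to_markdown(reports))
    return reports, out_dir
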