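"""Format readers and writers: FASTA, descriptor tables, datasets, predictions.

Parsing is strict — malformed rows fail with their location — and numeric
round-trips are lossless (17 significant digits).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .classifier import PredictionRecord
from .descriptors import (STATS_FEATURE_NAMES, ProteinSequence, StatsVector,
                          sanitize_sequence)
from .pairs import PairDataset

FLOAT_FMT = "%.17g"


def read_entity_fasta(
    path: str | Path,
    entity_pattern: str | None = None,
) -> dict[str, list[ProteinSequence]]:
    """Read a multi-FASTA of proteins grouped into entities.

    The entity id of a record defaults to the first token of its header
    (each record is then its own entity); ``entity_pattern`` supplies a
    regex whose first group extracts the entity id from the full
    description instead (e.g. ``entity=(\\S+)`` groups protein records
    under their phage or host strain).
    """
    pattern = re.compile(entity_pattern) if entity_pattern else None
    entities: dict[str, list[ProteinSequence]] = {}
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        if pattern:
            m = pattern.search(record.description)
            if not m:
                raise ValueError(
                    f"{path}: record {record.id!r} does not match entity pattern "
                    f"{entity_pattern!r}"
                )
            entity_id = m.group(1)
        else:
            entity_id = record.id
        seq = sanitize_sequence(record.id, str(record.seq))
        entities.setdefault(entity_id, []).append(seq)
    if n == 0:
        raise ValueError(f"{path}: no FASTA records found")
    return entities


def write_descriptor_table(path: str | Path, vectors: list[StatsVector]) -> None:
    """Per-sequence/entity descriptor TSV: id column + the 26 features."""
    df = pd.DataFrame([v.to_array() for v in vectors],
                      columns=list(STATS_FEATURE_NAMES))
    df.insert(0, "id", [v.id for v in vectors])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    expected = ["id"] + list(STATS_FEATURE_NAMES)
    if list(df.columns) != expected:
        raise ValueError(f"{path}: descriptor table must have columns {expected}")
    return df


def save_dataset(ds: PairDataset, out_dir: str | Path) -> None:
    """Persist an assembled dataset: samples.tsv plus one TSV per block."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = pd.DataFrame({"sample_id": ds.sample_ids, "label": ds.labels})
    if ds.flags is not None:
        samples["flag"] = ds.flags
    samples.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    for block in ("stats", "expert1", "expert2"):
        arr = getattr(ds, block)
        pd.DataFrame(arr).to_csv(out_dir / f"{block}.tsv", sep="\t",
                                 index=False, header=False, float_format=FLOAT_FMT)


def load_dataset(in_dir: str | Path) -> PairDataset:
    in_dir = Path(in_dir)
    samples = pd.read_csv(in_dir / "samples.tsv", sep="\t")
    blocks = {
        block: pd.read_csv(in_dir / f"{block}.tsv", sep="\t", header=None,
                    float_precision="round_trip").to_numpy()
        for block in ("stats", "expert1", "expert2")
    }
    return PairDataset(
        sample_ids=[str(s) for s in samples["sample_id"]],
        labels=samples["label"].to_numpy(),
        flags=samples["flag"].to_numpy() if "flag" in samples else None,
        **blocks,
    )


def write_predictions(path: str | Path, records: list[PredictionRecord]) -> None:
    df = pd.DataFrame([{
        "sample_id": r.sample_id, "p_hat": r.p_hat, "y_hat": r.y_hat,
        "alpha1": r.alpha1, "alpha2": r.alpha2,
    } for r in records])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"sample_id", "p_hat", "y_hat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: prediction table missing columns {sorted(missing)}")
    return df
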