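"""Expert embedding providers.

The two "expert" feature streams are fixed-length per-entity vectors in the
role of pre-trained protein language-model embeddings (d = 1024 in the
reference configuration).  The pipeline consumes them through a uniform
provider contract, so the source can be:

* ``synthetic`` — a deterministic content-addressed pseudo-embedding used
  for testing and simulation (no downloads, fully reproducible);
* ``table`` — precomputed vectors loaded from a TSV file;
* ``plm-adapter`` — an optional hook for a real protein language model,
  never imported by the core package or the test suite.

Per-protein vectors are pooled (mean by default, max optionally) into one
vector per entity, since a sample is a phage or host organism that may
carry several protein records.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .descriptors import ProteinSequence

DEFAULT_DIM = 1024


@dataclass(frozen=True)
class ExpertEmbedding:
    """One expert stream's fixed-length vector for one entity."""

    entity_id: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError(f"embedding for {self.entity_id!r} must be a finite 1-D vector")
        object.__setattr__(self, "vector", v)


@dataclass(frozen=True)
class ProviderSpec:
    """Configuration of one expert stream.

    ``seed`` fixes all synthetic output; ``path`` points at a TSV table for
    the table provider; ``pooling`` reduces per-protein vectors to one
    per-entity vector.
    """

    name: Literal["synthetic", "table", "plm-adapter"] = "synthetic"
    d: int = DEFAULT_DIM
    seed: int = 0
    path: str | Path | None = None
    pooling: Literal["mean", "max"] = "mean"
    adapter: Callable[[list[ProteinSequence], int], np.ndarray] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("embedding dimension d must be >= 2")
        if self.name == "table" and self.path is None:
            raise ValueError("table provider requires a path")


def synthetic_embed(seed: int, d: int, sequences: list[ProteinSequence]) -> np.ndarray:
    """Deterministic pseudo-embedding of an entity's protein content.

    The vector is a pure function of ``(seed, sorted sequence strings)``:
    the sequences are sorted so record order never matters, hashed, and the
    hash seeds a generator that draws ``d`` values uniform in [-1, 1].
    Reproducible across processes and platforms.
    """
    if d < 2:
        raise ValueError("d must be >= 2")
    if not sequences:
        raise ValueError("need at least one sequence to embed")
    content = "|".join(sorted(s.residues for s in sequences))
    digest = hashlib.sha256(f"{seed}:{content}".encode()).digest()
    # keep the derived seed in 32-bit range so downstream RNGs accept it
    rng = np.random.default_rng(int.from_bytes(digest[:4], "big"))
    return rng.uniform(-1.0, 1.0, size=d)


def load_embedding_table(path: str | Path) -> dict[str, np.ndarray]:
    """Load a TSV of per-entity vectors (header ``id`` then numeric columns).

    Every row must have the same width; a ragged or non-numeric row raises
    with its line number.
    """
    path = Path(path)
    table: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise ValueError(f"{path}: first header column must be 'id'")
        width = len(header) - 1
        if width < 2:
            raise ValueError(f"{path}: need at least 2 feature columns")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) - 1 != width:
                raise ValueError(
                    f"{path}:{lineno}: expected {width} values, got {len(parts) - 1}"
                )
            try:
                vec = np.array([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            table[parts[0]] = vec
    return table


def write_embedding_table(path: str | Path, table: dict[str, np.ndarray]) -> None:
    """Write per-entity vectors as TSV (columns ``id, e0001..e{d}``) at full precision."""
    d = len(next(iter(table.values())))
    df = pd.DataFrame(
        {eid: np.asarray(vec, dtype=float) for eid, vec in table.items()}
    ).T
    df.columns = [f"e{i + 1:04d}" for i in range(d)]
    df.index.name = "id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def embed_entity(spec: ProviderSpec, sequences: list[ProteinSequence],
                 entity_id: str = "") -> ExpertEmbedding:
    """Produce one entity's embedding under the given provider spec.

    Deterministic given the spec and the input sequences.  For the table
    provider a missing entity id raises a lookup error.
    """
    if not sequences and spec.name != "table":
        raise ValueError(f"entity {entity_id!r}: at least one sequence required")
    entity_id = entity_id or (sequences[0].id if sequences else "")

    if spec.name == "synthetic":
        vec = synthetic_embed(spec.seed, spec.d, sequences)
    elif spec.name == "table":
        table = load_embedding_table(spec.path)  # type: ignore[arg-type]
        if entity_id not in table:
            raise KeyError(f"entity {entity_id!r} not found in embedding table {spec.path}")
        vec = table[entity_id]
    elif spec.name == "plm-adapter":
        if spec.adapter is None:
            raise ValueError("plm-adapter provider requires an adapter callable")
        per_protein = np.atleast_2d(spec.adapter(sequences, spec.d))
        vec = per_protein.max(axis=0) if spec.pooling == "max" else per_protein.mean(axis=0)
    else:  # pragma: no cover - guarded by ProviderSpec literal type
        raise ValueError(f"unknown provider {spec.name!r}")

    if len(vec) != spec.d:
        raise ValueError(
            f"entity {entity_id!r}: provider returned width {len(vec)}, expected {spec.d}"
        )
    return ExpertEmbedding(entity_id=entity_id, vector=vec)
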