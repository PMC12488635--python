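"""Interpretable statistical protein descriptors.

Three descriptors summarise a protein sequence:

* **AAC** (amino-acid composition): the frequency of each of the 20
  standard residues, ``AAC_i = n_i / L`` where ``n_i`` is the count of
  residue ``i`` and ``L`` the sequence length.
* **AC** (atomic composition): the fraction of C, H, N, O and S atoms in
  the free amino acids of the sequence, ``AC_j = a_j / sum_k a_k``.
* **MW** (molecular weight): ``MW = sum_i n_i * M(A_i)`` in daltons, a
  literal sum of free amino-acid masses with no peptide-bond correction.

Concatenated in the fixed order ``20 AAC (alphabetical) || 5 AC
(C,H,N,O,S) || 1 MW`` they form the 26-dimensional statistics vector that
feeds both the gating network and the classifier.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .residue_tables import AMINO_ACIDS, ELEMENTS, ResidueTables, default_tables

logger = logging.getLogger(__name__)

#: Width of the full statistics vector: 20 AAC + 5 AC + 1 MW.
STATS_DIM = 26

#: Column names of the statistics block, in concatenation order.
STATS_FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"aac_{aa}" for aa in AMINO_ACIDS] + [f"ac_{el}" for el in ELEMENTS] + ["mw"]
)

_VALID = set(AMINO_ACIDS)
_WHITESPACE = re.compile(r"\s+")


class EmptySequenceError(ValueError):
    """Raised when nothing survives sanitization of a sequence record."""


@dataclass(frozen=True)
class ProteinSequence:
    """A sanitized protein sequence restricted to the 20 standard residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptySequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(f"sequence {self.id!r} contains non-standard residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class StatsVector:
    """The 26-dimensional descriptor block for one sequence or entity."""

    aac: np.ndarray
    ac: np.ndarray
    mw: float
    id: str = field(default="", compare=False)

    def to_array(self) -> np.ndarray:
        """Concatenate as ``aac || ac || mw`` (length 26)."""
        return np.concatenate([self.aac, self.ac, [self.mw]])


def sanitize_sequence(record_id: str, raw: str) -> ProteinSequence:
    """Uppercase *raw* and drop every character outside the 20-letter alphabet.

    Ambiguity codes (X, B, Z, J), the rare residues U and O, stop/gap symbols
    and whitespace are all removed; a warning is logged with the counts of
    what was dropped.

    Raises
    ------
    EmptySequenceError
        If no standard residue survives, naming the offending record.
    """
    cleaned = _WHITESPACE.sub("", raw).upper()
    kept = [c for c in cleaned if c in _VALID]
    dropped = Counter(c for c in cleaned if c not in _VALID)
    if dropped:
        logger.warning(
            "sequence %r: dropped %d non-standard character(s): %s",
            record_id, sum(dropped.values()), dict(dropped),
        )
    if not kept:
        raise EmptySequenceError(
            f"sequence {record_id!r} has no standard residues after sanitization"
        )
    return ProteinSequence(id=record_id, residues="".join(kept))


def amino_acid_composition(seq: ProteinSequence) -> np.ndarray:
    """Per-residue frequencies in alphabetical one-letter order (length 20)."""
    counts = Counter(seq.residues)
    L = len(seq)
    return np.array([counts.get(aa, 0) / L for aa in AMINO_ACIDS])


def atomic_composition(seq: ProteinSequence, tables: ResidueTables | None = None) -> np.ndarray:
    """C,H,N,O,S atom fractions over the sequence's free amino acids (length 5)."""
    tables = tables or default_tables()
    counts = Counter(seq.residues)
    totals = np.zeros(len(ELEMENTS))
    for aa in AMINO_ACIDS:  # fixed order keeps the sum permutation invariant
        if aa in counts:
            totals += counts[aa] * np.asarray(tables.atom_counts[aa], dtype=float)
    return totals / totals.sum()


def molecular_weight(seq: ProteinSequence, tables: ResidueTables | None = None) -> float:
    """Sum of free amino-acid masses in daltons (no water-loss correction)."""
    tables = tables or default_tables()
    counts = Counter(seq.residues)
    # fixed summation order makes the result exactly permutation invariant
    return float(sum(counts[aa] * tables.masses[aa] for aa in AMINO_ACIDS if aa in counts))


def build_stats_vector(seq: ProteinSequence, tables: ResidueTables | None = None) -> StatsVector:
    """Assemble the full 26-dimensional descriptor block for one sequence."""
    tables = tables or default_tables()
    return StatsVector(
        aac=amino_acid_composition(seq),
        ac=atomic_composition(seq, tables),
        mw=molecular_weight(seq, tables),
        id=seq.id,
    )


def entity_stats_vector(
    sequences: list[ProteinSequence],
    tables: ResidueTables | None = None,
    entity_id: str = "",
) -> StatsVector:
    """Descriptor block for a multi-protein entity.

    The proteins of an entity (a phage or a host strain) are treated as one
    pooled residue sample: AAC and AC are computed over the concatenation of
    all sequences and MW is the mean per-protein weight, so the block stays
    on the scale of a single protein regardless of proteome size.
    """
    if not sequences:
        raise ValueError(f"entity {entity_id!r} has no sequences")
    tables = tables or default_tables()
    pooled = ProteinSequence(
        id=entity_id or sequences[0].id,
        residues="".join(s.residues for s in sequences),
    )
    mws = [molecular_weight(s, tables) for s in sequences]
    return StatsVector(
        aac=amino_acid_composition(pooled),
        ac=atomic_composition(pooled, tables),
        mw=float(np.mean(mws)),
        id=pooled.id,
    )
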