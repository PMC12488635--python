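"""Per-residue reference data for the statistical descriptors.

The tables describe the 20 standard amino acids as *free* molecules: the
atomic composition descriptor counts every C, H, N, O and S atom of the
free amino acid, and the molecular-weight descriptor sums free amino-acid
masses with no peptide-bond water correction.  Masses are derived from the
molecular formulas below using IUPAC 2021 standard (average) atomic
weights, which keeps the mass table and the atom-count table mutually
consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

#: The 20 standard one-letter codes, alphabetical.  This order fixes the
#: layout of the AAC block of every descriptor vector.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Elements tracked by the atomic-composition descriptor, in fixed order.
ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "S")

# IUPAC standard atomic weights (2021 abridged values), g/mol.
_ATOMIC_WEIGHT = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}

# Molecular formulas of the free amino acids as (C, H, N, O, S) counts.
_FORMULAS: dict[str, tuple[int, int, int, int, int]] = {
    "A": (3, 7, 1, 2, 0),   # alanine      C3H7NO2
    "C": (3, 7, 1, 2, 1),   # cysteine     C3H7NO2S
    "D": (4, 7, 1, 4, 0),   # aspartate    C4H7NO4
    "E": (5, 9, 1, 4, 0),   # glutamate    C5H9NO4
    "F": (9, 11, 1, 2, 0),  # phenylalanine C9H11NO2
    "G": (2, 5, 1, 2, 0),   # glycine      C2H5NO2
    "H": (6, 9, 3, 2, 0),   # histidine    C6H9N3O2
    "I": (6, 13, 1, 2, 0),  # isoleucine   C6H13NO2
    "K": (6, 14, 2, 2, 0),  # lysine       C6H14N2O2
    "L": (6, 13, 1, 2, 0),  # leucine      C6H13NO2
    "M": (5, 11, 1, 2, 1),  # methionine   C5H11NO2S
    "N": (4, 8, 2, 3, 0),   # asparagine   C4H8N2O3
    "P": (5, 9, 1, 2, 0),   # proline      C5H9NO2
    "Q": (5, 10, 2, 3, 0),  # glutamine    C5H10N2O3
    "R": (6, 14, 4, 2, 0),  # arginine     C6H14N4O2
    "S": (3, 7, 1, 3, 0),   # serine       C3H7NO3
    "T": (4, 9, 1, 3, 0),   # threonine    C4H9NO3
    "V": (5, 11, 1, 2, 0),  # valine       C5H11NO2
    "W": (11, 12, 2, 2, 0), # tryptophan   C11H12N2O2
    "Y": (9, 11, 1, 3, 0),  # tyrosine     C9H11NO3
}


def _mass(formula: tuple[int, int, int, int, int]) -> float:
    return sum(n * _ATOMIC_WEIGHT[el] for n, el in zip(formula, ELEMENTS))


@dataclass(frozen=True)
class ResidueTables:
    """Reference masses and atom counts for the 20 standard residues.

    Attributes
    ----------
    masses
        Average mass of each free amino acid, daltons.
    atom_counts
        (C, H, N, O, S) atom counts of each free amino acid.
    """

    masses: Mapping[str, float]
    atom_counts: Mapping[str, tuple[int, int, int, int, int]]

    def __post_init__(self) -> None:
        for table in (self.masses, self.atom_counts):
            if sorted(table) != sorted(AMINO_ACIDS):
                raise ValueError("residue table must cover exactly the 20 standard residues")
        if any(m <= 0 for m in self.masses.values()):
            raise ValueError("residue masses must be positive")
        if any(c[0] < 1 or min(c) < 0 for c in self.atom_counts.values()):
            raise ValueError("atom counts must be >= 0 with at least one carbon")


def default_tables() -> ResidueTables:
    """The package's built-in free amino-acid tables."""
    return ResidueTables(
        masses=MappingProxyType({aa: _mass(f) for aa, f in _FORMULAS.items()}),
        atom_counts=MappingProxyType(dict(_FORMULAS)),
    )
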