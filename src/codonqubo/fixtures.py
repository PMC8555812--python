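"""Deterministic generators for peptides, toy usage tables and worked cases.

These stand in for downloaded protein sequences: every test input is a
pure function of a :class:`FixtureSpec`, so the whole suite runs offline
and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .codon_tables import (
    STANDARD_AMINO_ACIDS,
    SYNONYMOUS_CODONS,
    CodonUsageTable,
)
from .encoding import QubitLayout

__all__ = [
    "FixtureSpec",
    "WorkedExample",
    "random_peptide",
    "random_valid_bits",
    "uniform_table",
    "adversarial_table",
    "worked_examples",
]

#: alphabet policies: all 20 standard residues, or only the three
#: six-codon residues (the worst case for search-space size per residue)
ALPHABETS = {"all20": STANDARD_AMINO_ACIDS, "six_codon": "LRS"}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    peptide_length: int = 20
    alphabet: str = "all20"

    def __post_init__(self) -> None:
        if self.peptide_length < 1:
            raise ValueError("peptide_length must be >= 1")
        if self.alphabet not in ALPHABETS:
            raise ValueError(f"unknown alphabet policy {self.alphabet!r}")


def random_peptide(spec: FixtureSpec) -> str:
    """Seeded uniform draw over the policy alphabet."""
    rng = np.random.default_rng(spec.seed)
    letters = ALPHABETS[spec.alphabet]
    return "".join(rng.choice(list(letters), size=spec.peptide_length))


def random_valid_bits(layout: QubitLayout, seed: int = 0) -> np.ndarray:
    """Seeded uniform random one-hot assignment (one codon per position)."""
    rng = np.random.default_rng(seed)
    bits = np.zeros(layout.M, dtype=np.int8)
    for sl in layout.position_slices:
        bits[sl.start + int(rng.integers(0, sl.stop - sl.start))] = 1
    return bits


def uniform_table(organism: str = "uniform") -> CodonUsageTable:
    """Every synonymous codon equally frequent (e.g. each Leu codon 1/6)."""
    weights = {
        aa: {c: 1.0 for c in codons} for aa, codons in SYNONYMOUS_CODONS.items()
    }
    return CodonUsageTable.from_weights(organism, weights)


def adversarial_table() -> CodonUsageTable:
    """Synthetic table with a zero-frequency codon (CTA for Leu), for
    exercising the epsilon_f floor: its log-inverse penalty must stay
    finite, and an optimizer with c_f > 0 should never pick it while a
    synonymous alternative exists."""
    weights: dict[str, dict[str, float]] = {
        aa: {c: 1.0 for c in codons} for aa, codons in SYNONYMOUS_CODONS.items()
    }
    weights["L"]["CTA"] = 0.0
    return CodonUsageTable.from_weights("synthetic_zero_freq", weights)


@dataclass(frozen=True)
class WorkedExample:
    name: str
    kind: str  # "layout" or "repeat"
    inputs: tuple[Any, ...]
    expected: dict[str, Any]


def worked_examples() -> list[WorkedExample]:
    """Small pinned cases used across the test suite.

    Layout cases carry (peptide,) with expected variable and state counts;
    repeat cases carry (codon_a, codon_b) with the expected run penalty
    per mode.
    """
    return [
        WorkedExample("layout-GSK", "layout", ("GSK",), {"M": 12, "states": 48}),
        WorkedExample("layout-LLLL", "layout", ("LLLL",), {"M": 24, "states": 1296}),
        WorkedExample("r-ATA-TCG", "repeat", ("ATA", "TCG"), {"window": 0, "junction": 0}),
        WorkedExample("r-ATA-ACG", "repeat", ("ATA", "ACG"), {"window": 3, "junction": 3}),
        WorkedExample("r-CGG-GGG", "repeat", ("CGG", "GGG"), {"window": 24, "junction": 24}),
        WorkedExample("r-GGC-GGC", "repeat", ("GGC", "GGC"), {"window": 3, "junction": 0}),
    ]
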