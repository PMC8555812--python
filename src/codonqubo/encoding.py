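"""One-hot variable layout for a peptide and bit/sequence conversion.

Every candidate codon at every peptide position gets its own binary
variable.  A bit vector is *valid* when exactly one variable per position
is set; the selected codons concatenate to the designed nucleotide
sequence.  Variables are ordered by position and, within a position,
lexicographically by codon, so layouts (and everything derived from them)
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import numpy as np

from .codon_tables import CodonUsageTable

__all__ = ["Variable", "QubitLayout", "DecodeResult", "build_layout",
           "count_valid_states", "decode", "encode"]


@dataclass(frozen=True)
class Variable:
    """One binary variable: candidate ``codon`` at peptide ``position`` (0-based)."""

    index: int
    position: int
    codon: str


@dataclass(frozen=True)
class QubitLayout:
    peptide: str
    variables: tuple[Variable, ...]

    @property
    def M(self) -> int:
        """Total number of binary variables."""
        return len(self.variables)

    @property
    def n_nt(self) -> int:
        """Nucleotide length of any decoded sequence (3 per residue)."""
        return 3 * len(self.peptide)

    @cached_property
    def position_slices(self) -> tuple[slice, ...]:
        """Variable-index slice per peptide position."""
        counts = [0] * len(self.peptide)
        for v in self.variables:
            counts[v.position] += 1
        slices, start = [], 0
        for n in counts:
            slices.append(slice(start, start + n))
            start += n
        return tuple(slices)

    def codons_at(self, position: int) -> tuple[str, ...]:
        return tuple(v.codon for v in self.variables[self.position_slices[position]])


@dataclass(frozen=True)
class DecodeResult:
    """Outcome of interpreting a bit vector against a layout.

    ``violations`` lists ``(position, n_selected)`` with 1-based positions
    for every residue where the one-hot constraint is broken (zero or more
    than one codon selected).
    """

    valid: bool
    dna: str | None
    violations: tuple[tuple[int, int], ...] = ()


def build_layout(peptide: str, table: CodonUsageTable) -> QubitLayout:
    """Lay out one variable per synonymous codon per position.

    The variable count per position equals the synonymous-codon count of
    that residue in ``table`` (1-6), so e.g. a run of four leucines yields
    24 variables.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    peptide = peptide.upper()
    variables: list[Variable] = []
    for p, aa in enumerate(peptide):
        try:
            codons = table.codons_for(aa)
        except KeyError:
            raise ValueError(
                f"residue {aa!r} at position {p + 1} has no codons in table "
                f"{table.organism!r}"
            ) from None
        for codon in sorted(codons):
            variables.append(Variable(index=len(variables), position=p, codon=codon))
    return QubitLayout(peptide=peptide, variables=tuple(variables))


def count_valid_states(layout: QubitLayout) -> int:
    """Number of one-hot assignments: the product of per-position codon counts."""
    total = 1
    for sl in layout.position_slices:
        total *= sl.stop - sl.start
    return total


def _as_bits(layout: QubitLayout, bits: Sequence[int] | np.ndarray) -> np.ndarray:
    arr = np.asarray(bits, dtype=np.int8)
    if arr.shape != (layout.M,):
        raise ValueError(f"bit vector length {arr.shape} does not match M={layout.M}")
    return arr


def decode(layout: QubitLayout, bits: Sequence[int] | np.ndarray) -> DecodeResult:
    """Turn a bit vector into a nucleotide sequence, or flag why it cannot be.

    Valid vectors select exactly one codon per position; the result is the
    3L-nucleotide concatenation of the selected codons.  Invalid vectors
    produce ``valid=False`` with every offending position listed.
    """
    arr = _as_bits(layout, bits)
    codons: list[str] = []
    violations: list[tuple[int, int]] = []
    for p, sl in enumerate(layout.position_slices):
        selected = [layout.variables[i].codon for i in range(sl.start, sl.stop) if arr[i]]
        if len(selected) == 1:
            codons.append(selected[0])
        else:
            violations.append((p + 1, len(selected)))
    if violations:
        return DecodeResult(valid=False, dna=None, violations=tuple(violations))
    return DecodeResult(valid=True, dna="".join(codons))


def encode(layout: QubitLayout, dna: str) -> np.ndarray:
    """Inverse of :func:`decode`: one-hot bits for a synonymous nucleotide sequence."""
    dna = dna.upper()
    if len(dna) != layout.n_nt:
        raise ValueError(f"dna length {len(dna)} does not match 3L={layout.n_nt}")
    bits = np.zeros(layout.M, dtype=np.int8)
    for p, sl in enumerate(layout.position_slices):
        codon = dna[3 * p : 3 * p + 3]
        for i in range(sl.start, sl.stop):
            if layout.variables[i].codon == codon:
                bits[i] = 1
                break
        else:
            raise ValueError(
                f"codon {codon} at position {p + 1} is not a synonymous codon of "
                f"{layout.peptide[p]!r}"
            )
    return bits
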