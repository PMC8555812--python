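"""Direct classical objective on nucleotide sequences.

This is the scoring function the genetic algorithm uses: it evaluates a
candidate DNA sequence without ever touching the quadratic model, yet is
mathematically equivalent to it — for every valid one-hot assignment the
model energy and this score agree to at least eight decimal places.  The
``-L * epsilon`` constant is kept in the total for exactly that
comparability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Seq import Seq

from .codon_tables import CodonUsageTable, GENETIC_CODE, Parameters, log_inverse_frequencies
from .hamiltonian import repeat_run_penalty

__all__ = ["ScoreBreakdown", "gc_fraction", "translate", "classical_score"]


@dataclass(frozen=True)
class ScoreBreakdown:
    """Additive decomposition of the classical objective."""

    usage_bias: float
    gc_term: float
    repeat_term: float
    epsilon_term: float

    @property
    def total(self) -> float:
        return self.usage_bias + self.gc_term + self.repeat_term + self.epsilon_term


def gc_fraction(dna: str) -> float:
    """Fraction of G and C bases in ``dna``."""
    dna = dna.upper()
    if not dna:
        raise ValueError("empty sequence")
    bad = set(dna) - set("ACGT")
    if bad:
        raise ValueError(f"invalid nucleotide letters: {sorted(bad)}")
    return (dna.count("G") + dna.count("C")) / len(dna)


def translate(dna: str) -> str:
    """Standard-genetic-code translation; stop codons are an error."""
    dna = dna.upper()
    if len(dna) % 3:
        raise ValueError(f"length {len(dna)} is not divisible by 3")
    bad = set(dna) - set("ACGT")
    if bad:
        raise ValueError(f"invalid nucleotide letters: {sorted(bad)}")
    peptide = str(Seq(dna).translate())
    if "*" in peptide:
        raise ValueError(f"stop codon at residue {peptide.index('*') + 1}")
    return peptide


def classical_score(
    dna: str,
    peptide: str,
    table: CodonUsageTable,
    params: Parameters | None = None,
) -> ScoreBreakdown:
    """Score a candidate DNA sequence for ``peptide`` directly.

    Components: ``c_f * sum sigma(codon_p)`` (usage bias),
    ``c_gc * (rho_GC - rho_t)^2`` (GC target),
    ``c_r * sum r(codon_p, codon_{p+1})`` over adjacent codons (repeats),
    and ``-L * epsilon`` (the per-residue selection reward of the model).
    """
    params = params or Parameters()
    dna = dna.upper()
    peptide = peptide.upper()
    if translate(dna) != peptide:
        raise ValueError("dna does not translate to the given peptide")

    sigma = log_inverse_frequencies(table, params.epsilon_f)
    codons = [dna[i : i + 3] for i in range(0, len(dna), 3)]
    usage = params.c_f * math.fsum(sigma[c] for c in codons)
    gc = params.c_gc * (gc_fraction(dna) - params.rho_t) ** 2
    repeat = params.c_r * math.fsum(
        repeat_run_penalty(a, b, params.repeat_mode) for a, b in zip(codons, codons[1:])
    )
    eps = -len(peptide) * params.epsilon
    return ScoreBreakdown(usage_bias=usage, gc_term=gc, repeat_term=repeat, epsilon_term=eps)
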