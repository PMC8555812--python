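"""Codon usage tables and the rare-codon penalty vector.

Codon optimization penalizes rare codons through the log-inverse of the
host's codon usage frequency: ``sigma(c) = -log(f_c + eps_f)``.  Common
codons (``f`` near 1) contribute almost nothing; codons the host rarely or
never uses carry a large positive penalty.  ``eps_f`` is a strictly positive
floor that keeps the logarithm finite for codons with zero recorded usage.

Frequencies follow the relative-usage convention: within each synonymous
family they sum to 1.  Tables given in other conventions (e.g. per-1000
counts) are renormalized per amino acid on load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "GENETIC_CODE",
    "SYNONYMOUS_CODONS",
    "CodonUsageTable",
    "Parameters",
    "load_codon_table",
    "log_inverse_frequencies",
]

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: codon -> amino acid under the standard genetic code; stop codons excluded
#: (only polypeptides are optimized, never translation termination).
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)

#: amino acid -> synonymous codons in canonical (lexicographic) order.
SYNONYMOUS_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in GENETIC_CODE.items() if a == aa))
    for aa in STANDARD_AMINO_ACIDS
}

_SUM_TOL = 1e-6

#: organisms with a usage table shipped inside the package
BUNDLED_TABLES = {"e_coli": "e_coli.tsv"}


@dataclass(frozen=True)
class Parameters:
    """Weights and constants of the codon-optimization objective.

    Attributes
    ----------
    c_f : float
        Weight of the codon-usage-bias term.
    c_gc : float
        Weight of the quadratic GC-content term.
    c_r : float
        Weight of the sequential-repeat penalty.
    epsilon : float
        Per-selected-codon one-body reward (subtracted from every linear
        coefficient) that makes selecting codons energetically favorable.
    rho_t : float
        Target GC fraction in [0, 1].
    epsilon_f : float
        Strictly positive frequency floor inside the log-inverse penalty.
    tau_value : float
        Finite stand-in for the "infinite" same-position penalty; must
        dominate every non-constraint coefficient of the model being built.
    repeat_mode : str
        ``"window"`` scores the longest single-nucleotide run anywhere in
        the 6-mer concatenation of two adjacent codons; ``"junction"``
        scores only runs crossing the codon boundary.
    """

    c_f: float = 0.1
    c_gc: float = 1.0
    c_r: float = 0.1
    epsilon: float = 1.0
    rho_t: float = 0.5
    epsilon_f: float = 1e-10
    tau_value: float = 50.0
    repeat_mode: str = "window"

    def __post_init__(self) -> None:
        for name in ("c_f", "c_gc", "c_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.epsilon_f <= 0:
            raise ValueError("epsilon_f must be strictly positive")
        if not 0.0 <= self.rho_t <= 1.0:
            raise ValueError("rho_t must lie in [0, 1]")
        if self.tau_value <= 0:
            raise ValueError("tau_value must be strictly positive")
        if self.repeat_mode not in ("window", "junction"):
            raise ValueError("repeat_mode must be 'window' or 'junction'")


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-amino-acid synonymous codons with relative usage frequencies.

    ``entries`` maps each amino-acid letter to ``((codon, frequency), ...)``
    where frequencies within a family sum to 1 (a zero frequency is allowed
    for codons a host effectively never uses).
    """

    organism: str
    entries: Mapping[str, tuple[tuple[str, float], ...]]

    def __post_init__(self) -> None:
        for aa, pairs in self.entries.items():
            if aa not in STANDARD_AMINO_ACIDS:
                raise ValueError(f"unknown amino acid letter {aa!r}")
            codons = [c for c, _ in pairs]
            if not 1 <= len(codons) <= 6:
                raise ValueError(f"{aa}: expected 1-6 synonymous codons, got {len(codons)}")
            if len(set(codons)) != len(codons):
                raise ValueError(f"{aa}: duplicate codons")
            for codon, freq in pairs:
                if GENETIC_CODE.get(codon) != aa:
                    raise ValueError(f"codon {codon} does not translate to {aa}")
                if not 0.0 <= freq <= 1.0:
                    raise ValueError(f"{aa}/{codon}: frequency {freq} outside [0, 1]")
            total = math.fsum(f for _, f in pairs)
            if abs(total - 1.0) > _SUM_TOL:
                raise ValueError(f"{aa}: frequencies sum to {total}, expected 1")

    # -- queries ---------------------------------------------------------

    def amino_acids(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def codons_for(self, amino_acid: str) -> tuple[str, ...]:
        try:
            return tuple(c for c, _ in self.entries[amino_acid])
        except KeyError:
            raise KeyError(f"amino acid {amino_acid!r} not in table") from None

    def frequency(self, codon: str) -> float:
        for pairs in self.entries.values():
            for c, f in pairs:
                if c == codon:
                    return f
        raise KeyError(f"codon {codon!r} not in table")

    def frequencies(self) -> dict[str, float]:
        """Flat codon -> frequency map over every codon in the table."""
        return {c: f for pairs in self.entries.values() for c, f in pairs}

    # -- construction / serialization ------------------------------------

    @classmethod
    def from_weights(
        cls, organism: str, weights: Mapping[str, Mapping[str, float]]
    ) -> "CodonUsageTable":
        """Build a table from raw non-negative weights, renormalizing each
        synonymous family to sum to 1 (zero weights stay zero)."""
        entries = {}
        for aa in sorted(weights):
            fam = weights[aa]
            total = math.fsum(fam.values())
            if total <= 0:
                raise ValueError(f"{aa}: family weights sum to {total}")
            entries[aa] = tuple(sorted((c, w / total) for c, w in fam.items()))
        return cls(organism=organism, entries=entries)

    @classmethod
    def from_file(cls, path: str | Path, organism: str | None = None) -> "CodonUsageTable":
        """Read a tab-separated ``amino_acid  codon  frequency`` file."""
        path = Path(path)
        weights: dict[str, dict[str, float]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
                aa, codon, raw = parts
                try:
                    freq = float(raw)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: bad frequency {raw!r}") from None
                if codon in weights.setdefault(aa, {}):
                    raise ValueError(f"{path}:{lineno}: duplicate codon {codon}")
                weights[aa][codon] = freq
        if not weights:
            raise ValueError(f"{path}: no codon entries found")
        return cls.from_weights(organism or path.stem, weights)

    def write(self, path: str | Path) -> None:
        """Write the table as tab-separated text with full-precision
        frequencies, so a reload reproduces it exactly."""
        lines = [f"# codon usage table: {self.organism}"]
        for aa in sorted(self.entries):
            for codon, freq in self.entries[aa]:
                lines.append(f"{aa}\t{codon}\t{freq!r}")
        Path(path).write_text("\n".join(lines) + "\n")


def load_codon_table(source: str | Path) -> CodonUsageTable:
    """Load a codon usage table by organism name or file path.

    ``source`` may name a bundled table (``"e_coli"``) or point to a
    tab-separated file in the same format.
    """
    if isinstance(source, str) and source in BUNDLED_TABLES:
        ref = resources.files("codonqubo.data") / BUNDLED_TABLES[source]
        with resources.as_file(ref) as p:
            return CodonUsageTable.from_file(p, organism=source)
    path = Path(source)
    if path.exists():
        return CodonUsageTable.from_file(path)
    raise ValueError(
        f"unknown organism or missing table file {source!r}; "
        f"bundled tables: {sorted(BUNDLED_TABLES)}"
    )


def log_inverse_frequencies(
    table: CodonUsageTable, epsilon_f: float = 1e-10
) -> dict[str, float]:
    """Rare-codon penalty vector: ``sigma(c) = -log(f_c + epsilon_f)``.

    Strictly decreasing in frequency, so rarer codons always cost more;
    finite even at zero frequency thanks to the ``epsilon_f`` floor.
    """
    if epsilon_f <= 0:
        raise ValueError("epsilon_f must be strictly positive")
    return {c: -math.log(f + epsilon_f) for c, f in table.frequencies().items()}
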