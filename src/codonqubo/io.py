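"""File formats: peptide FASTA input, QUBO export/import, result output.

All coefficient serialization uses Python's shortest round-trip ``repr``
for floats, so an exported model re-imported and evaluated on the same
bits gives bit-identical energies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from Bio import SeqIO

from .codon_tables import STANDARD_AMINO_ACIDS, Parameters
from .encoding import QubitLayout
from .hamiltonian import QuadraticModel
from .solvers import SolverResult

__all__ = [
    "RunConfig",
    "InvalidResultError",
    "read_peptides",
    "split_peptide",
    "export_qubo",
    "import_qubo",
    "write_result",
]


class InvalidResultError(ValueError):
    """Raised when asked to write a result whose assignment is not a valid
    one-hot state; carries the offending positions."""

    def __init__(self, violations: tuple[tuple[int, int], ...]):
        self.violations = violations
        detail = "; ".join(
            f"position {p}: {'no codon' if n == 0 else f'{n} codons'} selected"
            for p, n in violations
        )
        super().__init__(f"invalid one-hot assignment ({detail})")


@dataclass
class RunConfig:
    """Resolved configuration of one CLI run; round-trips through YAML."""

    parameters: Parameters
    solver: str = "exact"
    solver_options: dict | None = None
    table_source: str = "e_coli"
    input_path: str | None = None
    output_path: str | None = None
    log_level: str = "INFO"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["parameters"] = asdict(self.parameters)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["parameters"] = Parameters(**doc.get("parameters", {}))
        return cls(**doc)


def read_peptides(path: str | Path) -> list[tuple[str, str]]:
    """Read amino-acid FASTA records as ``(id, sequence)`` pairs in file order.

    Sequences are upper-cased; any letter outside the 20 standard amino
    acids is an error naming the record and 1-based offset.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for off, letter in enumerate(seq, start=1):
            if letter not in STANDARD_AMINO_ACIDS:
                raise ValueError(
                    f"record {rec.id!r}: invalid residue {letter!r} at position {off}"
                )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def split_peptide(peptide: str, fragment_length: int) -> list[str]:
    """Consecutive non-overlapping fragments; a shorter final remainder is kept."""
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    return [peptide[i : i + fragment_length] for i in range(0, len(peptide), fragment_length)]


def _legend(layout: QubitLayout) -> dict[str, dict]:
    # 1-based positions in user-facing output
    return {
        str(v.index): {"position": v.position + 1, "codon": v.codon}
        for v in layout.variables
    }


def export_qubo(model: QuadraticModel, path: str | Path, format: str = "coo") -> None:
    """Write the model's coefficients to disk.

    ``"coo"``: header lines ``# vars M`` and ``# offset <value>``, then one
    line per nonzero term ``i j value`` with ``i == j`` for one-body and
    ``i < j`` for two-body entries (0-based, fixed ordering).

    ``"json"``: the same content as one structured document, including the
    variable -> (position, codon) legend when the model carries a layout.
    """
    path = Path(path)
    if format == "coo":
        lines = [f"# vars {model.M}", f"# offset {float(model.offset)!r}"]
        for i, v in enumerate(model.h):
            if v != 0.0:
                lines.append(f"{i} {i} {float(v)!r}")
        for (i, j) in sorted(model.J):
            lines.append(f"{i} {j} {float(model.J[(i, j)])!r}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        doc = {
            "vars": model.M,
            "offset": model.offset,
            "linear": {str(i): float(v) for i, v in enumerate(model.h) if v != 0.0},
            "quadratic": [[i, j, model.J[(i, j)]] for (i, j) in sorted(model.J)],
        }
        if model.layout is not None:
            doc["peptide"] = model.layout.peptide
            doc["legend"] = _legend(model.layout)
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_qubo(path: str | Path) -> QuadraticModel:
    """Read a model written by :func:`export_qubo` (format auto-detected)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        doc = json.loads(text)
        h = np.zeros(doc["vars"])
        for i, v in doc["linear"].items():
            h[int(i)] = v
        J = {(int(i), int(j)): float(v) for i, j, v in doc["quadratic"]}
        return QuadraticModel(h=h, J=J, offset=float(doc["offset"]))

    n_vars = None
    offset = 0.0
    entries = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts[:1] == ["vars"]:
                n_vars = int(parts[1])
            elif parts[:1] == ["offset"]:
                offset = float(parts[1])
            continue
        i, j, v = line.split()
        entries.append((int(i), int(j), float(v)))
    if n_vars is None:
        raise ValueError(f"{path}: missing '# vars' header")
    h = np.zeros(n_vars)
    J: dict[tuple[int, int], float] = {}
    for i, j, v in entries:
        if i == j:
            h[i] = v
        else:
            J[(i, j)] = v
    return QuadraticModel(h=h, J=J, offset=offset)


def write_result(
    result: SolverResult,
    peptide_id: str,
    path: str | Path,
    layout: QubitLayout | None = None,
) -> None:
    """Write an optimized nucleotide sequence as FASTA.

    The header carries the solver name, the model energy to 10 decimals,
    and the seed.  Invalid assignments are refused with a diagnostic
    listing the violating positions (pass ``layout`` to recover them from
    the stored bits).
    """
    if not result.valid or result.dna is None:
        violations: tuple[tuple[int, int], ...] = ()
        if layout is not None:
            from .encoding import decode

            violations = decode(layout, result.bits).violations
        raise InvalidResultError(violations)
    header = (
        f">{peptide_id} solver={result.solver} "
        f"energy={result.energy:.10f} seed={result.seed}"
    )
    Path(path).write_text(f"{header}\n{result.dna}\n")
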