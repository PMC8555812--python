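"""Binary quadratic model of the codon-optimization objective.

The designed sequence is scored by a Hamiltonian over one-hot codon
variables ``q_i`` in {0, 1}:

    H = sum_i h_i q_i + sum_{i<j} J_ij q_i q_j + offset

with four physical contributions:

* usage bias  — ``c_f * sigma_i`` per selected codon, where ``sigma`` is
  the log-inverse usage frequency (rare codons cost more);
* GC content  — the quadratic ``c_gc * (rho_GC - rho_t)^2`` expanded into
  linear terms, pairwise cross terms over *all* variable pairs, and the
  constant ``c_gc * rho_t^2`` carried as the model offset;
* repeats     — ``c_r * r(a, b)`` between codons at adjacent positions,
  where ``r`` grows quadratically with the longest single-nucleotide run;
* validity    — a reward ``-epsilon`` per selected codon and a large
  penalty ``tau`` for every same-position pair, which together make the
  ground state a valid one-hot assignment.

On any valid assignment the model energy equals the direct classical score
of the decoded sequence (see :mod:`codonqubo.scoring`) to better than
eight decimal places; tests pin this equivalence.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .codon_tables import CodonUsageTable, Parameters, log_inverse_frequencies
from .encoding import QubitLayout, build_layout

__all__ = [
    "QuadraticModel",
    "usage_bias_terms",
    "gc_content_terms",
    "repeat_run_penalty",
    "repeat_terms",
    "constraint_terms",
    "assemble",
    "energy",
]


def _gc_count(codon: str) -> int:
    return codon.count("G") + codon.count("C")


@dataclass
class QuadraticModel:
    """Upper-triangular binary quadratic model: ``h``, sparse ``J``, constant offset.

    ``J`` keys are ordered pairs ``(i, j)`` with ``i < j``.  The model is
    treated as immutable after construction; ``layout`` (when present)
    records the variable -> (position, codon) meaning for decoding and
    export.
    """

    h: np.ndarray
    J: dict[tuple[int, int], float]
    offset: float = 0.0
    layout: QubitLayout | None = None
    _pairs: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if not np.all(np.isfinite(self.h)) or not np.isfinite(self.offset):
            raise ValueError("model coefficients must be finite")
        for (i, j), v in self.J.items():
            if not 0 <= i < j < self.M:
                raise ValueError(f"J key ({i}, {j}) is not upper-triangular in [0, {self.M})")
            if not np.isfinite(v):
                raise ValueError(f"J[{i}, {j}] is not finite")

    @property
    def M(self) -> int:
        return len(self.h)

    def _pair_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._pairs is None:
            if self.J:
                keys = sorted(self.J)
                ii = np.array([k[0] for k in keys], dtype=np.intp)
                jj = np.array([k[1] for k in keys], dtype=np.intp)
                vv = np.array([self.J[k] for k in keys], dtype=float)
            else:
                ii = jj = np.empty(0, dtype=np.intp)
                vv = np.empty(0, dtype=float)
            self._pairs = (ii, jj, vv)
        return self._pairs

    def energy(self, bits: Sequence[int] | np.ndarray) -> float:
        """Evaluate ``offset + h.b + sum J_ij b_i b_j`` in double precision."""
        b = np.asarray(bits, dtype=float)
        if b.shape != (self.M,):
            raise ValueError(f"bit vector length {b.shape} does not match M={self.M}")
        ii, jj, vv = self._pair_arrays()
        return float(self.offset + self.h @ b + vv @ (b[ii] * b[jj]))

    def energies(self, bit_matrix: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`energy` over rows of a (n, M) 0/1 matrix."""
        B = np.asarray(bit_matrix, dtype=float)
        ii, jj, vv = self._pair_arrays()
        return self.offset + B @ self.h + (B[:, ii] * B[:, jj]) @ vv


def usage_bias_terms(
    layout: QubitLayout, sigma: Mapping[str, float], c_f: float
) -> np.ndarray:
    """Linear usage-bias contribution ``c_f * sigma(codon_i)`` per variable."""
    try:
        return np.array([c_f * sigma[v.codon] for v in layout.variables])
    except KeyError as exc:
        raise KeyError(f"no log-inverse frequency for codon {exc.args[0]!r}") from None


def gc_content_terms(
    layout: QubitLayout, c_gc: float, rho_t: float
) -> tuple[np.ndarray, dict[tuple[int, int], float], float]:
    """GC-target quadratic expanded to BQM form.

    With ``s_i`` the G/C count of codon ``i`` (0-3) and ``N`` the
    nucleotide length 3L:

    * two-body, all pairs i<j:  ``2 c_gc / N^2 * s_i s_j``
    * one-body:                 ``c_gc / N^2 * s_i^2 - 2 rho_t c_gc / N * s_i``
    * offset:                   ``c_gc * rho_t^2``

    Because the expansion of the square is exact on binary variables, the
    summed contribution on any valid one-hot state equals
    ``c_gc * (rho_GC - rho_t)^2`` to machine precision.
    """
    n = layout.n_nt
    s = np.array([_gc_count(v.codon) for v in layout.variables], dtype=float)
    linear = c_gc / n**2 * s**2 - 2.0 * rho_t * c_gc / n * s
    quadratic: dict[tuple[int, int], float] = {}
    coupling = 2.0 * c_gc / n**2
    if coupling != 0.0:
        nz = np.nonzero(s)[0]
        for a, i in enumerate(nz):
            for j in nz[a + 1 :]:
                quadratic[(int(i), int(j))] = float(coupling * s[i] * s[j])
    return linear, quadratic, c_gc * rho_t**2


def repeat_run_penalty(codon_a: str, codon_b: str, mode: str = "window") -> int:
    """Penalty ``r = runlen^2 - 1`` for single-nucleotide runs across two
    adjacent codons.

    ``runlen`` is the longest run in the 6-mer ``a + b`` (mode
    ``"window"``) or the longest run crossing the a/b boundary (mode
    ``"junction"``).  A lone nucleotide is a run of 1, so ``r >= 0``; the
    function is asymmetric in its arguments in general.
    """
    for codon in (codon_a, codon_b):
        if len(codon) != 3 or any(b not in "ACGT" for b in codon):
            raise ValueError(f"malformed codon {codon!r}")
    if mode == "window":
        hexamer = codon_a + codon_b
        runlen = best = 1
        for prev, cur in zip(hexamer, hexamer[1:]):
            runlen = runlen + 1 if cur == prev else 1
            best = max(best, runlen)
    elif mode == "junction":
        if codon_a[-1] == codon_b[0]:
            suffix = 3 - len(codon_a.rstrip(codon_a[-1]))
            prefix = 3 - len(codon_b.lstrip(codon_b[0]))
            best = suffix + prefix
        else:
            best = 1
    else:
        raise ValueError("mode must be 'window' or 'junction'")
    return best**2 - 1


def repeat_terms(
    layout: QubitLayout, c_r: float, mode: str = "window"
) -> dict[tuple[int, int], float]:
    """Two-body repeat penalties ``c_r * r(codon_i, codon_j)`` restricted to
    variable pairs at sequentially adjacent peptide positions (the
    earlier-position codon is always the first argument of ``r``)."""
    quadratic: dict[tuple[int, int], float] = {}
    if c_r == 0:
        return quadratic
    slices = layout.position_slices
    for p in range(len(slices) - 1):
        for i in range(slices[p].start, slices[p].stop):
            for j in range(slices[p + 1].start, slices[p + 1].stop):
                r = repeat_run_penalty(
                    layout.variables[i].codon, layout.variables[j].codon, mode
                )
                if r:
                    quadratic[(i, j)] = c_r * r
    return quadratic


def constraint_terms(
    layout: QubitLayout, epsilon: float, tau_value: float
) -> tuple[np.ndarray, dict[tuple[int, int], float]]:
    """Validity terms: ``-epsilon`` on every variable, ``tau`` on every
    same-position pair.  On a valid one-hot state the pairwise part is 0
    and the linear part contributes ``-L * epsilon``."""
    if tau_value <= 0:
        raise ValueError("tau_value must be strictly positive")
    linear = np.full(layout.M, -epsilon, dtype=float)
    quadratic: dict[tuple[int, int], float] = {}
    for sl in layout.position_slices:
        for i in range(sl.start, sl.stop):
            for j in range(i + 1, sl.stop):
                quadratic[(i, j)] = tau_value
    return linear, quadratic


def assemble(
    peptide: str, table: CodonUsageTable, params: Parameters | None = None
) -> QuadraticModel:
    """Build the full model for ``peptide`` under ``table`` and ``params``.

    Deterministic for fixed inputs.  Emits a warning when ``tau_value``
    does not strictly dominate the largest non-constraint coefficient,
    since the one-hot barrier is then not guaranteed.
    """
    params = params or Parameters()
    layout = build_layout(peptide, table)
    sigma = log_inverse_frequencies(table, params.epsilon_f)

    h_f = usage_bias_terms(layout, sigma, params.c_f)
    h_gc, j_gc, offset = gc_content_terms(layout, params.c_gc, params.rho_t)
    j_r = repeat_terms(layout, params.c_r, params.repeat_mode)
    h_p, j_tau = constraint_terms(layout, params.epsilon, params.tau_value)

    h = h_f + h_gc + h_p
    J: dict[tuple[int, int], float] = defaultdict(float)
    for terms in (j_gc, j_r, j_tau):
        for key, value in terms.items():
            J[key] += value

    scale = max(
        float(np.max(np.abs(h_f + h_gc))) if layout.M else 0.0,
        max((abs(v) for v in j_gc.values()), default=0.0),
        max((abs(v) for v in j_r.values()), default=0.0),
    )
    if params.tau_value <= scale:
        warnings.warn(
            f"tau_value={params.tau_value} does not dominate the largest "
            f"non-constraint coefficient ({scale:.4g}); invalid assignments "
            "may beat valid ones",
            stacklevel=2,
        )
    return QuadraticModel(h=h, J=dict(J), offset=offset, layout=layout)


def energy(model: QuadraticModel, bits: Sequence[int] | np.ndarray) -> float:
    """Functional alias for :meth:`QuadraticModel.energy`."""
    return model.energy(bits)
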