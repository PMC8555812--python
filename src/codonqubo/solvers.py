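"""Minimizers for the codon-optimization model.

Three routes to the ground state:

* :func:`exact_ground_state` — exhaustive enumeration of valid one-hot
  states (the oracle; feasible up to ~10^6 states);
* :func:`genetic_algorithm` — population search over valid codon
  assignments via synonymous point mutations, scored by the classical
  objective (the classical baseline);
* :func:`simulated_annealing` — single-bit-flip Metropolis chains over
  the full 2^M space with geometric cooling (a desk-scale classical
  analogue of an annealer; unlike the GA it can, in principle, return an
  invalid assignment, which is flagged rather than repaired).

All solvers are deterministic for a fixed seed, and no solver can beat
the exact enumerator on enumerable instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .codon_tables import CodonUsageTable, Parameters, log_inverse_frequencies
from .encoding import QubitLayout, build_layout, decode, encode
from .hamiltonian import QuadraticModel, assemble, repeat_run_penalty

__all__ = [
    "SolverResult",
    "GAConfig",
    "TrialSummary",
    "exact_ground_state",
    "genetic_algorithm",
    "simulated_annealing",
    "run_trials",
]


@dataclass(frozen=True)
class SolverResult:
    """Outcome of one optimization run.

    ``energy`` is always the quadratic-model energy of ``bits`` as
    evaluated by the hamiltonian module; ``dna`` is the decoded sequence
    when the assignment is a valid one-hot state, else ``None``.
    """

    bits: np.ndarray
    energy: float
    dna: str | None
    valid: bool
    solver: str
    trials: int
    seed: int | None = None


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    ``generations=None`` resolves by peptide length: 100 generations for
    peptides of at most 20 residues, 6000 for longer inputs.  Each
    generation procreates ``offspring_per_generation`` times by mutating a
    uniformly chosen parent at one random position (or, when
    ``mutation_rate`` is set, at each position independently with that
    probability); the best ``elitism`` individuals always survive.
    """

    generations: int | None = None
    offspring_per_generation: int = 50
    population_size: int = 50
    mutation_rate: float | None = None
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations is not None and self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.offspring_per_generation < 1:
            raise ValueError("offspring_per_generation must be >= 1")
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.elitism < 0 or self.elitism > self.population_size:
            raise ValueError("elitism must lie in [0, population_size]")

    def resolve_generations(self, peptide_length: int) -> int:
        if self.generations is not None:
            return self.generations
        return 100 if peptide_length <= 20 else 6000


@dataclass(frozen=True)
class TrialSummary:
    """Energies from repeated seeded runs with summary statistics."""

    results: tuple[SolverResult, ...]
    min_energy: float
    mean_energy: float
    std_energy: float


# ---------------------------------------------------------------------------
# shared per-position tables for the valid-state objective
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _ChainTables:
    """Classical objective restricted to valid states, decomposed per
    position: linear part, G/C counts, and adjacent-pair repeat matrices.
    The GC term stays global: c_gc * (sum(s)/N - rho_t)^2."""

    layout: QubitLayout
    linear: tuple[np.ndarray, ...]
    gc_counts: tuple[np.ndarray, ...]
    repeat: tuple[np.ndarray, ...]
    c_gc: float
    rho_t: float

    def score(self, choice: Sequence[int]) -> float:
        e = 0.0
        s = 0.0
        for p, k in enumerate(choice):
            e += self.linear[p][k]
            s += self.gc_counts[p][k]
            if p:
                e += self.repeat[p - 1][choice[p - 1], k]
        rho = s / self.layout.n_nt
        return e + self.c_gc * (rho - self.rho_t) ** 2

    def score_population(self, choices: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`score` over rows of an (n, L) index matrix."""
        n, L = choices.shape
        e = np.zeros(n)
        s = np.zeros(n)
        for p in range(L):
            e += self.linear[p][choices[:, p]]
            s += self.gc_counts[p][choices[:, p]]
            if p:
                e += self.repeat[p - 1][choices[:, p - 1], choices[:, p]]
        return e + self.c_gc * (s / self.layout.n_nt - self.rho_t) ** 2


def _chain_tables(
    layout: QubitLayout, table: CodonUsageTable, params: Parameters
) -> _ChainTables:
    sigma = log_inverse_frequencies(table, params.epsilon_f)
    linear, gc_counts, repeat = [], [], []
    per_pos = [layout.codons_at(p) for p in range(len(layout.peptide))]
    for codons in per_pos:
        linear.append(
            np.array([params.c_f * sigma[c] - params.epsilon for c in codons])
        )
        gc_counts.append(np.array([c.count("G") + c.count("C") for c in codons], dtype=float))
    for a, b in zip(per_pos, per_pos[1:]):
        repeat.append(
            np.array(
                [
                    [params.c_r * repeat_run_penalty(ca, cb, params.repeat_mode) for cb in b]
                    for ca in a
                ]
            )
        )
    return _ChainTables(
        layout=layout,
        linear=tuple(linear),
        gc_counts=tuple(gc_counts),
        repeat=tuple(repeat),
        c_gc=params.c_gc,
        rho_t=params.rho_t,
    )


def _choice_to_bits(layout: QubitLayout, choice: Sequence[int]) -> np.ndarray:
    bits = np.zeros(layout.M, dtype=np.int8)
    for sl, k in zip(layout.position_slices, choice):
        bits[sl.start + int(k)] = 1
    return bits


def _result_from_bits(
    model: QuadraticModel, bits: np.ndarray, solver: str, trials: int, seed: int | None
) -> SolverResult:
    assert model.layout is not None
    dec = decode(model.layout, bits)
    return SolverResult(
        bits=bits,
        energy=model.energy(bits),
        dna=dec.dna,
        valid=dec.valid,
        solver=solver,
        trials=trials,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# exact enumeration
# ---------------------------------------------------------------------------


def exact_ground_state(
    peptide: str,
    table: CodonUsageTable,
    params: Parameters | None = None,
    state_cap: int = 10**6,
) -> SolverResult:
    """Enumerate every valid one-hot state and return the minimum-energy one.

    Ties break to the first state in canonical enumeration order (positions
    left to right, codons lexicographic).  The state space is the product of
    per-position codon counts and must not exceed ``state_cap``.
    """
    params = params or Parameters()
    model = assemble(peptide, table, params)
    layout = model.layout
    assert layout is not None
    counts = [sl.stop - sl.start for sl in layout.position_slices]
    n_states = math.prod(counts)
    if n_states > state_cap:
        raise ValueError(f"{n_states} valid states exceed cap {state_cap}")

    tables = _chain_tables(layout, table, params)
    # accumulate energies over positions; after appending position p the
    # flat state index is i_prev * counts[p] + k, so the previous codon
    # index is recoverable as (index // 1) % counts[p-1] of the prior stage.
    e = np.zeros(1)
    s = np.zeros(1)
    for p, nk in enumerate(counts):
        contrib = tables.linear[p][None, :]
        if p:
            last = np.arange(e.size) % counts[p - 1]
            contrib = contrib + tables.repeat[p - 1][last, :]
        e = (e[:, None] + contrib).ravel()
        s = (s[:, None] + tables.gc_counts[p][None, :]).ravel()
    e += params.c_gc * (s / layout.n_nt - params.rho_t) ** 2

    best = int(np.argmin(e))
    choice = []
    idx = best
    for nk in reversed(counts):
        choice.append(idx % nk)
        idx //= nk
    choice.reverse()
    bits = _choice_to_bits(layout, choice)
    return _result_from_bits(model, bits, solver="exact", trials=n_states, seed=None)


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------


def genetic_algorithm(
    peptide: str,
    table: CodonUsageTable,
    params: Parameters | None = None,
    config: GAConfig | None = None,
    return_trace: bool = False,
) -> SolverResult | tuple[SolverResult, np.ndarray]:
    """Evolve valid codon assignments by synonymous point mutations.

    The search never leaves the valid one-hot subspace, so the constraint
    penalties never fire; scoring is the direct classical objective, and
    the returned energy is re-evaluated through the quadratic model.  With
    ``return_trace`` the per-generation best-so-far energies (a
    non-increasing series) are returned alongside the result.
    """
    params = params or Parameters()
    config = config or GAConfig()
    model = assemble(peptide, table, params)
    layout = model.layout
    assert layout is not None
    rng = np.random.default_rng(config.seed)
    tables = _chain_tables(layout, table, params)
    counts = np.array([sl.stop - sl.start for sl in layout.position_slices])
    L = len(counts)
    generations = config.resolve_generations(L)

    pop = rng.integers(0, counts, size=(config.population_size, L))
    scores = tables.score_population(pop)
    order = np.argsort(scores, kind="stable")
    pop, scores = pop[order], scores[order]
    trace = [scores[0]]

    for _ in range(generations):
        parents = pop[rng.integers(0, len(pop), size=config.offspring_per_generation)]
        children = parents.copy()
        if config.mutation_rate is None:
            pos = rng.integers(0, L, size=len(children))
            children[np.arange(len(children)), pos] = rng.integers(0, counts[pos])
        else:
            mask = rng.random(children.shape) < config.mutation_rate
            resampled = rng.integers(0, counts, size=children.shape)
            children[mask] = resampled[mask]
        child_scores = tables.score_population(children)
        elite_n = config.elitism
        merged = np.vstack([pop[:elite_n], children])
        merged_scores = np.concatenate([scores[:elite_n], child_scores])
        order = np.argsort(merged_scores, kind="stable")[: config.population_size]
        pop, scores = merged[order], merged_scores[order]
        trace.append(scores[0])

    bits = _choice_to_bits(layout, pop[0])
    result = _result_from_bits(
        model, bits, solver="ga", trials=generations, seed=config.seed
    )
    if return_trace:
        return result, np.array(trace)
    return result


# ---------------------------------------------------------------------------
# simulated annealing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule.  Temperatures default to the model's
    coefficient scale (max |h| + max |J|) down to 1e-3 of it."""

    n_sweeps: int = 1000
    t_start: float | None = None
    t_end_fraction: float = 1e-3


def simulated_annealing(
    model: QuadraticModel,
    n_reads: int = 10,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
) -> SolverResult:
    """Single-bit-flip Metropolis annealing over the full 2^M space.

    Runs ``n_reads`` independent chains from uniform random starts and
    returns the lowest-energy read; the result is flagged invalid when the
    best read violates one-hot decoding.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    M = model.M

    W = np.zeros((M, M))
    for (i, j), v in model.J.items():
        W[i, j] += v
        W[j, i] += v
    scale = float(np.max(np.abs(model.h)) if M else 1.0) + (
        max((abs(v) for v in model.J.values()), default=0.0)
    )
    t0 = schedule.t_start if schedule.t_start is not None else max(scale, 1e-12)
    temps = t0 * (schedule.t_end_fraction ** (np.arange(schedule.n_sweeps) / max(schedule.n_sweeps - 1, 1)))

    best_bits: np.ndarray | None = None
    best_energy = np.inf
    for _ in range(n_reads):
        b = rng.integers(0, 2, size=M).astype(np.int8)
        local = model.h + W @ b  # local field: dE of setting bit i, given others
        for t in temps:
            flips = rng.integers(0, M, size=M)
            logu = np.log(rng.random(M))
            for i, lu in zip(flips, logu):
                delta = local[i] if b[i] == 0 else -local[i]
                if delta <= 0 or lu < -delta / t:
                    if b[i] == 0:
                        b[i] = 1
                        local += W[i]
                    else:
                        b[i] = 0
                        local -= W[i]
        e = model.energy(b)
        if e < best_energy:
            best_energy = e
            best_bits = b.copy()
    assert best_bits is not None
    return _result_from_bits(model, best_bits, solver="sa", trials=n_reads, seed=seed)


# ---------------------------------------------------------------------------
# repeated trials
# ---------------------------------------------------------------------------


def run_trials(
    solver: str,
    peptide: str,
    table: CodonUsageTable,
    params: Parameters | None = None,
    n_trials: int = 20,
    seed: int = 0,
    **solver_kwargs,
) -> TrialSummary:
    """Run a named solver ``n_trials`` times with per-trial seeds derived
    from ``seed`` and summarize the energies (min, mean, population sd)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = params or Parameters()
    results = []
    for t in range(n_trials):
        trial_seed = seed + t
        if solver == "exact":
            results.append(exact_ground_state(peptide, table, params, **solver_kwargs))
        elif solver == "ga":
            cfg = solver_kwargs.get("config") or GAConfig()
            cfg = GAConfig(
                generations=cfg.generations,
                offspring_per_generation=cfg.offspring_per_generation,
                population_size=cfg.population_size,
                mutation_rate=cfg.mutation_rate,
                elitism=cfg.elitism,
                seed=trial_seed,
            )
            results.append(genetic_algorithm(peptide, table, params, cfg))
        elif solver == "sa":
            model = assemble(peptide, table, params)
            results.append(
                simulated_annealing(
                    model,
                    n_reads=solver_kwargs.get("n_reads", 10),
                    schedule=solver_kwargs.get("schedule"),
                    seed=trial_seed,
                )
            )
        else:
            raise ValueError(f"unknown solver {solver!r}")
    energies = np.array([r.energy for r in results])
    return TrialSummary(
        results=tuple(results),
        min_energy=float(energies.min()),
        mean_energy=float(energies.mean()),
        std_energy=float(energies.std()),
    )
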