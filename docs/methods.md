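# Methods

## Problem and model

Codon optimization selects one synonymous codon per residue of a fixed
polypeptide to optimize heuristic expression proxies. `codonqubo`
formulates it as a binary quadratic model (QUBO) over a *one-hot*
encoding: each candidate codon at each position is a binary variable
`q_i`, and a bit vector is valid when exactly one variable per position is
set. The Hamiltonian is the sum of four contributions.

**Usage bias.** Each selected codon pays `c_f * sigma_i` with
`sigma_i = -log(f_i + eps_f)`, where `f_i` is the host's relative usage of
that codon within its synonymous family. The negative log makes the
penalty strictly decreasing in frequency: near zero for dominant codons,
large for rare ones. `eps_f` (default `1e-10`, configurable) keeps the
penalty finite for codons with zero recorded usage — small enough not to
perturb any realistic frequency (the smallest bundled frequency is 0.02),
large enough to avoid `log(0)`. Natural log is used; only relative
rankings are observable, so the base is a pure convention.

**GC content.** The target is the quadratic distance
`c_gc * (rho_GC - rho_t)^2` with `rho_GC` the G+C fraction of the decoded
sequence. Writing `rho_GC = sum_i s_i q_i / N` with `s_i` the G/C count of
codon `i` and `N = 3L` nucleotides, the square expands exactly over binary
variables (`q_i^2 = q_i`) into a linear part
`c_gc/N^2 * s_i^2 - 2 rho_t c_gc/N * s_i`, pairwise couplings
`2 c_gc/N^2 * s_i s_j` over **all** variable pairs (same-position pairs
included — they vanish on valid states and are dominated by the validity
penalty on invalid ones), and a constant `c_gc * rho_t^2` carried as the
model offset. Because the expansion is an algebraic identity, the summed
terms reproduce the closed form to ~1e-16 on every valid state; the test
suite pins 1e-12. Carrying the offset in the model (rather than dropping
the constant) keeps reported energies directly comparable with the
classical score.

Note on the two uses of "N": sums over variables range over all `M`
candidate codons; the GC normalizer is the nucleotide length `3L`. Only
this reading makes `rho_GC` a fraction in [0, 1] on valid states.

**Sequential repeats.** For codons at adjacent positions,
`r(a, b) = runlen^2 - 1` where `runlen` is the longest single-nucleotide
run. Two definitions are exposed via `repeat_mode`: `"window"` (default)
takes the longest run anywhere in the 6-mer `a + b`; `"junction"` takes
only runs crossing the codon boundary. Both reproduce the three pinned
examples `r(ATA,TCG)=0`, `r(ATA,ACG)=3`, `r(CGG,GGG)=24`; they differ on
pairs like `(GGC, GGC)` (3 vs 0), which is pinned in tests. `window` is
the default because it also penalizes within-codon runs, serving the goal
of minimizing repeated nucleotides more completely. `r` is asymmetric in
general (`r(ATA,ACG)=3` but `r(ACG,ATA)=0`), so couplings always use the
(earlier-position, later-position) order. Non-adjacent positions carry no
repeat coupling, so this term alone needs no full connectivity.

**Validity constraints.** A reward `-epsilon` on every variable makes
selecting codons favorable; a penalty `tau` (default 50) on every
same-position pair forbids double selection. `tau` must strictly dominate
the largest non-constraint coefficient — `assemble` warns when it does
not. Its exact magnitude is otherwise non-critical because results are
always validity-checked by decoding; a brute-force test over all `2^M`
bit vectors (M <= 16) confirms the global minimum is a valid one-hot
state under the defaults.

Default constants: `c_f = 0.1`, `c_gc = 1`, `c_r = 0.1`, `epsilon = 1`,
`rho_t = 0.5`, `tau = 50`. Variables are ordered by position then
lexicographically by codon, positions are 0-based internally and 1-based
in all user-facing output, and codons use the DNA alphabet {A,C,G,T}.

## Equivalent classical score

The genetic algorithm never touches the quadratic model: it scores DNA
sequences directly as
`c_f * sum sigma + c_gc * (rho_GC - rho_t)^2 + c_r * sum r - L * epsilon`.
The `-L * epsilon` constant is deliberately kept so GA scores and model
energies are directly comparable. Equivalence of the two routes on every
valid assignment (not just optima) is the package's central invariant,
asserted to 1e-8 over thousands of randomized draws and reported by
`scripts/acceptance.py` (typically 13–14 agreeing decimal places; the
residual is double-precision summation-order noise).

## Solvers

*Exact enumeration* walks the Cartesian product of per-position codon sets
(capped at 1e6 states, the practical desk-scale limit), accumulating the
valid-state objective position by position with vectorized arrays, and
re-evaluates the winner through the quadratic model so the reported energy
is bit-identical to `energy(model, bits)`. Ties break to the first state
in canonical enumeration order. It is the oracle every other solver is
tested against.

*Genetic algorithm*: population 50, offspring 50 per generation, each
offspring a copy of a uniformly chosen parent with one position's codon
resampled uniformly from its synonymous set; survivor selection keeps the
best `population_size` of {elite, offspring} with elitism 1, so the
best-so-far energy is non-increasing. Generations default to 100 for
peptides of <= 20 residues and 6000 for longer inputs (the intermediate
21–100 range is assigned the large-input setting, the conservative
choice). Mutations preserve translation, so the GA searches only valid
sequences and the constraint terms never fire; an optional per-position
`mutation_rate` switches to independent per-site mutation. All choices
are config-exposed; the defaults are the minimal faithful reading of a
"basic" GA.

*Simulated annealing*: independent single-bit-flip Metropolis chains over
the full `2^M` space with geometric cooling from the coefficient scale
(max |h| + max |J|) down to 1e-3 of it over 1000 sweeps of M proposals
each. Initialization is uniform random over all bit vectors, so unlike
the GA it can in principle return an invalid assignment, which is flagged
rather than repaired. A practical caveat measured on enumerable 20-mers:
because moving between valid states requires two flips through an
~epsilon barrier, individual reads freeze into near-degenerate valid
local optima and recover the exact ground state only a few percent of the
time; reliable ground-state recovery needs on the order of 100 reads
(e.g. several seeded runs of `n_reads = 20`), which is how the tests
assert it. This mirrors the known behavior of annealing hardware on
one-hot codon models, where repeated reads are likewise essential.

All solvers are bitwise reproducible for fixed seeds, and no solver can
return an energy below the exact enumerator's on enumerable instances.
`run_trials` wraps repeated seeded runs and reports min/mean/sd
(population sd, so a single trial reports 0).

## Synthetic data and what tests show

The fixture generator draws peptides uniformly over the 20 standard
residues (or over {L, R, S}, the six-codon residues, for worst-case
sizing), seeded and purely functional. Real proteins have biased residue
composition, local structure and length distributions that uniform draws
do not emulate; this does not matter for the properties tested here —
encoding bijections, algebraic equivalence of the two scoring routes,
constraint dominance, optimizer correctness — because all are
composition-independent claims. No claim is made about biological
expression outcomes of the optimized sequences. The bundled *E. coli*
table carries widely published K-12 relative-usage values; absolute
energies depend on the table version, so all tests are table-internal
(equivalence and monotonicity) rather than pinned to absolute usage-bias
values. The `adversarial_table` fixture is a synthetic table with a
zero-frequency leucine codon for exercising the `eps_f` floor.

Problem sizes used throughout the suite and the acceptance script — 20
peptides of length 20 for the equivalence check, 4-residue peptides for
GA recovery, up to 16 variables for the brute-force dominance scan, up to
~5e4 enumerated states for solver cross-checks — are desk-scale choices
that keep every check exhaustive or near-exhaustive while running in
seconds.

## Numerical choices and limitations

- All energies are evaluated in double precision; coefficient
  serialization uses shortest round-trip decimal representation, so
  export → import reproduces energies bit-exactly.
- Degenerate inputs are rejected with diagnostics: empty peptides,
  residues missing from a table, non-positive `eps_f`, malformed codons,
  bit vectors of the wrong length. Decoding an invalid assignment is not
  an error — it returns the offending positions (1-based), since solvers
  must be able to report invalid reads.
- Fragmenting utility: consecutive non-overlapping windows with the
  remainder kept, e.g. a 1255-residue input at fragment length 20 gives
  62 full fragments plus one of 15.
- Not modeled: mRNA secondary structure, codon-pair bias, tRNA adaptation
  indices, hardware embedding (chain strength, physical-qubit graphs) and
  any solver-side rescaling of `tau` into device field ranges. The QUBO
  export exists precisely so external hardware adapters can consume the
  model.
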