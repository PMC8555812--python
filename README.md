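# codonqubo

Codon optimization as a binary quadratic model (BQM/QUBO).

Reverse-translating a polypeptide means choosing one synonymous codon per
residue — up to six choices per position — to maximize a heuristic
expression score in a host such as *E. coli*. `codonqubo` casts this
combinatorial design problem as minimization of a quadratic Hamiltonian
over one-hot binary codon variables, the formulation used by quantum
annealers and gate-based QUBO solvers, and solves it on an ordinary CPU
with exact enumeration, simulated annealing, or a genetic algorithm. It is
aimed at sequence-design practitioners and at people studying how codon
optimization maps onto quadratic binary optimization.

## The model

Every candidate codon at every position gets a binary variable
$q_i \in \{0,1\}$. The energy of an assignment is

$$H \;=\; \sum_i h_i q_i \;+\; \sum_{i<j} J_{ij}\, q_i q_j \;+\; c_{GC}\rho_T^2,$$

with

$$h_i = c_f\,\varsigma_i \;-\; \frac{2\rho_T c_{GC}}{N}s_i \;+\; \frac{c_{GC}}{N^2}s_i^2 \;-\; \varepsilon,
\qquad
J_{ij} = \frac{2 c_{GC}}{N^2}s_i s_j \;+\; c_R R_{ij} \;+\; \tau_{ij},$$

where $\varsigma_i = -\log(f_i + \varepsilon_f)$ penalizes rare codons,
$s_i$ counts G/C bases in codon $i$ (0–3), $N = 3L$ is the nucleotide
length, $R_{ij} = r(C_i, C_j)$ penalizes single-nucleotide runs between
sequentially adjacent codons with $r = \mathrm{runlen}^2 - 1$, and the
validity terms ($-\varepsilon$ per variable, $\tau = 50$ on same-position
pairs) make the ground state a valid one-hot selection. On every valid
assignment the model energy equals the direct classical score

$$c_f \sum_p \varsigma(C_p) \;+\; c_{GC}(\rho_{GC} - \rho_T)^2 \;+\; c_R \sum_p r(C_p, C_{p+1}) \;-\; L\varepsilon$$

to better than eight decimal places — the cross-check that validates the
quadratic expansion. Default constants: $c_f = 0.1$, $c_{GC} = 1$,
$c_R = 0.1$, $\varepsilon = 1$, $\rho_T = 0.5$.

## Worked example

```python
>>> import codonqubo as cq
>>> table = cq.load_codon_table("e_coli")
>>> layout = cq.build_layout("LLLL", table)       # four leucines
>>> layout.M, cq.count_valid_states(layout)
(24, 1296)
>>> result = cq.exact_ground_state("LLLL", table)
>>> result.dna, round(result.energy, 6)
('CTGCTGCTGCTG', -3.694963)
>>> cq.classical_score(result.dna, "LLLL", table).total
-3.6949633500782437
```

Four six-codon residues need 24 binary variables spanning
6^4 = 1296 valid one-hot states. Exact enumeration selects `CTG` (the
most-used *E. coli* leucine codon) at every position; the model energy and
the direct classical score of the decoded sequence agree to machine
precision. The energy is negative because each selected codon earns the
$-\varepsilon$ validity reward ($-4$ total here) against small usage-bias,
GC and repeat penalties.

The same run from the shell:

```sh
$ codonqubo optimize LLLL --solver exact
peptide	CTGCTGCTGCTG	-3.6949633501	exact
$ codonqubo score CTGCTGCTGCTG LLLL
usage_bias	0.2772588721
gc_term	0.0277777778
repeat_term	0.0000000000
epsilon_term	-4.0000000000
total	-3.6949633501
```

Other subcommands: `build-qubo` (export the model as plain-text "coo" or
JSON coefficients for external solvers), `split` (fragment long peptides),
`trials` (repeat a stochastic solver and summarize min/mean/sd).

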