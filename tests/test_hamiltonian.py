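import itertools
import math

import numpy as np
import pytest

from codonqubo.codon_tables import Parameters, log_inverse_frequencies
from codonqubo.encoding import build_layout, decode
from codonqubo.fixtures import FixtureSpec, random_peptide, random_valid_bits
from codonqubo.hamiltonian import (
    QuadraticModel,
    assemble,
    constraint_terms,
    energy,
    gc_content_terms,
    repeat_run_penalty,
    repeat_terms,
    usage_bias_terms,
)
from codonqubo.scoring import gc_fraction


def dense_energy(model, bits):
    """Independent dense-matrix evaluation: b @ Q @ b with h on the diagonal."""
    b = np.asarray(bits, dtype=float)
    Q = np.diag(model.h.copy())
    for (i, j), v in model.J.items():
        Q[i, j] = v
    return float(b @ Q @ b + model.offset)


class TestUsageBias:
    def test_zero_weight_gives_zero_contributions(self, ecoli):
        layout = build_layout("GSK", ecoli)
        sigma = log_inverse_frequencies(ecoli)
        assert np.all(usage_bias_terms(layout, sigma, 0.0) == 0.0)

    def test_uniform_leucine_contribution_is_weighted_log_six(self, uniform):
        layout = build_layout("L", uniform)
        sigma = log_inverse_frequencies(uniform, epsilon_f=1e-10)
        contrib = usage_bias_terms(layout, sigma, 0.1)
        assert contrib == pytest.approx(0.1 * math.log(6), abs=1e-6)

    def test_missing_sigma_entry_is_an_error(self, ecoli):
        layout = build_layout("M", ecoli)
        with pytest.raises(KeyError, match="ATG"):
            usage_bias_terms(layout, {}, 0.1)


class TestGCContent:
    def test_single_met_terms_match_hand_expansion(self, ecoli):
        # ATG has one G/C, N = 3: linear = 1/9 - 2*0.5/3, offset = 0.25,
        # and the selected-state total is (1/3 - 1/2)^2 = 1/36.
        layout = build_layout("M", ecoli)
        linear, quad, offset = gc_content_terms(layout, c_gc=1.0, rho_t=0.5)
        assert linear[0] == pytest.approx(1 / 9 - 1 / 3)
        assert quad == {}
        assert offset == pytest.approx(0.25)
        assert linear[0] + offset == pytest.approx(1 / 36)

    def test_gc_free_selection_costs_quarter_at_half_target(self, uniform):
        # peptide KK can be encoded AAA AAA: rho_GC = 0 so the quadratic
        # distance to target 0.5 is 0.25.
        layout = build_layout("KK", uniform)
        linear, quad, offset = gc_content_terms(layout, c_gc=1.0, rho_t=0.5)
        bits = np.zeros(layout.M, dtype=int)
        for p, sl in enumerate(layout.position_slices):
            bits[sl.start + list(layout.codons_at(p)).index("AAA")] = 1
        total = offset + linear @ bits + sum(
            v * bits[i] * bits[j] for (i, j), v in quad.items()
        )
        assert total == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_on_valid_states(self, ecoli, seed):
        """Summed GC terms on any valid one-hot state equal
        c_gc * (rho_GC - rho_t)^2 to 1e-12."""
        peptide = random_peptide(FixtureSpec(seed=seed, peptide_length=12))
        layout = build_layout(peptide, ecoli)
        linear, quad, offset = gc_content_terms(layout, c_gc=1.0, rho_t=0.5)
        bits = random_valid_bits(layout, seed=seed)
        total = offset + linear @ bits + sum(
            v * bits[i] * bits[j] for (i, j), v in quad.items()
        )
        rho = gc_fraction(decode(layout, bits).dna)
        assert total == pytest.approx((rho - 0.5) ** 2, abs=1e-12)


class TestRepeatRunPenalty:
    @pytest.mark.parametrize(
        "a, b, window, junction",
        [
            ("ATA", "TCG", 0, 0),
            ("ATA", "ACG", 3, 3),
            ("CGG", "GGG", 24, 24),
            ("AAA", "AAA", 35, 35),
            ("GGC", "GGC", 3, 0),  # within-codon run vs no boundary run
            ("ACG", "ATA", 0, 0),  # reverse of (ATA, ACG): asymmetric
        ],
    )
    def test_published_and_discriminating_pairs(self, a, b, window, junction):
        assert repeat_run_penalty(a, b, "window") == window
        assert repeat_run_penalty(a, b, "junction") == junction

    def test_always_non_negative(self):
        from codonqubo.codon_tables import GENETIC_CODE

        codons = list(GENETIC_CODE)[:16]
        for a, b in itertools.product(codons, repeat=2):
            for mode in ("window", "junction"):
                assert repeat_run_penalty(a, b, mode) >= 0

    def test_malformed_codon_is_an_error(self):
        with pytest.raises(ValueError, match="malformed"):
            repeat_run_penalty("AT", "TCG")
        with pytest.raises(ValueError, match="malformed"):
            repeat_run_penalty("ATA", "TCU")


class TestRepeatTerms:
    def test_single_position_has_no_pairs(self, ecoli):
        assert repeat_terms(build_layout("L", ecoli), 0.1) == {}

    def test_zero_weight_gives_empty_map(self, ecoli):
        assert repeat_terms(build_layout("GG", ecoli), 0.0) == {}

    def test_glycine_pair_run_of_six(self, ecoli):
        layout = build_layout("GG", ecoli)
        terms = repeat_terms(layout, 0.1, "window")
        idx = {v.codon: v.index for v in layout.variables if v.position == 0}
        jdx = {v.codon: v.index for v in layout.variables if v.position == 1}
        assert terms[(idx["GGG"], jdx["GGG"])] == pytest.approx(3.5)

    def test_only_sequentially_adjacent_pairs_present(self, ecoli):
        layout = build_layout("GSG", ecoli)
        terms = repeat_terms(layout, 0.1)
        for i, j in terms:
            assert layout.variables[j].position == layout.variables[i].position + 1


class TestConstraintTerms:
    def test_linear_reward_and_same_position_penalties(self, ecoli):
        layout = build_layout("GK", ecoli)
        linear, quad = constraint_terms(layout, epsilon=1.0, tau_value=50.0)
        assert np.all(linear == -1.0)
        same_pos_pairs = {
            (i, j)
            for sl in layout.position_slices
            for i in range(sl.start, sl.stop)
            for j in range(i + 1, sl.stop)
        }
        assert set(quad) == same_pos_pairs
        assert all(v == 50.0 for v in quad.values())

    def test_valid_state_pays_no_tau_and_minus_l_epsilon(self, ecoli):
        layout = build_layout("GSK", ecoli)
        linear, quad = constraint_terms(layout, epsilon=1.0, tau_value=50.0)
        bits = random_valid_bits(layout, seed=0)
        pair_cost = sum(v * bits[i] * bits[j] for (i, j), v in quad.items())
        assert pair_cost == 0.0
        assert linear @ bits == pytest.approx(-3.0)


class TestAssembleAndEnergy:
    def test_constraint_only_model(self, ecoli):
        params = Parameters(c_f=0.0, c_gc=0.0, c_r=0.0, epsilon=1.0)
        model = assemble("GSK", ecoli, params)
        assert np.all(model.h == -1.0)
        assert model.offset == 0.0
        assert all(v == params.tau_value for v in model.J.values())

    def test_single_met_ground_energy(self, ecoli, defaults):
        model = assemble("M", ecoli, defaults)
        expected = 0.1 * -math.log(1 + 1e-10) + (1 / 3 - 1 / 2) ** 2 - 1.0
        assert model.energy([1]) == pytest.approx(expected, abs=1e-10)
        assert model.energy([1]) == pytest.approx(-0.97222, abs=1e-5)

    def test_all_zero_bits_energy_is_offset(self, ecoli, defaults):
        model = assemble("GSK", ecoli, defaults)
        assert model.energy(np.zeros(model.M)) == model.offset == 0.25

    def test_energy_matches_dense_oracle_on_random_bits(self, ecoli, defaults):
        rng = np.random.default_rng(7)
        for seed in range(5):
            peptide = random_peptide(FixtureSpec(seed=seed, peptide_length=6))
            model = assemble(peptide, ecoli, defaults)
            for _ in range(20):
                bits = rng.integers(0, 2, size=model.M)
                assert model.energy(bits) == pytest.approx(
                    dense_energy(model, bits), abs=1e-10
                )

    def test_same_position_coupling_at_least_tau(self, ecoli, defaults):
        model = assemble("LL", ecoli, defaults)
        layout = model.layout
        for sl in layout.position_slices:
            for i in range(sl.start, sl.stop):
                for j in range(i + 1, sl.stop):
                    assert model.J[(i, j)] >= defaults.tau_value

    def test_rarer_codon_never_lowers_usage_bias(self, ecoli, defaults):
        """Swapping a selected codon for a strictly rarer synonym raises
        the usage-bias component."""
        sigma = log_inverse_frequencies(ecoli, defaults.epsilon_f)
        for aa, pairs in ecoli.entries.items():
            ranked = sorted(pairs, key=lambda cf: cf[1])
            for (rare, f_rare), (common, f_common) in zip(ranked, ranked[1:]):
                if f_rare < f_common:
                    assert sigma[rare] > sigma[common]

    def test_non_dominant_tau_warns(self, ecoli):
        with pytest.warns(UserWarning, match="dominate"):
            assemble("GSK", ecoli, Parameters(c_f=10.0, tau_value=0.5))

    def test_wrong_bit_length_is_an_error(self, ecoli, defaults):
        model = assemble("GSK", ecoli, defaults)
        with pytest.raises(ValueError, match="length"):
            energy(model, [1, 0, 1])

    def test_model_rejects_bad_coefficients(self):
        with pytest.raises(ValueError, match="upper-triangular"):
            QuadraticModel(h=np.zeros(2), J={(1, 0): 1.0})
        with pytest.raises(ValueError, match="finite"):
            QuadraticModel(h=np.array([np.inf]), J={})
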