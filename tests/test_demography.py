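"""Logistic growth, egg production, bank turnover, and migration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from foundersim import demography
from foundersim._state import get_space
from foundersim.demography import (
    DemographyParams,
    asexual_growth,
    bank_hatch,
    bank_survive,
    bank_update,
    migrate,
    produce_eggs,
)


def closed_form_logistic(n0, r, K, t):
    return K / (1.0 + (K / n0 - 1.0) * np.exp(-r * t))


class TestAsexualGrowth:
    def test_single_genotype_matches_closed_form(self):
        out = asexual_growth(np.array([1.0]), np.array([0.3]), 2e7, 60.0)
        assert out[0] == pytest.approx(closed_form_logistic(1.0, 0.3, 2e7, 60.0),
                                       rel=1e-8)
        assert out[0] == pytest.approx(1.533e7, rel=1e-3)

    def test_empty_population_stays_empty(self):
        out = asexual_growth(np.zeros(4), np.full(4, 0.3), 2e7, 60.0)
        assert np.all(out == 0.0)

    def test_absent_genotypes_stay_absent(self):
        out = asexual_growth(np.array([5.0, 0.0]), np.array([0.2, 0.9]),
                             1e4, 60.0)
        assert out[1] == 0.0
        assert out[0] > 5.0

    def test_equal_rates_preserve_frequencies(self):
        n0 = np.array([3.0, 17.0, 2.0])
        out = asexual_growth(n0, np.full(3, 0.4), 1e5, 60.0)
        np.testing.assert_allclose(out / out.sum(), n0 / n0.sum(), rtol=1e-8)

    def test_negative_rate_decays(self):
        out = asexual_growth(np.array([100.0]), np.array([-0.05]), 1e4, 60.0)
        assert out[0] == pytest.approx(closed_form_logistic(100.0, -0.05, 1e4,
                                                            60.0), rel=1e-6)
        assert out[0] < 100.0

    def test_total_never_exceeds_carrying_capacity(self, rng):
        for _ in range(5):
            n0 = rng.random(6) * 100
            rates = rng.uniform(0.05, 1.0, size=6)
            K = 10 ** rng.uniform(3, 7)
            out = asexual_growth(n0, rates, K, 60.0)
            assert out.sum() <= K * (1 + 1e-6)
            assert out.sum() >= n0.sum()  # all r > 0, starting below K

    def test_scalar_integral_equals_full_system_integration(self, rng):
        # the reduced one-dimensional form must reproduce the directly
        # integrated multi-genotype logistic system on populations starting
        # below carrying capacity (negative deviant rates included)
        for _ in range(8):
            k = int(rng.integers(2, 8))
            K = 10 ** rng.uniform(2.5, 7.5)
            n0 = rng.random(k) * (rng.uniform(0.001, 0.8) * K / k)
            rates = rng.uniform(-0.1, 1.0, size=k)
            tau = rng.uniform(10, 90)
            mine = asexual_growth(n0, rates, K, tau)

            def rhs(_t, N):
                return N * rates * (1.0 - N.sum() / K)

            ref = solve_ivp(rhs, (0.0, tau), n0, rtol=1e-11, atol=1e-13).y[:, -1]
            np.testing.assert_allclose(mine, ref, rtol=1e-6)

    def test_over_capacity_population_decays_to_carrying_capacity(self):
        # all growth rates positive: an over-capacity population relaxes to K
        n0 = np.array([3e4, 2e4])
        out = asexual_growth(n0, np.array([0.3, 0.5]), 1e4, 60.0)
        assert out.sum() == pytest.approx(1e4, rel=1e-3)

        def rhs(_t, N):
            return N * np.array([0.3, 0.5]) * (1.0 - N.sum() / 1e4)

        ref = solve_ivp(rhs, (0.0, 60.0), n0, rtol=1e-11, atol=1e-13).y[:, -1]
        np.testing.assert_allclose(out, ref, rtol=1e-6)

    def test_divergent_instance_raises_instead_of_hanging(self):
        # over capacity and dominated by negative rates: the logistic system
        # has no finite attractor; the integrator must fail loudly
        from foundersim.demography import GrowthIntegrationError
        n0 = np.array([3000.0, 1000.0])
        rates = np.array([-0.1, 0.8])
        with pytest.raises(GrowthIntegrationError):
            asexual_growth(n0, rates, 100.0, 200.0)


class TestProduceEggs:
    def test_total_egg_count_from_sexual_output(self, rng):
        space = get_space(1, False)
        plankton = np.zeros(space.n_genotypes)
        plankton[0] = 1000.0
        params = DemographyParams(K=1e6)
        eggs = produce_eggs(plankton, params, space, 0.5, rng)
        assert eggs.sum() == 1050  # 1000 * m(0.7) * sr(0.5) * e(3)

    def test_monomorphic_clone_breeds_true(self, rng):
        space = get_space(2, True)
        plankton = np.zeros(space.n_genotypes)
        idx = space.n_genotypes - 1  # fully homozygous corner state
        plankton[idx] = 500.0
        for c in (0.0, 0.5):
            eggs = produce_eggs(plankton, DemographyParams(K=1e6), space, c, rng)
            assert eggs[idx] == eggs.sum() > 0

    def test_heterozygous_clone_yields_hwe_offspring(self, rng):
        space = get_space(1, False)
        het = next(i for i, (a, b) in enumerate(space.pair_states) if a != b)
        plankton = np.zeros(space.n_genotypes)
        plankton[het] = 40000.0
        eggs = produce_eggs(plankton, DemographyParams(K=1e6), space, 0.5, rng)
        frac = eggs / eggs.sum()
        expected = {het: 0.5}
        hom = [i for i in range(space.n_genotypes) if i != het]
        for i in hom:
            expected[i] = 0.25
        for i, exp in expected.items():
            se = np.sqrt(exp * (1 - exp) / eggs.sum())
            assert abs(frac[i] - exp) < 5 * se

    def test_extinct_plankton_yields_empty_cohort(self, rng):
        space = get_space(1, False)
        eggs = produce_eggs(np.zeros(space.n_genotypes),
                            DemographyParams(K=1e6), space, 0.5, rng)
        assert eggs.sum() == 0.0


class TestBank:
    def test_deterministic_survival_and_hatching(self, rng):
        params = DemographyParams()
        bank = np.array([10_000.0])
        hatched, remaining = bank_update(np.zeros(1), bank, params, rng)
        assert hatched[0] == pytest.approx(10_000 * 0.763 * 0.046)  # ~351
        assert remaining[0] == pytest.approx(10_000 * 0.763 * (1 - 0.046))

    def test_no_bank_discards_unhatched_survivors(self, rng):
        params = DemographyParams(bank_present=False)
        hatched, remaining = bank_update(np.zeros(1), np.array([10_000.0]),
                                         params, rng)
        assert hatched[0] == pytest.approx(10_000 * 0.763 * 0.046)
        assert remaining[0] == 0.0

    def test_zero_survival_empties_bank(self, rng):
        params = DemographyParams(gamma=0.0)
        hatched, remaining = bank_update(np.zeros(1), np.array([500.0]),
                                         params, rng)
        assert hatched[0] == 0.0 and remaining[0] == 0.0

    def test_stochastic_regime_matches_binomial_expectation(self):
        params = DemographyParams()
        rng = np.random.default_rng(77)
        draws = 10_000
        total = 0.0
        for _ in range(draws):
            hatched, _ = bank_update(np.zeros(1), np.array([500.0]), params,
                                     rng)
            total += hatched[0]
        expected = 500 * 0.763 * 0.046  # 17.549
        se = np.sqrt(500 * 0.763 * 0.046 * (1 - 0.763 * 0.046) / draws)
        assert abs(total / draws - expected) < 3 * se

    def test_stochastic_counts_are_integers(self):
        params = DemographyParams()
        rng = np.random.default_rng(5)
        hatched, remaining = bank_update(np.zeros(2),
                                         np.array([400.0, 300.0]), params, rng)
        assert np.all(hatched == np.rint(hatched))
        assert np.all(remaining == np.rint(remaining))

    def test_regime_threshold_consistency(self):
        # mean of stochastic draws at 999 eggs ~ deterministic fractions at 1,000
        params = DemographyParams()
        rng = np.random.default_rng(11)
        reps = 4_000
        acc = 0.0
        for _ in range(reps):
            surv = bank_survive(np.array([999.0]), params, rng)
            acc += surv[0]
        det = bank_survive(np.array([1000.0]), params, rng)[0]
        se = np.sqrt(999 * 0.763 * (1 - 0.763) / reps)
        assert abs(acc / reps - det * 999 / 1000) < 4 * se


class TestMigrate:
    def test_zero_migrants_empty(self, rng):
        assert migrate(np.array([10.0, 5.0]), 0, rng).sum() == 0.0

    def test_empty_donor_sends_nothing(self, rng):
        assert migrate(np.zeros(3), 7, rng).sum() == 0.0

    def test_monomorphic_donor_sends_identical_eggs(self, rng):
        out = migrate(np.array([0.0, 42.0]), 7, rng)
        assert out[1] == 7.0 and out[0] == 0.0

    def test_donor_not_depleted(self, rng):
        donor = np.array([100.0, 100.0])
        before = donor.copy()
        migrate(donor, 50, rng)
        np.testing.assert_array_equal(donor, before)

    def test_multinomial_split_of_even_donor(self):
        rng = np.random.default_rng(99)
        out = migrate(np.array([500.0, 500.0]), 10_000, rng)
        assert out.sum() == 10_000
        assert abs(out[0] - 5000) < 3 * np.sqrt(10_000 * 0.25)


class TestNeutralityMartingale:
    def test_expected_egg_allele_frequency_equals_parental(self):
        # with no selection the egg allele frequency is an unbiased draw
        # around the parental frequency (drift has no direction)
        space = get_space(2, False)
        rng = np.random.default_rng(123)
        weights = rng.random(space.n_genotypes) * 50
        p_parent, _ = space.allele_freqs(weights)
        params = DemographyParams(K=1e6)
        reps = 400
        freqs = np.zeros((reps, space.n))
        for i in range(reps):
            eggs = produce_eggs(weights, params, space, 0.5, rng)
            freqs[i], _ = space.allele_freqs(eggs)
        n_eggs = produce_eggs(weights, params, space, 0.5, rng).sum()
        se = np.sqrt(0.25 / (2 * n_eggs) / reps)
        np.testing.assert_allclose(freqs.mean(axis=0), p_parent,
                                   atol=5 * max(se, 1e-4))
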