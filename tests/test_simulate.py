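"""Genotype simulators: HWD genotype probabilities, null independence,
conditional alternative, and the D' <-> D conversion."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from ldmc import (
    HaplotypeFreqs,
    LocusModel,
    PairModel,
    dprime_to_D,
    genotype_probs,
    ld_from_haplotypes,
    simulate_alternative,
    simulate_null,
)


class TestLocusModel:
    @pytest.mark.parametrize(
        "p1, d_h, expect",
        [
            (0.5, 0.0, (0.25, 0.5, 0.25)),
            (0.5, 0.05, (0.30, 0.40, 0.30)),  # positive d_h removes heterozygotes
            (0.9, 0.0, (0.81, 0.18, 0.01)),
        ],
    )
    def test_genotype_probs(self, p1, d_h, expect):
        probs = genotype_probs(LocusModel(p1, d_h))
        assert probs == pytest.approx(expect, abs=1e-12)
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)

    def test_infeasible_d_h_reports_range(self):
        with pytest.raises(ValueError, match="feasible range"):
            LocusModel(0.9, -0.5)

    def test_probs_sum_to_one_on_grid(self):
        for p1 in np.linspace(0.05, 0.95, 10):
            lo, hi = -min(p1 ** 2, (1 - p1) ** 2), p1 * (1 - p1)
            for d_h in np.linspace(lo, hi, 7):
                probs = genotype_probs(LocusModel(p1, d_h))
                assert sum(probs) == pytest.approx(1.0, abs=1e-12)
                assert all(-1e-12 <= p <= 1 + 1e-12 for p in probs)


class TestNullSimulator:
    def test_seed_determinism(self):
        a, b = LocusModel(0.3), LocusModel(0.7, 0.02)
        g1 = simulate_null(a, b, 500, seed=42)
        g2 = simulate_null(a, b, 500, seed=42)
        np.testing.assert_array_equal(g1[0], g2[0])
        np.testing.assert_array_equal(g1[1], g2[1])

    def test_double_homozygote_frequency(self):
        """P(2,2) under HWE with p1 = q1 = 0.5 is 0.0625."""
        n = 10000
        g_a, g_b = simulate_null(LocusModel(0.5), LocusModel(0.5), n, seed=3)
        p_hat = np.mean((g_a == 2) & (g_b == 2))
        se = np.sqrt(0.0625 * (1 - 0.0625) / n)
        assert abs(p_hat - 0.0625) <= 3 * se

    def test_independence_g_statistic(self):
        """The 9-cell table shows no association between loci."""
        g_a, g_b = simulate_null(LocusModel(0.4), LocusModel(0.6), 10000, seed=4)
        obs = np.zeros((3, 3))
        np.add.at(obs, (g_a.astype(int), g_b.astype(int)), 1)
        res = chi2_contingency(obs, lambda_="log-likelihood")
        assert res.pvalue > 1e-4  # smoke check: no gross dependence


class TestAlternativeSimulator:
    def test_d_zero_conditionals_collapse_to_marginal(self):
        pm = PairModel(LocusModel(0.5, 0.03), LocusModel(0.3), d=0.0, n=10)
        assert pm.conditional_b1 == pytest.approx((0.3, 0.3))

    def test_true_haplotype_frequency(self):
        """Phase-known record of the generator matches f11 = p1 q1 + D."""
        pm = PairModel(LocusModel(0.5), LocusModel(0.5), d=0.0625, n=10000)
        _, _, counts = simulate_alternative(pm, seed=5, return_haplotype_counts=True)
        f11_hat = counts[0] / (2 * pm.n)
        se = np.sqrt(0.3125 * (1 - 0.3125) / (2 * pm.n))
        assert abs(f11_hat - 0.3125) <= 3 * se
        np.testing.assert_allclose(np.sum(counts), 2 * pm.n)

    def test_phased_r2_recovers_target(self):
        """r2 computed from the generator's phase-known counts matches
        D^2/(p1 p2 q1 q2) within sampling error."""
        d = dprime_to_D(0.5, 0.5, 0.25)
        pm = PairModel(LocusModel(0.5), LocusModel(0.5), d=d, n=10000)
        _, _, counts = simulate_alternative(pm, seed=6, return_haplotype_counts=True)
        stats = ld_from_haplotypes(HaplotypeFreqs.from_counts(*counts))
        target = d ** 2 / 0.5 ** 4
        assert stats.r2 == pytest.approx(target, abs=0.01)

    def test_infeasible_d_reports_range(self):
        with pytest.raises(ValueError, match="feasible range"):
            PairModel(LocusModel(0.9), LocusModel(0.1), d=0.2, n=10)

    def test_seed_determinism(self):
        pm = PairModel(LocusModel(0.5), LocusModel(0.5), d=0.05, n=200, seed=9)
        g1 = simulate_alternative(pm)
        g2 = simulate_alternative(pm)
        np.testing.assert_array_equal(g1[0], g2[0])
        np.testing.assert_array_equal(g1[1], g2[1])


class TestDprimeConversion:
    def test_known_value(self):
        assert dprime_to_D(0.5, 0.5, 0.25) == pytest.approx(0.0625)

    def test_zero(self):
        assert dprime_to_D(0.3, 0.8, 0.0) == 0.0

    @pytest.mark.parametrize("p1,q1,dp,sign", [(0.5, 0.5, 0.25, 1), (0.3, 0.6, 0.4, 1), (0.7, 0.2, 0.8, -1)])
    def test_round_trip_through_ld_stats(self, p1, q1, dp, sign):
        d = dprime_to_D(p1, q1, dp, sign)
        h = HaplotypeFreqs(
            p1 * q1 + d, p1 * (1 - q1) - d, (1 - p1) * q1 - d, (1 - p1) * (1 - q1) + d
        )
        s = ld_from_haplotypes(h)
        assert s.Dprime == pytest.approx(dp, abs=1e-12)
        assert np.sign(s.D) == (np.sign(d) if dp else 0)
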