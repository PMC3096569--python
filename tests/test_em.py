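"""EM haplotype-frequency estimation: tabulation, ascent, oracle agreement,
consistency, and scalar/batch equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldmc import (
    GenotypeTable,
    HaplotypeFreqs,
    LocusModel,
    PairModel,
    em_haplotype_freqs,
    genotype_table_from_calls,
    ld_from_haplotypes,
    observed_loglik,
    simulate_alternative,
)
from ldmc.em import _em_batch


def table(**cells):
    c = np.zeros((3, 3), dtype=int)
    for key, v in cells.items():
        i, j = int(key[1]), int(key[2])
        c[i, j] = v
    return GenotypeTable(c)


class TestTabulation:
    def test_basic(self):
        t = genotype_table_from_calls([0, 1, 2], [0, 1, 2])
        assert t.n == 3
        assert t.counts[0, 0] == t.counts[1, 1] == t.counts[2, 2] == 1

    def test_pairwise_deletion(self):
        t = genotype_table_from_calls([1, None], [1, 1])
        assert t.n == 1 and t.counts[1, 1] == 1 and t.n_excluded == 1
        t2 = genotype_table_from_calls([1, np.nan], [1, 1])
        assert t2.n == 1 and t2.n_excluded == 1

    def test_corners(self):
        t = genotype_table_from_calls([2, 2, 0, 0], [2, 0, 2, 0])
        corners = [t.counts[2, 2], t.counts[2, 0], t.counts[0, 2], t.counts[0, 0]]
        assert corners == [1, 1, 1, 1] and t.n == 4

    def test_errors(self):
        with pytest.raises(ValueError):
            genotype_table_from_calls([0, 1], [0])
        with pytest.raises(ValueError):
            genotype_table_from_calls([0, 3], [0, 0])


class TestEM:
    def test_no_double_het_is_closed_form(self):
        """Without double heterozygotes EM is the counting estimate."""
        t = table(c22=2, c21=3, c10=1, c00=4)
        r = em_haplotype_freqs(t)
        assert r.converged and r.iterations == 1
        # haplotypes: c22 -> 2x(11); c21 -> 11+12; c10 -> 12+22; c00 -> 2x(22)
        expect = np.array([2 * 2 + 3, 3 + 1, 0, 1 + 4 * 2]) / 20
        np.testing.assert_allclose(r.freqs.as_array(), expect, atol=1e-12)

    def test_pure_coupling(self):
        r = em_haplotype_freqs(table(c00=1, c22=1))
        np.testing.assert_allclose(r.freqs.as_array(), [0.5, 0, 0, 0.5], atol=1e-12)
        assert ld_from_haplotypes(r.freqs).r2 == pytest.approx(1.0)

    def test_grid_search_oracle(self):
        """EM agrees with brute-force maximisation of the observed-data
        likelihood over the one free parameter (the coupling split);
        allele margins are phase-invariant so the slice contains the MLE."""
        t = table(c22=3, c00=3, c11=4)
        r = em_haplotype_freqs(t)
        p1, q1 = r.freqs.p1, r.freqs.q1
        lo, hi = max(0.0, p1 + q1 - 1.0), min(p1, q1)
        grid = np.linspace(lo, hi, 50001)
        lls = [
            observed_loglik(t, HaplotypeFreqs(f11, p1 - f11, q1 - f11, 1 - p1 - q1 + f11))
            for f11 in grid
        ]
        best = grid[int(np.argmax(lls))]
        assert r.freqs.f11 == pytest.approx(best, abs=1e-4)
        assert r.loglik >= max(lls) - 1e-6

    def test_consistency_at_large_n(self):
        """EM recovers the generating haplotype frequencies at n = 10,000."""
        pm = PairModel(LocusModel(0.5), LocusModel(0.5), d=0.0625, n=10000)
        g_a, g_b = simulate_alternative(pm, seed=0)
        r = em_haplotype_freqs(genotype_table_from_calls(g_a, g_b))
        truth = np.array(pm.haplotype_freqs)
        se = np.sqrt(truth * (1 - truth) / (2 * pm.n))
        np.testing.assert_array_less(np.abs(r.freqs.as_array() - truth), 3 * se)

    def test_zero_individuals_rejected(self):
        with pytest.raises(ValueError):
            GenotypeTable(np.zeros((3, 3), dtype=int))


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=30), min_size=9, max_size=9))
def test_em_ascent_and_one_step_improvement(cells):
    """The observed-data log-likelihood never decreases along EM iterations,
    and any EM step from an arbitrary start does not lower it."""
    c = np.array(cells).reshape(3, 3)
    if c.sum() == 0:
        c[1, 1] = 1
    t = GenotypeTable(c)
    r = em_haplotype_freqs(t, keep_trace=True)
    diffs = np.diff(r.trace)
    assert np.all(diffs >= -1e-9)
    assert np.isfinite(r.loglik)


def test_batch_matches_scalar():
    """The vectorised EM is table-for-table identical to the scalar EM."""
    rng = np.random.default_rng(5)
    tables = [
        rng.multinomial(int(rng.integers(2, 200)), rng.dirichlet(np.ones(9))).reshape(3, 3)
        for _ in range(100)
    ]
    freqs, iters, conv = _em_batch(np.array(tables))
    for k, c in enumerate(tables):
        r = em_haplotype_freqs(GenotypeTable(c))
        np.testing.assert_allclose(freqs[k], r.freqs.as_array(), atol=1e-12)
        assert iters[k] == r.iterations
        assert conv[k] == r.converged


def test_observed_loglik_flags_impossible_data():
    t = table(c11=2, c22=1)
    h = HaplotypeFreqs(0.0, 0.5, 0.5, 0.0)  # no coupling haplotypes at all
    assert observed_loglik(t, h) == float("-inf")
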