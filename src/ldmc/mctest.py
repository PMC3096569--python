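"""Monte Carlo bootstrap test of linkage disequilibrium.

Applied to EM-estimated haplotype counts the statistic N·r² is far from
χ²₁-distributed: haplotype-estimation variability inflates the tail.
The remedy implemented here builds the null distribution of N·r²
empirically.  Under the null hypothesis of no LD the genotypes at the
two SNPs are independent, so a null data set can be manufactured from
the observed one by resampling the single-locus genotypes at each SNP
with replacement and pairing the two resampled sets at random.  Each
bootstrap replicate is then pushed through the same pipeline as the
real data (EM phasing, then N·r²), so the null sample carries the same
estimation variability as the observed statistic — including any
Hardy-Weinberg disequilibrium at either locus, because whole
single-locus *genotypes* (never individual alleles) are resampled.

The p-value is the add-one empirical exceedance probability
(1 + #{null ≥ observed}) / (B + 1), never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .em import _em_batch, complete_pairs, em_haplotype_freqs, genotype_table_from_calls
from .ld import LDStats, MonomorphicLocusError, _nr2_batch, ld_from_haplotypes

__all__ = ["MCTestResult", "bootstrap_null", "mc_ld_test"]


@dataclass
class MCTestResult:
    """Result of the Monte Carlo LD test for one SNP pair.

    ``n_degenerate`` counts bootstrap replicates in which a resampled
    locus came out monomorphic; those contribute statistic 0 (no
    evidence of LD) to the null sample.
    """

    observed: LDStats
    null_sample: np.ndarray
    p_value: float
    B: int
    seed: object
    n_degenerate: int
    n: int  # complete individuals used

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MC LD test: r2={self.observed.r2:.6g} D'={self.observed.Dprime:.6g} "
            f"Nr2={self.observed.Nr2:.6g} p={self.p_value:.6g} "
            f"(n={self.n}, B={self.B})"
        )


def _pair_tables(
    rng: np.random.Generator, m_a: np.ndarray, m_b: np.ndarray
) -> np.ndarray:
    """Random pairing of two genotype multisets, vectorised over replicates.

    Given per-replicate genotype counts ``m_a``, ``m_b`` (each (B, 3)),
    draws the 3×3 joint table produced by pairing the two multisets
    uniformly at random: row i of the table is a multivariate
    hypergeometric draw of the B-genotype pool, taken sequentially and
    decomposed into scalar hypergeometric draws so the whole batch is
    one set of vectorised calls.
    """
    n_rep = m_a.shape[0]
    tables = np.zeros((n_rep, 3, 3), dtype=np.int64)
    remaining = m_b.astype(np.int64).copy()
    for i in range(2):  # last row is the remainder of the pool
        n_i = m_a[:, i].astype(np.int64)
        x0 = rng.hypergeometric(remaining[:, 0], remaining[:, 1] + remaining[:, 2], n_i)
        x1 = rng.hypergeometric(remaining[:, 1], remaining[:, 2], n_i - x0)
        tables[:, i, 0] = x0
        tables[:, i, 1] = x1
        tables[:, i, 2] = n_i - x0 - x1
        remaining -= tables[:, i, :]
    tables[:, 2, :] = remaining
    return tables


def _bootstrap_null(
    g_a: np.ndarray,
    g_b: np.ndarray,
    B: int,
    rng: np.random.Generator,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, int]:
    """Null N·r² sample plus the count of degenerate replicates."""
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    n = g_a.size
    if n < 2:
        raise ValueError("need at least 2 individuals with complete genotypes")
    p_a = np.bincount(g_a, minlength=3) / n
    p_b = np.bincount(g_b, minlength=3) / n
    # resampling n genotypes with replacement <=> multinomial counts at the
    # empirical genotype frequencies; random pairing <=> fixed-margin table
    m_a = rng.multinomial(n, p_a, size=B)
    m_b = rng.multinomial(n, p_b, size=B)
    tables = _pair_tables(rng, m_a, m_b)
    freqs, _, _ = _em_batch(tables, tol=tol, max_iter=max_iter)
    nr2, degenerate = _nr2_batch(freqs, 2 * n)
    return nr2, int(degenerate.sum())


def bootstrap_null(g_a, g_b, B: int, seed=None) -> np.ndarray:
    """Bootstrap null sample of N·r² for one SNP pair.

    Each replicate resamples the n single-locus genotypes with
    replacement at SNP A and, independently, at SNP B, pairs them in
    random order, and recomputes N·r² through the EM phasing step.
    Deterministic given ``seed``.
    """
    a, b = complete_pairs(g_a, g_b)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nr2, _ = _bootstrap_null(a, b, B, rng)
    return nr2


def mc_ld_test(g_a, g_b, B: int = 10000, seed=None) -> MCTestResult:
    """Monte Carlo LD test for a pair of bi-allelic SNPs.

    Parameters
    ----------
    g_a, g_b : sequences of {0, 1, 2, missing}
        Unphased genotypes (copies of allele 1) for the two SNPs;
        individuals missing either call are dropped.
    B : int
        Bootstrap replicates for the null distribution.
    seed : int, Generator or None
        Source of randomness; fixing it makes the test reproducible.

    Returns
    -------
    MCTestResult
        Observed LD statistics (report r² together with the p-value),
        the null sample, and the add-one empirical p-value.

    Raises
    ------
    MonomorphicLocusError
        If either SNP is monomorphic in the observed (complete) data:
        the LD test is undefined.
    """
    a, b = complete_pairs(g_a, g_b)
    if a.size < 2:
        raise ValueError("need at least 2 individuals with complete genotypes")
    for name, g in (("A", a), ("B", b)):
        alleles = int(np.sum(g))
        if alleles == 0 or alleles == 2 * g.size:
            raise MonomorphicLocusError(
                f"LD test undefined: SNP {name} is monomorphic in the sample"
            )
    table = genotype_table_from_calls(a, b)
    em = em_haplotype_freqs(table)
    observed = ld_from_haplotypes(em.freqs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null, n_degenerate = _bootstrap_null(a, b, B, rng)
    p_value = (1.0 + int(np.sum(null >= observed.Nr2))) / (B + 1.0)
    return MCTestResult(
        observed=observed,
        null_sample=null,
        p_value=p_value,
        B=B,
        seed=seed,
        n_degenerate=n_degenerate,
        n=int(a.size),
    )
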