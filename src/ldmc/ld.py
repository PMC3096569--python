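"""Linkage-disequilibrium measures for a pair of bi-allelic SNPs.

Everything here is a deterministic function of the four haplotype
frequencies f(A1B1), f(A1B2), f(A2B1), f(A2B2) and the chromosome count
``N``.  The measures are the classical ones:

* ``D``  — gametic disequilibrium, f(A1B1) − p1·q1, where p1 and q1 are
  the marginal frequencies of alleles A1 and B1;
* ``D'`` — |D| normalised by its frequency-dependent bound D_max
  (Lewontin), so that D' ∈ [0, 1];
* ``r²`` — squared correlation of the allele indicators,
  D² / (p1·p2·q1·q2);
* ``N·r²`` — the test statistic; on a phased sample it equals the
  Pearson χ² statistic of the 2×2 haplotype contingency table.

When the haplotypes are estimated rather than observed, N·r² is *not*
χ²₁-distributed; the Monte Carlo test in :mod:`ldmc.mctest` exists for
exactly that reason.  :func:`chi2_pvalue_naive` is provided so the naive
(invalid for estimated haplotypes) χ² test can be reproduced and studied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_FREQ_TOL = 1e-9

__all__ = [
    "MonomorphicLocusError",
    "HaplotypeFreqs",
    "LDStats",
    "ld_from_haplotypes",
    "chi2_pvalue_naive",
]


class MonomorphicLocusError(ValueError):
    """LD is undefined when one of the loci carries a single allele."""


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Frequencies of the four two-locus haplotypes plus sample size.

    Attributes
    ----------
    f11, f12, f21, f22 : float
        Frequencies of haplotypes A1B1, A1B2, A2B1, A2B2.  They must be
        non-negative and sum to one (a deviation below 1e-9 is
        renormalised away; anything larger is an error).
    N : int
        Number of chromosomes in the sample — twice the number of
        diploid individuals.  ``N = 0`` is allowed for population-level
        (non-sample) frequencies; the Nr² statistic is then 0.
    """

    f11: float
    f12: float
    f21: float
    f22: float
    N: int = 0

    def __post_init__(self) -> None:
        f = np.array([self.f11, self.f12, self.f21, self.f22], dtype=float)
        if np.any(f < -_FREQ_TOL):
            raise ValueError(f"haplotype frequencies must be non-negative, got {f}")
        f = np.clip(f, 0.0, None)
        total = f.sum()
        if abs(total - 1.0) > _FREQ_TOL:
            raise ValueError(
                f"haplotype frequencies must sum to 1 (got {total!r}); "
                "deviations above 1e-9 are treated as data errors"
            )
        f /= total
        if self.N < 0 or self.N != int(self.N):
            raise ValueError(f"N must be a non-negative integer, got {self.N!r}")
        for name, value in zip(("f11", "f12", "f21", "f22"), f):
            object.__setattr__(self, name, float(value))
        object.__setattr__(self, "N", int(self.N))

    @classmethod
    def from_counts(cls, c11: int, c12: int, c21: int, c22: int) -> "HaplotypeFreqs":
        """Build from observed (phased) haplotype counts."""
        counts = np.array([c11, c12, c21, c22], dtype=float)
        if np.any(counts < 0):
            raise ValueError("haplotype counts must be non-negative")
        n = counts.sum()
        if n <= 0:
            raise ValueError("at least one haplotype is required")
        return cls(*(counts / n), N=int(n))

    # marginal allele frequencies
    @property
    def p1(self) -> float:
        """Frequency of allele A1 at the first locus."""
        return self.f11 + self.f12

    @property
    def p2(self) -> float:
        return 1.0 - self.p1

    @property
    def q1(self) -> float:
        """Frequency of allele B1 at the second locus."""
        return self.f11 + self.f21

    @property
    def q2(self) -> float:
        return 1.0 - self.q1

    def as_array(self) -> np.ndarray:
        return np.array([self.f11, self.f12, self.f21, self.f22])


@dataclass(frozen=True)
class LDStats:
    """LD summary for one SNP pair.

    ``Nr2 = N * r2`` exactly; ``Dprime`` is |D|/D_max with the Lewontin
    bound, and is defined as 0 when D = 0.
    """

    D: float
    Dmax: float
    Dprime: float
    r2: float
    Nr2: float


def ld_from_haplotypes(h: HaplotypeFreqs) -> LDStats:
    """Compute D, D', r² and N·r² from haplotype frequencies.

    Raises
    ------
    MonomorphicLocusError
        If either locus is monomorphic (p1 or q1 equal to 0 or 1), in
        which case every LD measure is undefined.
    """
    p1, q1 = h.p1, h.q1
    if not (0.0 < p1 < 1.0 and 0.0 < q1 < 1.0):
        raise MonomorphicLocusError(
            f"LD undefined: monomorphic locus (p1={p1}, q1={q1})"
        )
    p2, q2 = 1.0 - p1, 1.0 - q1
    d = h.f11 - p1 * q1
    if d > 0:
        dmax = min(p1 * q2, p2 * q1)
    elif d < 0:
        dmax = min(p1 * q1, p2 * q2)
    else:
        dmax = min(p1 * q2, p2 * q1)  # irrelevant: D' := 0 when D = 0
    dprime = abs(d) / dmax if d != 0.0 else 0.0
    r2 = d * d / (p1 * p2 * q1 * q2)
    return LDStats(D=d, Dmax=dmax, Dprime=dprime, r2=r2, Nr2=h.N * r2)


def chi2_pvalue_naive(stat: float) -> float:
    """Upper-tail χ²₁ probability of a non-negative statistic.

    This is the *naive* p-value for N·r²: it is only valid when the
    haplotypes are directly observed.  Applied to EM-estimated haplotype
    counts it grossly understates the p-value (the type-I error of the
    resulting test is inflated several-fold); it is exposed so that this
    failure mode can be reproduced and quantified.
    """
    if stat < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {stat}")
    return float(stats.chi2.sf(stat, df=1))


def _nr2_batch(freqs: np.ndarray, n_chrom) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised N·r² over rows of haplotype-frequency vectors.

    Rows where either locus is monomorphic get statistic 0 (the
    "no evidence of LD" policy used for degenerate bootstrap
    replicates) and are flagged in the returned boolean mask.
    """
    f = np.asarray(freqs, dtype=float)
    p1 = f[:, 0] + f[:, 1]
    q1 = f[:, 0] + f[:, 2]
    denom = p1 * (1.0 - p1) * q1 * (1.0 - q1)
    degenerate = denom <= 0.0
    d = f[:, 0] - p1 * q1
    safe = np.where(degenerate, 1.0, denom)
    r2 = np.where(degenerate, 0.0, d * d / safe)
    return n_chrom * r2, degenerate
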