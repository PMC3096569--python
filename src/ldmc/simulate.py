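"""Two-SNP genotype simulators for the null (no LD) and alternative (LD)
hypotheses, with optional Hardy-Weinberg disequilibrium at each locus.

Single-locus genotype frequencies are parameterised by the allele
frequency p1 and a HWD coefficient D_H:

    P(2 copies) = p1² + D_H,
    P(1 copy)   = 2·p1·p2 − 2·D_H,
    P(0 copies) = p2² + D_H.

Under the null the two loci are independent, so the 9-cell joint
genotype distribution is the product multinomial.  Under the
alternative, SNP A genotypes are drawn from the single-locus model and
the SNP B allele on each of the two homologous chromosomes is drawn
conditionally on that chromosome's A allele:

    P(B1 | A1) = q1 + D/p1,      P(B1 | A2) = q1 − D/p2,

which yields haplotype frequencies f11 = p1·q1 + D, f12 = p1·q2 − D,
f21 = p2·q1 − D, f22 = p2·q2 + D.  Because the two B alleles of an
individual are drawn independently given the A alleles, locus B is in
HWE conditionally; HWD enters only through locus A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LocusModel",
    "PairModel",
    "genotype_probs",
    "simulate_null",
    "simulate_alternative",
    "dprime_to_D",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class LocusModel:
    """Single bi-allelic locus: allele-1 frequency and HWD coefficient.

    Negative ``d_h`` raises heterozygosity above the HWE value
    2·p1·p2, positive ``d_h`` lowers it.  The feasible range of
    ``d_h`` is [−min(p1², p2²), p1·p2]; outside it some genotype
    probability leaves [0, 1].
    """

    p1: float
    d_h: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p1 < 1.0:
            raise ValueError(f"allele frequency p1 must be in (0,1), got {self.p1}")
        p1, p2 = self.p1, 1.0 - self.p1
        lo, hi = -min(p1 * p1, p2 * p2), p1 * p2
        if not lo <= self.d_h <= hi:
            raise ValueError(
                f"HWD coefficient d_h={self.d_h} infeasible for p1={p1}; "
                f"feasible range is [{lo:.6g}, {hi:.6g}]"
            )


def genotype_probs(m: LocusModel) -> tuple[float, float, float]:
    """Genotype probabilities (P(2 copies), P(1 copy), P(0 copies))."""
    p1, p2 = m.p1, 1.0 - m.p1
    return (p1 * p1 + m.d_h, 2 * p1 * p2 - 2 * m.d_h, p2 * p2 + m.d_h)


def _copies_probs(m: LocusModel) -> np.ndarray:
    """Genotype probabilities indexed by copy number 0, 1, 2."""
    p2c, p1c, p0c = genotype_probs(m)
    return np.array([p0c, p1c, p2c])


def dprime_to_D(p1: float, q1: float, dprime: float, sign: int = 1) -> float:
    """Convert a target D' (with a sign for the direction of association)
    to the raw disequilibrium coefficient D = sign · D' · D_max."""
    if not (0.0 < p1 < 1.0 and 0.0 < q1 < 1.0):
        raise ValueError("allele frequencies must be in (0,1)")
    if not 0.0 <= dprime <= 1.0:
        raise ValueError(f"D' must be in [0,1], got {dprime}")
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    p2, q2 = 1.0 - p1, 1.0 - q1
    dmax = min(p1 * q2, p2 * q1) if sign > 0 else min(p1 * q1, p2 * q2)
    return sign * dprime * dmax


@dataclass(frozen=True)
class PairModel:
    """Two-locus model for the alternative simulator.

    ``locus_b.p1`` plays the role of q1 (frequency of B1).  ``d`` is
    the gametic disequilibrium between the SNPs; ``locus_b.d_h`` is
    ignored by design (B alleles are generated per chromosome, so
    locus B is conditionally in HWE).
    """

    locus_a: LocusModel
    locus_b: LocusModel
    d: float = 0.0
    n: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        p1, p2 = self.locus_a.p1, 1.0 - self.locus_a.p1
        q1, q2 = self.locus_b.p1, 1.0 - self.locus_b.p1
        lo = -min(p1 * q1, p2 * q2)
        hi = min(p1 * q2, p2 * q1)
        t1 = q1 + self.d / p1
        t2 = q1 - self.d / p2
        if not (0.0 <= t1 <= 1.0 and 0.0 <= t2 <= 1.0):
            raise ValueError(
                f"D={self.d} infeasible for p1={p1}, q1={q1}; "
                f"feasible range is [{lo:.6g}, {hi:.6g}]"
            )

    @property
    def conditional_b1(self) -> tuple[float, float]:
        """(P(B1|A1), P(B1|A2)) for one chromosome."""
        p1, p2 = self.locus_a.p1, 1.0 - self.locus_a.p1
        q1 = self.locus_b.p1
        return (q1 + self.d / p1, q1 - self.d / p2)

    @property
    def haplotype_freqs(self) -> tuple[float, float, float, float]:
        """True (f11, f12, f21, f22) implied by the model."""
        p1, p2 = self.locus_a.p1, 1.0 - self.locus_a.p1
        q1, q2 = self.locus_b.p1, 1.0 - self.locus_b.p1
        d = self.d
        return (p1 * q1 + d, p1 * q2 - d, p2 * q1 - d, p2 * q2 + d)


def simulate_null(
    a: LocusModel, b: LocusModel, n: int, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n individuals with independent genotypes at the two loci.

    The joint distribution is the 9-cell multinomial with product cell
    probabilities; we draw each locus independently, which is the same
    distribution.  Returns two length-n arrays of allele-1 copy numbers.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _rng(seed)
    g_a = rng.choice(3, size=n, p=_copies_probs(a))
    g_b = rng.choice(3, size=n, p=_copies_probs(b))
    return g_a.astype(np.int8), g_b.astype(np.int8)


def simulate_alternative(
    pm: PairModel, seed=None, return_haplotype_counts: bool = False
):
    """Draw n individuals under LD via the two-step conditional scheme.

    Step 1 draws SNP A genotypes from the single-locus (possibly HWD)
    model; step 2 draws, for each of the two homologous chromosomes,
    the B allele conditionally on that chromosome's A allele.  With
    ``return_haplotype_counts=True`` the generator's phase-known record
    (c11, c12, c21, c22 haplotype counts over the 2n chromosomes) is
    returned as a third element — the truth EM only estimates.

    ``seed`` overrides ``pm.seed`` when given.
    """
    rng = _rng(pm.seed if seed is None else seed)
    t1, t2 = pm.conditional_b1
    g_a = rng.choice(3, size=pm.n, p=_copies_probs(pm.locus_a)).astype(np.int64)
    # B1 alleles carried on A1 chromosomes / on A2 chromosomes per individual
    b_on_a1 = rng.binomial(g_a, t1)
    b_on_a2 = rng.binomial(2 - g_a, t2)
    g_b = b_on_a1 + b_on_a2
    if return_haplotype_counts:
        n_a1 = int(g_a.sum())
        c11 = int(b_on_a1.sum())
        c21 = int(b_on_a2.sum())
        counts = (c11, n_a1 - c11, c21, 2 * pm.n - n_a1 - c21)
        return g_a.astype(np.int8), g_b.astype(np.int8), counts
    return g_a.astype(np.int8), g_b.astype(np.int8)


def _null_tables(
    a: LocusModel, b: LocusModel, n: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """(reps, 3, 3) joint genotype tables under independence."""
    p9 = np.outer(_copies_probs(a), _copies_probs(b)).ravel()
    return rng.multinomial(n, p9, size=reps).reshape(reps, 3, 3)


def _alternative_tables(
    pm: PairModel, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """(reps, 3, 3) joint genotype tables under the alternative model.

    Equal in law to tabulating :func:`simulate_alternative` output:
    given the SNP A genotype, the B genotype of an individual is the sum
    of two independent conditional Bernoulli draws, so each A-genotype
    stratum is multinomial over B copy numbers.
    """
    t1, t2 = pm.conditional_b1
    n_a = rng.multinomial(pm.n, _copies_probs(pm.locus_a), size=reps)
    rows = np.array(
        [
            # A genotype 0: both chromosomes A2 -> Binomial(2, t2)
            [(1 - t2) ** 2, 2 * t2 * (1 - t2), t2 * t2],
            # A genotype 1: one A1 and one A2 chromosome
            [
                (1 - t1) * (1 - t2),
                t1 * (1 - t2) + (1 - t1) * t2,
                t1 * t2,
            ],
            # A genotype 2: both chromosomes A1 -> Binomial(2, t1)
            [(1 - t1) ** 2, 2 * t1 * (1 - t1), t1 * t1],
        ]
    )
    tables = np.empty((reps, 3, 3), dtype=np.int64)
    for i in range(3):
        tables[:, i, :] = rng.multinomial(n_a[:, i], rows[i])
    return tables
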