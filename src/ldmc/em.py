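"""Maximum-likelihood haplotype-frequency estimation for two SNPs (EM).

Unphased diploid genotypes at two bi-allelic loci reduce to a 3×3 count
table indexed by (copies of A1, copies of B1).  Every cell except the
double heterozygote (1, 1) determines its two haplotypes uniquely; a
double heterozygote is either A1B1/A2B2 ("coupling") or A1B2/A2B1
("repulsion").  The EM algorithm iterates:

* E-step: split each double heterozygote between the coupling phase
  with weight w = f11·f22 / (f11·f22 + f12·f21) and the repulsion phase
  with weight 1 − w;
* M-step: haplotype frequency = expected haplotype count / 2n.

Cell probabilities assume random union of haplotypes (HWE at the
haplotype level).  That assumption is deliberate even when the data
come from a Hardy-Weinberg-disequilibrium population: the resulting
bias of likelihood-based haplotype estimation under HWD is one of the
phenomena this package is built to study.

The marginal allele frequencies are phase-invariant, so every EM
iterate (and every stationary point of the likelihood) has margins
equal to the sample allele frequencies; only the coupling/repulsion
split is actually estimated.  This is what makes the 1-D grid-search
oracle used in the tests valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ld import HaplotypeFreqs

__all__ = [
    "GenotypeTable",
    "EMResult",
    "genotype_table_from_calls",
    "em_haplotype_freqs",
    "observed_loglik",
]

MISSING = -1  # internal integer code for a missing genotype call


def _as_calls(g, name: str = "genotypes") -> np.ndarray:
    """Coerce a genotype sequence to int8 with MISSING for absent calls.

    Accepts 0/1/2 copies of allele 1; ``None``, NaN and -1 mark missing.
    """
    a = np.asarray(g)
    if a.dtype == object:
        a = np.array([np.nan if v is None else v for v in a], dtype=float)
    a = a.astype(float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be a 1-D sequence")
    miss = np.isnan(a) | (a == MISSING)
    values = a[~miss]
    if values.size and not np.all(np.isin(values, (0.0, 1.0, 2.0))):
        bad = values[~np.isin(values, (0.0, 1.0, 2.0))][0]
        raise ValueError(f"{name} must contain 0/1/2/missing, got {bad!r}")
    out = np.where(miss, MISSING, a).astype(np.int8)
    return out


def complete_pairs(g_a, g_b) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise deletion: keep individuals with both genotypes present."""
    a = _as_calls(g_a, "genotypes at SNP A")
    b = _as_calls(g_b, "genotypes at SNP B")
    if a.size != b.size:
        raise ValueError(
            f"genotype sequences differ in length ({a.size} vs {b.size})"
        )
    keep = (a != MISSING) & (b != MISSING)
    return a[keep], b[keep]


@dataclass(frozen=True)
class GenotypeTable:
    """3×3 joint genotype counts, ``counts[i, j]`` = individuals with
    i copies of A1 and j copies of B1.  The (1, 1) cell holds the
    phase-ambiguous double heterozygotes."""

    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got shape {c.shape}")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            if not np.all(c == np.floor(c)) or np.any(c < 0):
                raise ValueError("counts must be non-negative integers")
        c = c.astype(np.int64)
        if c.sum() < 1:
            raise ValueError("genotype table must contain at least one individual")
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "n_excluded", int(self.n_excluded))

    @property
    def n(self) -> int:
        """Number of (complete) individuals."""
        return int(self.counts.sum())

    def transpose(self) -> "GenotypeTable":
        """Swap the roles of SNP A and SNP B."""
        return GenotypeTable(self.counts.T.copy(), self.n_excluded)


def genotype_table_from_calls(g_a, g_b) -> GenotypeTable:
    """Tabulate joint 3×3 genotype counts, dropping incomplete pairs."""
    a = _as_calls(g_a, "genotypes at SNP A")
    b = _as_calls(g_b, "genotypes at SNP B")
    if a.size != b.size:
        raise ValueError(
            f"genotype sequences differ in length ({a.size} vs {b.size})"
        )
    keep = (a != MISSING) & (b != MISSING)
    excluded = int(a.size - keep.sum())
    counts = np.bincount(
        3 * a[keep].astype(np.int64) + b[keep], minlength=9
    ).reshape(3, 3)
    return GenotypeTable(counts, n_excluded=excluded)


@dataclass
class EMResult:
    """Outcome of the EM fit.

    ``freqs.N`` equals 2n chromosomes.  ``trace`` holds the per-iteration
    observed-data log-likelihood when the fit was run with
    ``keep_trace=True`` (it is non-decreasing: EM ascent).
    """

    freqs: HaplotypeFreqs
    loglik: float
    iterations: int
    converged: bool
    trace: tuple = field(default_factory=tuple)


# deterministic haplotype contributions of the eight unambiguous cells:
# row = haplotype (11, 12, 21, 22), entries index the flattened 3x3 table
# counts[i, j] with i copies of A1, j copies of B1.
_DET = np.array(
    [
        # (0,0) (0,1) (0,2) (1,0) (1,1) (1,2) (2,0) (2,1) (2,2)
        [0, 0, 0, 0, 0, 1, 0, 1, 2],  # A1B1
        [0, 0, 0, 1, 0, 0, 2, 1, 0],  # A1B2
        [0, 1, 2, 0, 0, 1, 0, 0, 0],  # A2B1
        [2, 1, 0, 1, 0, 0, 0, 0, 0],  # A2B2
    ],
    dtype=float,
)


def _genotype_cell_probs(f: np.ndarray) -> np.ndarray:
    """9 genotype-cell probabilities under random union of haplotypes."""
    f11, f12, f21, f22 = f
    p = np.empty((3, 3))
    p[2, 2] = f11 * f11
    p[2, 1] = 2 * f11 * f12
    p[2, 0] = f12 * f12
    p[1, 2] = 2 * f11 * f21
    p[1, 1] = 2 * f11 * f22 + 2 * f12 * f21
    p[1, 0] = 2 * f12 * f22
    p[0, 2] = f21 * f21
    p[0, 1] = 2 * f21 * f22
    p[0, 0] = f22 * f22
    return p


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of the 9 genotype cells (with coefficient)."""
    p = _genotype_cell_probs(f).ravel()
    c = counts.ravel()
    if np.any((p <= 0.0) & (c > 0)):
        return float("-inf")
    p = p / p.sum()
    return float(stats.multinomial.logpmf(c, n=int(c.sum()), p=p))


def observed_loglik(t: GenotypeTable, h: HaplotypeFreqs) -> float:
    """Observed-data log-likelihood of haplotype frequencies ``h``.

    Cell probabilities are haplotype products (see module docstring);
    a zero-probability cell with a positive count yields −inf.
    """
    return _loglik(t.counts, h.as_array())


def em_haplotype_freqs(
    t: GenotypeTable,
    tol: float = 1e-8,
    max_iter: int = 1000,
    keep_trace: bool = False,
) -> EMResult:
    """EM estimate of the four haplotype frequencies from a 3×3 table.

    Starts from linkage equilibrium at the sample allele frequencies and
    stops when the largest absolute frequency change drops below ``tol``
    (or after ``max_iter`` iterations, in which case ``converged`` is
    False but the last iterate is still returned).  With no double
    heterozygotes the estimate is the closed-form counting estimate and
    a single iteration is reported.
    """
    c = t.counts.astype(float)
    n = c.sum()
    if n < 1:
        raise ValueError("EM requires at least one individual")
    two_n = 2.0 * n
    det = _DET @ c.ravel()
    dhet = c[1, 1]
    if dhet == 0:
        f = det / two_n
        freqs = HaplotypeFreqs(*f, N=int(two_n))
        ll = _loglik(t.counts, f)
        return EMResult(freqs, ll, 1, True, (ll,) if keep_trace else ())

    p1 = (det[0] + det[1] + dhet) / two_n  # allele margins are phase-invariant
    q1 = (det[0] + det[2] + dhet) / two_n
    f = np.array([p1 * q1, p1 * (1 - q1), (1 - p1) * q1, (1 - p1) * (1 - q1)])
    trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        denom = coupling + repulsion
        w = coupling / denom if denom > 0 else 0.5
        f_new = (det + dhet * np.array([w, 1 - w, 1 - w, w])) / two_n
        delta = np.abs(f_new - f).max()
        f = f_new
        if keep_trace:
            trace.append(_loglik(t.counts, f))
        if delta < tol:
            converged = True
            break
    freqs = HaplotypeFreqs(*f, N=int(two_n))
    ll = trace[-1] if keep_trace else _loglik(t.counts, f)
    return EMResult(freqs, ll, iterations, converged, tuple(trace))


def _em_batch(
    tables: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised EM over a stack of 3×3 tables.

    Parameters
    ----------
    tables : (m, 3, 3) array of counts.

    Returns
    -------
    freqs : (m, 4) haplotype frequencies (11, 12, 21, 22)
    iterations : (m,) int
    converged : (m,) bool

    Identical, table by table, to :func:`em_haplotype_freqs`; used by
    the bootstrap and the simulation studies where millions of small
    tables must be fit.
    """
    c = np.asarray(tables, dtype=float).reshape(-1, 9)
    m = c.shape[0]
    n = c.sum(axis=1)
    if np.any(n < 1):
        raise ValueError("every table must contain at least one individual")
    two_n = 2.0 * n
    det = c @ _DET.T  # (m, 4)
    dhet = c[:, 4]

    p1 = (det[:, 0] + det[:, 1] + dhet) / two_n
    q1 = (det[:, 0] + det[:, 2] + dhet) / two_n
    f = np.stack(
        [p1 * q1, p1 * (1 - q1), (1 - p1) * q1, (1 - p1) * (1 - q1)], axis=1
    )
    no_het = dhet == 0
    f[no_het] = det[no_het] / two_n[no_het, None]
    iterations = np.where(no_het, 1, 0)
    active = ~no_het
    for it in range(1, max_iter + 1):
        if not active.any():
            break
        coupling = f[:, 0] * f[:, 3]
        repulsion = f[:, 1] * f[:, 2]
        denom = coupling + repulsion
        w = np.where(denom > 0, coupling / np.maximum(denom, 1e-300), 0.5)
        weights = np.stack([w, 1 - w, 1 - w, w], axis=1)
        f_new = (det + dhet[:, None] * weights) / two_n[:, None]
        delta = np.abs(f_new - f).max(axis=1)
        f = np.where(active[:, None], f_new, f)
        newly = active & (delta < tol)
        iterations = np.where(newly, it, iterations)
        active &= ~newly
    iterations = np.where(active, max_iter, iterations)
    return f, iterations, ~active
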