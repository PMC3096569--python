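"""Simulation studies: type-I error of the naive χ² test and power of the
Monte Carlo LD test.

Two drivers mirror the two questions the package answers.

``type1_study`` simulates SNP pairs with *no* LD, runs the EM phasing
step per replicate, and measures how often N·r² exceeds χ²₁ quantiles —
the empirical size of the naive test, which is badly inflated because
haplotype estimation adds variability the χ² reference ignores.  With
``phase_known=True`` the statistic is computed from the simulator's true
haplotype counts instead, which restores nominal size and isolates
estimation variability as the cause of the inflation.

``power_study`` first simulates a D' = 0 arm to obtain empirical null
cutoffs of N·r² (the Monte Carlo critical values), then measures the
exceedance rate of arms simulated at increasing D'.  All arms share the
same cutoffs, and the cutoff at level α is the ⌊α(R+1)⌋-th largest of
the R null statistics.

A master seed spawns one independent substream per simulation arm, so
arms are reproducible regardless of evaluation order.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .em import _em_batch, em_haplotype_freqs, genotype_table_from_calls
from .ld import HaplotypeFreqs, MonomorphicLocusError, _nr2_batch, ld_from_haplotypes
from .simulate import (
    LocusModel,
    PairModel,
    _alternative_tables,
    _null_tables,
    dprime_to_D,
    simulate_alternative,
)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "type1_study",
    "power_study",
    "comparison_hook",
    "Replicate",
    "naive_chi2_rule",
    "phase_known_chi2_rule",
]

_POWER_GRID = (0.0, 0.025, 0.05, 0.075, 0.1, 0.125, 0.15, 0.175, 0.2, 0.225, 0.25)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a simulation study.

    Defaults are the study conditions of record: allele frequencies 0.5
    at both SNPs (maximising the double-heterozygote fraction and hence
    the effect of phase uncertainty), 1,000 individuals per replicate,
    10,000 replicates, and a D' grid from 0 to 0.25.  ``d_h`` applies
    to both loci in the null study and to SNP A in the power study
    (SNP B is generated per chromosome, hence conditionally in HWE).
    ``B`` is the per-test bootstrap size used only when individual
    Monte Carlo tests are run inside a study.
    """

    p1: float = 0.5
    q1: float = 0.5
    d_h: float = 0.0
    n: int = 1000
    reps: int = 10000
    dprime_grid: tuple = _POWER_GRID
    alphas: tuple = (0.05, 0.01, 0.001)
    seed: object = 0
    B: int = 10000

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not all(0.0 < a < 1.0 for a in self.alphas):
            raise ValueError(f"alphas must lie in (0,1), got {self.alphas}")
        if not all(0.0 <= d <= 1.0 for d in self.dprime_grid):
            raise ValueError(f"dprime_grid must lie in [0,1], got {self.dprime_grid}")
        LocusModel(self.p1, self.d_h)  # validates feasibility
        LocusModel(self.q1, self.d_h)
        for d in self.dprime_grid:
            dprime_to_D(self.p1, self.q1, d)

    def seed_sequence(self) -> np.random.SeedSequence:
        if isinstance(self.seed, np.random.SeedSequence):
            return self.seed
        return np.random.SeedSequence(self.seed)


@dataclass
class StudyReport:
    """Tabular outcome of a study.

    ``table`` has one row per (arm, level) with the estimated rate and
    its binomial standard error; ``null_cutoffs`` maps each level to the
    empirical critical value of N·r² from the null arm.
    """

    kind: str
    table: pd.DataFrame
    null_cutoffs: dict = field(default_factory=dict)
    nr2_null: np.ndarray | None = None
    config: StudyConfig | None = None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = [f"{self.kind} study ({self.config.reps if self.config else '?'} reps)"]
        lines.append(self.table.to_string(index=False))
        if self.null_cutoffs:
            cuts = ", ".join(
                f"alpha={a}: {c:.4f}" for a, c in self.null_cutoffs.items()
            )
            lines.append(f"empirical null cutoffs: {cuts}")
        return "\n".join(lines)


def _binom_se(p_hat: float, reps: int) -> float:
    return float(np.sqrt(p_hat * (1.0 - p_hat) / reps))


def empirical_cutoff(sample: np.ndarray, alpha: float) -> float:
    """Upper-α Monte Carlo critical value: the ⌊α(R+1)⌋-th largest value.

    A new null draw exceeds it with probability m/(R+1) = α when
    α(R+1) is an integer.  Requires α(R+1) ≥ 1.
    """
    r = sample.size
    m = int(np.floor(alpha * (r + 1)))
    if m < 1:
        raise ValueError(
            f"too few null replicates ({r}) to estimate the upper-{alpha} cutoff"
        )
    return float(np.sort(sample)[r - m])


def _null_nr2_sample(cfg: StudyConfig, rng: np.random.Generator) -> np.ndarray:
    """N·r² (via EM) for ``reps`` replicates simulated with no LD.

    Uses the two-step conditional generator with D = 0, i.e. SNP A under
    the (possibly HWD) single-locus model and SNP B in HWE — exactly the
    D' = 0 member of the alternative family, so power at D' = 0 is the
    size of the test by construction.
    """
    pm = PairModel(LocusModel(cfg.p1, cfg.d_h), LocusModel(cfg.q1), d=0.0, n=cfg.n)
    tables = _alternative_tables(pm, cfg.reps, rng)
    freqs, _, _ = _em_batch(tables)
    nr2, _ = _nr2_batch(freqs, 2 * cfg.n)
    return nr2


def type1_study(cfg: StudyConfig, phase_known: bool = False) -> StudyReport:
    """Empirical size of the naive χ²₁ test of N·r² under no LD.

    Simulates ``reps`` independent SNP pairs (product multinomial of the
    two single-locus genotype distributions), estimates haplotype
    frequencies by EM, and reports, per level α, the fraction of
    replicates with N·r² above the χ²₁ upper-α quantile together with
    the inflation factor (fraction / α).  The N·r² sample is retained so
    its empirical quantiles can serve as corrected critical values.

    ``phase_known=True`` replaces the EM step with the true haplotype
    counts (requires ``d_h = 0``: with no HWD, chromosomes are i.i.d.
    and the 2n haplotypes are a simple multinomial draw); the naive test
    is then correctly calibrated.
    """
    rng = np.random.default_rng(cfg.seed_sequence().spawn(1)[0])
    if phase_known:
        if cfg.d_h != 0.0:
            raise ValueError("phase-known control is defined for HWE (d_h = 0)")
        p1, q1 = cfg.p1, cfg.q1
        hap_p = [p1 * q1, p1 * (1 - q1), (1 - p1) * q1, (1 - p1) * (1 - q1)]
        counts = rng.multinomial(2 * cfg.n, hap_p, size=cfg.reps)
        freqs = counts / (2.0 * cfg.n)
        nr2, _ = _nr2_batch(freqs, 2 * cfg.n)
    else:
        tables = _null_tables(
            LocusModel(cfg.p1, cfg.d_h), LocusModel(cfg.q1, cfg.d_h), cfg.n, cfg.reps, rng
        )
        freqs, _, _ = _em_batch(tables)
        nr2, _ = _nr2_batch(freqs, 2 * cfg.n)

    rows = []
    cutoffs = {}
    for alpha in cfg.alphas:
        chi2_cut = float(stats.chi2.isf(alpha, df=1))
        rate = float(np.mean(nr2 > chi2_cut))
        rows.append(
            {
                "alpha": alpha,
                "rate": rate,
                "se": _binom_se(rate, cfg.reps),
                "inflation": rate / alpha,
            }
        )
        try:
            cutoffs[alpha] = empirical_cutoff(nr2, alpha)
        except ValueError:
            pass  # too few replicates for this tail
    kind = "type-I error (phase known)" if phase_known else "type-I error (naive chi2)"
    return StudyReport(kind, pd.DataFrame(rows), cutoffs, nr2_null=nr2, config=cfg)


def power_study(cfg: StudyConfig) -> StudyReport:
    """Power of the Monte Carlo LD test over a grid of D' values.

    A dedicated null arm (D' = 0) supplies the empirical critical
    values; every grid arm — including D' = 0 itself, which therefore
    estimates the realised size — is an independent simulation whose
    exceedance rate over those shared cutoffs is reported.
    """
    children = cfg.seed_sequence().spawn(1 + len(cfg.dprime_grid))
    nr2_null = _null_nr2_sample(cfg, np.random.default_rng(children[0]))
    cutoffs = {a: empirical_cutoff(nr2_null, a) for a in cfg.alphas}

    rows = []
    for k, dp in enumerate(cfg.dprime_grid):
        rng = np.random.default_rng(children[1 + k])
        d = dprime_to_D(cfg.p1, cfg.q1, dp)
        pm = PairModel(
            LocusModel(cfg.p1, cfg.d_h), LocusModel(cfg.q1), d=d, n=cfg.n
        )
        tables = _alternative_tables(pm, cfg.reps, rng)
        freqs, _, _ = _em_batch(tables)
        nr2, _ = _nr2_batch(freqs, 2 * cfg.n)
        for alpha in cfg.alphas:
            power = float(np.mean(nr2 > cutoffs[alpha]))
            rows.append(
                {
                    "dprime": dp,
                    "alpha": alpha,
                    "power": power,
                    "se": _binom_se(power, cfg.reps),
                }
            )
    return StudyReport("power", pd.DataFrame(rows), cutoffs, nr2_null=nr2_null, config=cfg)


Replicate = namedtuple("Replicate", ["g_a", "g_b", "hap_counts"])
"""One simulated data set handed to a plug-in test: the two genotype
sequences and the generator's phase-known haplotype counts."""


def naive_chi2_rule(rep: Replicate, alpha: float) -> bool:
    """Plug-in rule: EM phasing then N·r² against the χ²₁ quantile."""
    table = genotype_table_from_calls(rep.g_a, rep.g_b)
    result = em_haplotype_freqs(table)
    try:
        nr2 = ld_from_haplotypes(result.freqs).Nr2
    except MonomorphicLocusError:
        return False
    return nr2 > float(stats.chi2.isf(alpha, df=1))


def phase_known_chi2_rule(rep: Replicate, alpha: float) -> bool:
    """Plug-in rule: N·r² from the true haplotype counts against χ²₁."""
    try:
        nr2 = ld_from_haplotypes(HaplotypeFreqs.from_counts(*rep.hap_counts)).Nr2
    except MonomorphicLocusError:
        return False
    return nr2 > float(stats.chi2.isf(alpha, df=1))


def comparison_hook(
    test_fn: Callable[[Replicate, float], bool],
    cfg: StudyConfig,
    dprime_grid: Sequence[float] | None = None,
) -> StudyReport:
    """Run an arbitrary LD test over the same simulated replicates.

    ``test_fn(replicate, alpha) -> bool`` decides rejection; replicates
    are generated individual-by-individual (so the plug-in sees raw
    genotype sequences and the phase-known record) from the alternative
    model at each D' in the grid.  Intended for side-by-side power
    columns against alternative LD tests.
    """
    grid = tuple(cfg.dprime_grid if dprime_grid is None else dprime_grid)
    children = cfg.seed_sequence().spawn(len(grid))
    rows = []
    for k, dp in enumerate(grid):
        rng = np.random.default_rng(children[k])
        d = dprime_to_D(cfg.p1, cfg.q1, dp)
        pm = PairModel(LocusModel(cfg.p1, cfg.d_h), LocusModel(cfg.q1), d=d, n=cfg.n)
        rejections = {alpha: 0 for alpha in cfg.alphas}
        for _ in range(cfg.reps):
            g_a, g_b, hap = simulate_alternative(pm, seed=rng, return_haplotype_counts=True)
            rep = Replicate(g_a, g_b, hap)
            for alpha in cfg.alphas:
                if test_fn(rep, alpha):
                    rejections[alpha] += 1
        for alpha in cfg.alphas:
            rate = rejections[alpha] / cfg.reps
            rows.append(
                {
                    "dprime": dp,
                    "alpha": alpha,
                    "power": rate,
                    "se": _binom_se(rate, cfg.reps),
                }
            )
    return StudyReport("comparison", pd.DataFrame(rows), config=cfg)
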