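# Methods

## The statistical problem

Two bi-allelic SNPs, alleles A1/A2 (frequencies p1, p2) and B1/B2 (q1, q2).
With phased data the four haplotype counts are observed, and

    r² = D² / (p1·p2·q1·q2),      D = f(A1B1) − p1·q1,

satisfies N·r² = Pearson χ² of the 2×2 haplotype table (N = chromosomes = 2n
individuals), so N·r² ~ χ²₁ under independence.  With unphased genotypes the
only ambiguous configuration is the double heterozygote, which is either
coupling (A1B1/A2B2) or repulsion (A1B2/A2B1); haplotype frequencies must be
estimated, and the plug-in N·r̂² is stochastically larger than χ²₁ under the
null.  At p1 = q1 = 0.5 (the worst case — double-heterozygote frequency is
maximal) the unphased maximum-likelihood estimator of D has asymptotically
twice the phased-data variance, so N·r̂² ≈ 2·χ²₁: the naive test's true size
at nominal 0.05 is P(χ²₁ > 3.84/2) ≈ 0.166, and the relative inflation grows
without bound in the tail (≈ 7× at 0.01, ≈ 20× at 0.001).  The package's
simulations reproduce these rates, and a phase-known control (the same
statistic computed from the generator's true haplotype counts) restores
nominal size, isolating estimation variability as the cause.

## EM haplotype-frequency estimation (`ldmc.em`)

The sufficient statistic is the 3×3 table of (copies of A1, copies of B1).
Each cell except (1,1) contributes deterministic haplotype counts; the E-step
splits each double heterozygote between coupling, with weight
w = f11·f22 / (f11·f22 + f12·f21), and repulsion with weight 1 − w; the M-step
divides expected haplotype counts by 2n.  Details:

- **Likelihood.**  Multinomial over the 9 genotype cells with probabilities
  given by random union of haplotypes (e.g. P(1,1) = 2·f11·f22 + 2·f12·f21).
  HWE at the haplotype level is assumed *inside the likelihood* even when data
  are generated under HWD; the resulting bias of likelihood-based estimation
  under HWD is a study subject, not a defect to patch.
- **Initialisation.**  Linkage equilibrium at the sample allele frequencies —
  deterministic and unbiased toward either phase.  The allele margins are
  phase-invariant, so every iterate (and every stationary point) keeps the
  sample allele frequencies; only the 1-D coupling split is estimated.  This
  is also why a brute-force grid search over f11 with fixed margins is a valid
  independent oracle for the EM answer, used in the tests.
- **Convergence.**  Max absolute frequency change < 1e-8, at most 1000
  iterations (typically 20–80 at n = 1000); far below any tolerance that could
  move N·r² at the sample sizes involved.  When w is 0/0 (both phase products
  zero) it is set to 1/2.  Tables without double heterozygotes return the
  closed-form counting estimate in one step.
- **Missing data.**  Pairwise deletion before tabulation.
- **Batch path.**  `_em_batch` runs the identical update vectorised over a
  stack of tables (the bootstrap and the studies fit 10⁴–10⁶ tiny tables);
  a test asserts exact table-for-table agreement with the scalar EM.

## LD measures (`ldmc.ld`)

D' uses the Lewontin bound — D_max = min(p1·q2, p2·q1) for D > 0,
min(p1·q1, p2·q2) for D < 0 — and is defined as 0 at D = 0 to avoid 0/0.
Haplotype-frequency vectors are validated to sum to 1 within 1e-9 (smaller
deviations renormalised, larger ones rejected).  A monomorphic locus makes
every LD measure undefined and raises `MonomorphicLocusError`; policy is the
caller's (see the bootstrap below).

## The Monte Carlo test (`ldmc.mctest`)

Under the null the two SNPs' genotypes are independent, so a null data set is
manufactured from the observed one by resampling the n single-locus genotypes
with replacement at each SNP and pairing the two resampled multisets in random
order.  Whole genotypes — never individual alleles — are resampled, which
preserves each locus's own genotype distribution exactly; this is what keeps
the test valid under Hardy-Weinberg disequilibrium.  Each of the B replicates
is pushed through EM and N·r², giving the null sample.

- **Implementation.**  Resampled genotype counts are multinomial draws at the
  empirical genotype frequencies, and the random pairing given the two margins
  is a sequential multivariate-hypergeometric table — identical in law to
  resampling and shuffling sequences, but vectorisable across all B replicates.
- **Degenerate replicates.**  A resampled locus can come out monomorphic (it
  is astronomically rare at common allele frequencies and n = 1000); such
  replicates contribute statistic 0 — no evidence of LD — and are counted in
  `n_degenerate`.  Redrawing instead would bias the null sample's
  allele-frequency spread.
- **P-value.**  (1 + #{null ≥ observed}) / (B + 1), the standard add-one Monte
  Carlo convention: never exactly 0, conservative under ties.  Default
  B = 10,000.
- **Determinism.**  One seedable generator per invocation; identical
  (data, B, seed) replays bit-identically.

## Simulators (`ldmc.simulate`)

Genotype frequencies at one locus are (p1² + D_H, 2·p1·p2 − 2·D_H, p2² + D_H);
the feasible D_H range [−min(p1², p2²), p1·p2] is enforced with an explicit
message.  As the algebra shows, positive D_H *lowers* heterozygosity.  The
null simulator draws the two loci independently (equal in law to the 9-cell
product multinomial).  The alternative simulator draws SNP A genotypes from
the single-locus model, assigns the two alleles of a heterozygote to the two
homologous chromosomes (deterministically — the assignment is exchangeable),
and draws each chromosome's B allele from P(B1|A1) = q1 + D/p1 or
P(B1|A2) = q1 − D/p2, so the true haplotype frequencies are f11 = p1·q1 + D
etc., and locus B is conditionally in HWE by construction.  The generator can
return its phase-known haplotype counts, used by the phase-known control and
by consistency tests.  `dprime_to_D` maps a target D' to D = sign·D'·D_max.
Batch variants produce (reps, 3, 3) tables directly from stratified
multinomials — equal in law to per-individual simulation.

## Study drivers (`ldmc.experiments`)

Study conditions default to the design of record: p1 = q1 = 0.5, n = 1000
individuals per replicate, 10,000 replicates, D' grid 0 to 0.25 in steps of
0.025, levels 0.05/0.01/0.001.  The acceptance script runs the full 10,000;
the test suite uses 2,000 replicates with 3-binomial-SE tolerances.

- **Type-I study.**  Fraction of null replicates with N·r̂² above the χ²₁
  upper-α quantile, with binomial SE and inflation factor (rate/α), plus the
  retained null sample and its empirical quantiles.  `phase_known=True`
  replaces EM with true haplotype counts (HWE only: with D_H = 0 the 2n
  haplotypes are an i.i.d. multinomial sample).
- **Power study.**  A dedicated D' = 0 arm supplies empirical critical values;
  the cutoff at level α is the ⌊α(R+1)⌋-th largest of the R null statistics
  (at R = 10,000 and α = 0.001, the 10th largest).  Every grid arm — including
  D' = 0, which thereby estimates the realised size — is an independent
  simulation scored against those shared cutoffs.  Sharing cutoffs across arms
  mirrors how such power tables are constructed; running an independent D' = 0
  arm (rather than re-scoring the cutoff arm) makes the calibration row an out-
  of-sample estimate.
- **Comparison hook.**  Alternative LD tests published without reproducible
  formulas (the composite-LD χ² and the δ-method asymptotic test) are not
  reimplemented; `comparison_hook` runs any user-supplied rejection rule over
  the same simulated replicates (each rule sees the raw genotype sequences and
  the phase-known record), enabling side-by-side power columns.
- **Seeding.**  A master seed spawns one `SeedSequence` child per arm, so arms
  are reproducible in any order.

## Synthetic data vs. real data

The simulators generate exactly two loci with known allele frequencies, no
genotyping error, missingness-free calls, and (for the alternative) HWD at
SNP A only.  Real genotype data add missingness (handled by pairwise
deletion), genotyping error, and allele-frequency estimation at both loci
under arbitrary HWD — the bootstrap handles the latter by construction, but
passing simulation studies here does not certify behaviour under genotyping
artefacts or for rare variants (small allele counts make EM and the bootstrap
grainy; the degenerate-replicate policy then matters and p-values become
conservative).

## Known limitations

- Two loci only; no multi-SNP haplotype estimation.
- Single-pair testing; no multiplicity correction across pairs.
- The bootstrap costs B EM fits per tested pair (milliseconds here, but
  genome-wide all-pairs scanning is out of scope).
- At α = 0.001 with B = 10,000 the p-value granularity is ~1e-4; detecting
  smaller p-values needs larger B.
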