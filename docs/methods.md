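# Methods

## The association model

Methylation of CpG *i* in sample *j* is observed as a proportion
`m_ij = meth_ij / T_ij` from `T_ij` sequenced reads, strands pooled.  The
association model for a lipid trait is a binomial GLM with logit link,

    logit E[m_ij] = β0_i + β1_i · trait_j + γ_iᵀ · x_j,

weighted by the coverage `T_ij`, with covariates x = (age, sex, BMI,
capture-panel batch, optionally cell proportions with one column dropped to
break the simplex collinearity).  The trait is prepared once per cohort:
log-transformed when right-skewed (TG here), trimmed in a single pass at
mean ± 3 SD of the pre-trim distribution (the trim is **not** iterated), and
standardized, so β1 is in logit units per SD of trait.  β1 is tested with a
two-sided Wald z.  The weighted-binomial likelihood treats `T·m` methylated
reads out of `T` as the outcome; it is correct under pure binomial sampling
and deliberately ignores extra-binomial dispersion — miscalibration from
overdispersion is handled post hoc by the empirical-null step, which mirrors
the two-stage practice of sequencing EWAS rather than fitting a
beta-binomial per site.

Fitting is batched Newton/IRLS: all CpGs share the design matrix, missing
entries carry zero weight, and each iteration solves the per-CpG p×p normal
equations with a batched solve (einsum + `np.linalg.solve`).  Convergence is
declared when the largest score-equation component falls below 1e-8 (at most
50 iterations); a 1e-10 ridge keeps near-separated systems solvable, and
fits with runaway coefficients (|β| > 1e3) or non-convergence are flagged
with missing z rather than raised.  Against a generic maximum-likelihood
oracle (statsmodels GLM) the batched fitter agrees to ~1e-11 on random
instances; the test suite asserts 1e-6.

## Empirical-null recalibration

Raw z-scores from sequencing EWAS are biased and inflated by unmodelled
count overdispersion and residual structure.  The z vector is modelled as a
three-component Gaussian mixture — a dominant null `w0·N(μ0, σ0²)` flanked
by two signal components with means constrained at least 3σ0 below/above μ0
— fitted by EM with deterministic moment/quantile initialization (median,
MAD; signal components seeded at μ0 ± 4 MAD with weight 0.05 each).  The
separation constraint is the identifiability device: without it the signal
components absorb the null tails and σ0 is biased down.  Convergence is a
relative log-likelihood change below 1e-10 (up to 500 iterations); on
non-convergence the estimator falls back to the median/MAD null with a
warning flag.  Corrected statistics are `z' = (z − μ0)/σ0` with two-sided
normal p-values.  The estimator recovers a planted (bias, inflation) of
(0.2, 1.3) within ±0.05 at n = 10,000 and keeps σ0 within ±0.1 under 5%
signal contamination at |mean| = 4.

The genomic inflation factor is `λ = median(z²) / 0.4549364` (the χ²(1)
median).  On the default synthetic study λ(raw) ≈ 1.9 and λ(corrected) ≈
1.0.

Multiplicity is controlled per trait (each trait separately): Storey
q-values with π0 estimated on the λ-grid 0.05…0.95 (step 0.05) through a
cubic polynomial smoother evaluated at λ = 0.95, falling back to π0 = 1
(pure Benjamini–Hochberg) when fewer than 100 p-values or the estimate
exceeds 1; and the classical Bonferroni cutoff α/n_tests for replication
dissections.  Flagged (unfitted) records are excluded from the
multiplicity denominator.

## Regions and the positional statistic

Elements are half-open intervals `[start, end)`; all coordinates in the
package are 0-based half-open.  The positional statistic of a CpG in its
element is `(pos − midpoint)/length × 100` with the real-valued midpoint
`(start+end)/2` (no rounding, keeping the statistic exactly antisymmetric);
for promoters the sign is flipped when the TSS strand is '−' so positive
values point into the gene body.  UMR profiles are restricted to promoters
whose annotated TSS lies inside the element and within ±1.5 kb of the
element midpoint and that are not flagged bivalent — the window is anchored
at the midpoint because the generator places the TSS there; for external
element files the same rule applies to the annotated TSS, which is one of
several defensible readings of a "TSS ± 1.5 kb" restriction.

Enrichment contrasts are two-sided Fisher exact tests on [[a, b−a],
[c, d−c]] with the fold change `(a/b)/(c/d)` rounded **half-up** to one
decimal, matching printed fold-change tables.  The background includes the
foreground (count pairs such as 362/567 vs 22101/50759 are overlapping
sets).  The two-sided p sums hypergeometric outcomes at most as probable as
the observed table; it matches an exhaustive enumeration oracle on every
2×2 table with total ≤ 60.  Degenerate margins give p = 1 with a flag.

## Replication and fine-mapping

A discovery (region, trait) pair replicates when ≥1 CpG of the region
passes the per-trait Bonferroni cutoff in the replication cohort.  The
default Bonferroni denominator is the number of replication tests for that
trait across all candidate regions (a per-region denominator is available —
the choice is genuinely open; the global denominator is the more
conservative reading).  Region direction is the sign of its top (smallest
p, ties to the leftmost coordinate) CpG; classes are
same-direction/opposite-direction/not-replicated/untestable, which
partition the candidate set.  The fine-mapping contrast evaluates regions
with ≥2 discovery CpGs where one coincides with the replication top CpG and
calls the region "refined" when a non-overlapping CpG has a smaller
corrected p; evaluated CpGs are classed into positional bands (LMR midpoint
band |pct| ≤ 20; UMR bimodal band 20 ≤ |pct| ≤ 45).

## Integration

metQTL: per CpG×SNP pair within ±250 kb (inclusive), a covariate-adjusted
linear model of the methylation proportion on allele dosage.  The fits use
the Frisch–Waugh–Lovell projection — methylation and dosages are
residualized on the covariates once per CpG, making each pair test a scalar
correlation with exact OLS t statistics — and q-values are computed over
all tests genome-wide (per-cohort), the more conservative reading of an
"FDR 10%" rule whose scope is not fixed by convention.  An element is
"under genetic regulation" when ≥1 resident CpG has a significant metQTL.
Methylation enters QTL and expression fits on the proportion scale.

Methylation–expression association: Gaussian model `m ~ expression +
covariates` against the covariate-only null within ±1 Mb, tested by
likelihood ratio, `LRT = n·log(RSS0/RSS1)` with p from χ²(1); equal to a
two-fit oracle to 1e-8.  Distances are CpG (or element midpoint, for
element summaries) to the nearest edge of the transcribed region.
Expression–trait association uses the same LRT per gene.  Conditional
EWAS re-fits the weighted-binomial trait model with a SNP dosage appended
and reports the attenuation p_cond/p_marginal.  All integration fits are
fixed-effects models: the synthetic cohort has unrelated individuals, so
family/zygosity random effects have no meaning here.

## The synthetic study

The generator emulates the *statistical structure* the analysis assumes,
on one 10 Mb toy chromosome:

- **Elements** — disjoint LMRs (length ≈ 600 bp, ~7 CpGs each) and UMRs
  (≈ 2200 bp, ~37 CpGs, TSS at the element midpoint with random strand,
  5% flagged bivalent); 40% adipose-specific, the rest tissue-shared.
- **Counts** — per CpG/sample, latent `logit π = α_i + β_i·trait(std) +
  γ_i·dosage + ε`, with class-dependent baselines (promoters ~5%
  methylated, enhancers ~25%, background ~85%), sample noise ε ~ N(0, 0.1),
  beta-binomial draws with overdispersion ρ = 0.02 on negative-binomial
  totals (mean 33×, dispersion 0.3) split binomially between strands.
  ρ = 0.02 is a free parameter — the overdispersion of real capture
  bisulfite counts is not pinned down — chosen to produce visible but
  correctable inflation (λ ≈ 1.9).
- **Phenotypes** — TG log-normal, HDL/LDL/TC normal on mmol/L-like scales,
  coupled by an exchangeable latent correlation 0.3; age, sex
  (Bernoulli 0.6 female), BMI > 40 (severely obese cohort), a two-level
  capture-panel batch (~55/45), Dirichlet(5,3,2,1,1) cell proportions.
- **Planted effects** — lipid effects are planted element-wise (whole
  elements become lipid-linked, 1% of CpGs by default, ±0.3 logit per SD);
  metQTL CpGs get ±0.5 logit per allele from the nearest SNP within 50 kb;
  expression links (slope ±15 per unit methylation, noise SD 1) attach
  genes at mixed ranges — half proximal (<100 kb), half long-range
  (200–800 kb) — to variable lipid CpGs.  The replication cohort shares
  the genomic scaffolding and truth registry but has independent samples,
  and only effects inside tissue-shared elements are active.
- **Array mask** — a CpG subsample capturing 6% of LMR CpGs and 19% of UMR
  CpGs, emulating sparse array designs.

All randomness flows from one root seed through named `SeedSequence`
substreams; a fixed (seed, config) reproduces every output byte-for-byte.

What the generator does **not** emulate: read-level artefacts (clonal
reads, mapping error, bisulfite-conversion failure), LD between SNPs,
realistic CpG spacing/co-methylation, cell-type heterogeneity driving
methylation, or twin/family structure.  Passing tests therefore show the
statistical machinery is correct under the stated model, not that the
pipeline is robust to alignment-level artefacts, which are out of scope
(they act on BAMs upstream of the per-CpG counts this package consumes).

### Truth definition for recovery tests

The four lipid traits are correlated by construction, so a CpG planted for
one trait is genuinely (marginally) associated with the others.  Recovery
tests and the acceptance script therefore count a q ≤ 0.10 call as a true
discovery when its CpG carries a planted effect for *any* trait; the
realized false-discovery proportion under this definition averages ~0.11
over ten seeds at the default scale, within the Monte-Carlo band of the
nominal 0.10.

## Problem sizes

The default study is 200 samples and ~19,500 CpGs (400 LMRs + 400 UMRs
plus 10% background CpGs), chosen so one full simulate→QC→EWAS→adjust pass
takes ~20 s on one CPU; the end-to-end recovery test runs ten seeds at this
scale.  The analysis scripts use 120 samples and ~5,700 CpGs for
interactive turnaround.  Null-calibration tests use ≥2,000 null CpGs with
pure binomial counts; empirical-null recovery uses n = 10,000 statistics.

## Known limitations

- The empirical-null EM assumes an approximately Gaussian null; heavy
  non-Gaussian tails of beta-binomial z-scores are only partially absorbed,
  so the realized FDR at q ≤ 0.10 can sit slightly above nominal (~0.11
  here) — the same compromise the two-stage recalibration approach makes on
  real data.
- π0 smoothing uses a cubic polynomial on the λ-grid, not a spline with
  df selection; for very non-uniform p distributions the fallback π0 = 1
  makes q-values conservative.
- Fisher enrichment treats overlapping foreground/background as
  independent rows of the 2×2 table, as the printed contrasts do; the p is
  therefore approximate for nested sets, while the fold is exact.
- The conditional-EWAS attenuation ratio compares p-values, not effect
  sizes; it is a screening diagnostic, not a formal mediation estimate.
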