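# Methods

This note documents the statistical models implemented in `t2drep`, the
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical choices that matter when reading
results.

## Study design being modelled

An unmatched case-control replication study: a clinic-ascertained series of
young-onset type 2 diabetes cases and a population-survey control sample,
genotyped at the lead SNPs of loci discovered at genome-wide significance
in a reference (European) population.  The cohort sizes used throughout as
defaults are 830 cases and 1497 controls (878/1523 genotyped before the
call-rate filter), with three self-identified ethnolinguistic strata at
proportions 0.863 / 0.054 / 0.083 and one X-chromosome SNP in the panel.
Trace categories (≤0.3% of the population) are omitted from the default
strata because at this sample size they produce only degenerate CMH strata;
they can be configured explicitly.

## Synthetic cohort generator

**Model.**  Genotypes are independent across SNPs (the panel is one lead
SNP per locus, so linkage disequilibrium adds nothing testable).  Within
stratum *s*, the risk-allele frequency is `p + offset_s`, clipped to
(0.01, 0.99); genotypes follow Hardy–Weinberg proportions
(q², 2pq, p²) with the heterozygote class optionally multiplied by a
violation factor and renormalised.  Males are hemizygous at X SNPs (dosage
0/1).  Disease is assigned by

    logit P(D) = β₀ + Σ_i ln(OR_i)·g_i + γ_s ,

where γ_s is an optional stratum disease offset.  The intercept β₀ is
found by bisection so that the *population* expectation of P(D) equals the
target prevalence K (default 0.10) to 1e-6.  That expectation is computed
exactly by convolving the per-SNP atom distributions of the genetic linear
predictor on a 1e-4 log-odds grid, per stratum-by-sex cell — no Monte
Carlo inside the calibration loop.  Cases and controls are then obtained
by rejection sampling from the calibrated population, which is how a
cross-sectional control survey and a clinic case series actually arise and
keeps logistic-recovery tests honest.  A draw cap (default 20× the
expected required population) turns pathological configurations into an
explicit error rather than a hang.

**Covariates.**  Age is assigned after case/control status — uniform on
(20, 60) for cases and (25, 75) for controls — which is valid because age
does not enter the disease model, and mirrors the younger-case profile of
the design.  The ranges were calibrated once against the published
behaviour of the two association analyses: with near-disjoint ranges, age
becomes almost deterministic of status, which inflates conditional odds
ratios through non-collapsibility and decorrelates the adjusted-logistic
and CMH estimates (r ≈ 0.73), contradicting the published panel where the
two analyses agree closely (mean |ΔOR| ≈ 0.03, "highly correlated").  With
the adopted overlap the simulator reproduces that behaviour
(r ≈ 0.98, mean |ΔOR| ≈ 0.02).  Sex is male with probability 0.44 for
everyone, independent of disease.

**Missingness.**  Each genotype call is missing independently with
`missing_rate`; additionally, `round(bad_sample_rate × n)` randomly chosen
samples are degraded to a call rate strictly below 0.8 (at least
⌊0.2·S⌋+1 missing calls out of S SNPs), so the call-rate filter removes a
deterministic count — matching the bookkeeping-arithmetic checks.

**What it does not emulate.**  No linkage disequilibrium, imputation,
relatedness, genotyping-batch artifacts, or continuous admixture; ages are
uniform rather than survey-shaped; exclusion flags default to zero and are
set directly by tests.  Passing tests therefore demonstrate correctness of
the estimators under the design's idealised statistical structure, not
robustness to real-data artifacts.

## Quality control

Exclusion reasons are evaluated in a fixed order (missing GADA → GADA
positive → early insulin → mitochondrial), each sample counted once under
the first matching rule; the published arithmetic (965 − 29 − 48 − 10 =
878) implies the groups were disjoint, and the rule order makes overlap
handling deterministic.  The call-rate filter uses strict inequality
(< 0.80) with all genotyped SNPs in the denominator and runs *before* HWE
testing, so HWE counts are computed on post-filter samples.  HWE uses the
1-df asymptotic goodness-of-fit chi-square with the allele frequency
estimated from the counts, tested in controls by default; a monomorphic
SNP is a defined degenerate result (χ² = 0, p = 1, flagged), and an exact
conditional test is available behind a switch but off by default, since
the pipeline being reproduced used a plain p < 0.001 chi-square cut.  At
n ≈ 1500 the asymptotic test is essentially exactly calibrated (measured
type-I rate ≈ 1.0×10⁻³ at α = 10⁻³ over 4×10⁵ null SNPs).  X SNPs are
excluded from pooled HWE testing (hemizygous males are not a diploid
class); a females-only test is reported instead.  The config validates
0 < call-rate threshold ≤ 1; a threshold of exactly 0 is outside the
domain (any sample trivially passes), and identity behaviour is exercised
at an arbitrarily small positive threshold.

## Association

Dosages are oriented so they count the designated risk allele (complement
2−g, or 1−g for hemizygous males).  The log-additive logistic fit is
Newton maximum likelihood (statsmodels), complete-case per SNP, with Wald
CIs and p-values — matching the reporting conventions of the standard
tools this pipeline reproduces.  Covariates that make the design
rank-deficient (e.g. sex against a single-sex subset) are dropped and
recorded; separation or non-convergence yields a flagged result with
diagnostics rather than a silent NA.  The CMH analysis is built on allelic
2×2×K tables (2 alleles per diploid sample, 1 per male X genotype), the
classical form for SNP data: Mantel–Haenszel pooled OR,
Robins–Breslow–Greenland variance for the 95% CI, and the 1-df CMH
chi-square without continuity correction.  Strata with an all-zero margin
are skipped with a note; a single remaining stratum degenerates to the
ordinary allelic 2×2.  No multiple-testing correction is applied anywhere;
nominal significance is p ≤ 0.05 *inclusive* (the reproduced panel counts
loci printed at p = 0.048–0.049 as significant, which pins the inclusive
rule).

Under Hardy–Weinberg genotype frequencies the genotype-dosage logistic OR
and the allele-count CMH OR estimate the same per-allele quantity; on
simulated data they agree to within ~5%, a documented approximation, and
their estimates across a 36-SNP panel correlate at r > 0.95.

## Genetic risk score

Weights are w = ln(OR) of *reference-population* odds ratios — never the
study's own fit, to avoid winner's-curse circularity (the packaged result
table deliberately ships its reference columns empty; simulation-based
checks use the design ORs as the reference surrogate).  The raw score
Σ w·g is rescaled by N / Σ_available w, i.e. normalised to the mean-weight
scale and inflated to the full SNP count, so a unit is one average-effect
risk allele and individuals with missing genotypes remain comparable; with
complete data the rescaling is the identity on that scale.  The exact
printed form of the source's rescaling equation is not recoverable from
the available text (the equations appear only as images); the weight-sum
dialect above follows the cited rescaling convention, and a SNP-count
dialect (N/n_available on the mean-weight scale) is implemented behind a
switch — the two coincide for complete data.  The score is invariant to
positive rescaling of all weights, exactly.  Availability floor:
individuals with fewer than ⌈0.8·N⌉ genotypes (29 of 36) are excluded;
an individual whose available weights sum to ≤ 0 is flagged unscorable.
X dosages enter on the X-inactivation scale (male 0/1; female 0, 0.5, 1).

Quintile cut-points come from the pooled cases+controls score distribution
(the usual convention for risk-gradient figures; the source is silent),
assigned by rank so group sizes differ by at most one, with tied values at
a boundary all taking the lower quintile.  The per-unit OR adjusts for age
and sex; quintile ORs additionally adjust for stratum, mirroring the
published analysis descriptions.

## Trans-ethnic comparison

Directional consistency requires matching risk alleles and a
reference-oriented study OR above 1.  A study OR printed as exactly 1.00
counts as consistent by default: printed two-decimal precision masks an OR
marginally above 1, and this convention reproduces the published headline
count (31 of 36) — `ties="strict"` gives the conservative count (30).  The
sign test is the exact binomial tail P(X ≥ k | n, ½) in rational
arithmetic (for 31/36: 443704/2³⁶ ≈ 6.5×10⁻⁶; the source's printed
3.2×10⁻⁶ is not reproducible as an exact tail, mid-p, or normal
approximation, and the exact tail is reported).  Correlations are Pearson,
computed on raw ORs by default (matching scatter-plot axes) with a log
option, and fail loudly on fewer than 3 pairs or zero variance.

## Power

Power for the two-sided α-level test of the per-allele log OR (default
α = 0.05, K = 0.10): population genotype probabilities from HWE,
penetrances from the log-additive logistic model with the intercept solved
for K (Brent, 1e-13), case/control genotype distributions by Bayes
inversion, and the noncentrality |ln OR| / SE where SE² is the (2,2) entry
of the inverse expected Fisher information of the prospective logistic fit
over the case-control genotype mixture (the retrospective sample analysed
prospectively, with the intercept shifted by the sampling-fraction
log-odds).  At OR = 1 the power equals α exactly.  This is the standard
score-test formulation of case-control power; exactness to any particular
desktop calculator's output is not claimed, but the formula matches
Monte-Carlo power from the cohort simulator to within binomial error
(≈0.5 percentage points) across RAF ∈ {0.1, 0.3, 0.5} × OR ∈ {1.1, 1.3,
1.5} at 830/1497 with 2000 simulated cohorts per cell.

## Problem sizes used by the shipped checks

Parameter recovery: 200 replicates of 830/1497 at RAF 0.34, OR 1.38.
Risk-score gradient: 10–15 replicates at n = 2327 under the 36-SNP panel.
Power grid: 9 cells × 2000 simulated cohorts.  HWE calibration: 1–2×10⁵
null SNPs at n = 1497.  Type-I calibration of the logistic fit: 1000
replicates at 150/250.  These sizes give Monte-Carlo standard errors well
inside the asserted tolerances while keeping the full suite to a few
minutes on one CPU.

## Known limitations

* The simulator's independence and HWE assumptions make it a verification
  harness, not a population-genetic model; see "What it does not emulate".
* Wald inference near separation (tiny strata, near-monomorphic SNPs) is
  flagged rather than repaired; no Firth or exact logistic fallback.
* The power module covers the log-additive unmatched design only; no
  dominant/recessive modes or sample-size inversion.
* Reference-population ORs/RAFs are user-supplied inputs; nothing in the
  package re-derives them.
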