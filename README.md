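# t2drep

Statistical toolkit for candidate-SNP replication studies of type 2
diabetes (T2D), built around the design of a Sri Lankan case-control study
that genotyped the lead SNPs of 37 European genome-wide-significant T2D
loci in 878 cases and 1523 normoglycaemic controls.  The package is aimed
at genetic epidemiologists who need the full analysis chain of such a
study — quality control, per-SNP association, risk scores, trans-ethnic
comparison, power — as tested, reusable code, together with a synthetic
cohort generator that reproduces the study's statistical structure (no
individual-level genotypes were ever deposited).

## What it computes

**Quality control.**  Case-definition exclusions (missing/positive GADA
autoantibodies, insulin within 6 months of diagnosis, mitochondrial
diabetes), removal of samples with overall genotype call rate < 80%, and
removal of SNPs out of Hardy–Weinberg equilibrium in controls
(1-df chi-square, p < 0.001), with full bookkeeping
(input = kept + excluded at every step).

**Per-SNP association.**  For each SNP, oriented to its risk allele:

* a log-additive logistic regression, logit P(D=1) = β₀ + β·g + covariates
  (age, sex), reporting the per-allele odds ratio e^β with Wald 95% CI and
  p-value;
* the Cochran–Mantel–Haenszel test over allelic 2×2 tables stratified by
  ethnolinguistic subgroup (Sinhalese / Tamil / Muslim), with the
  Mantel–Haenszel pooled OR, Robins–Breslow–Greenland CI, and the 1-df CMH
  chi-square without continuity correction.

**Weighted genetic risk score.**  For individual *j* with available
genotypes A(j),

    raw_j = Σ_{i ∈ A(j)} w_i g_ij ,   w_i = ln(OR_i)  (reference-population ORs)

rescaled to the full panel of N SNPs,

    GRS_j = raw_j × N / Σ_{i ∈ A(j)} w_i ,

so one unit is one average-effect risk allele; individuals with genotypes
for fewer than 80% of SNPs (29 of 36) are excluded.  X-chromosome dosages
enter on the X-inactivation scale (males 0/1, females 0/0.5/1).  The score
relates to disease by a per-unit OR (logistic, adjusted for age and sex)
and by quintile ORs versus the lowest quintile (additionally adjusted for
stratum).

**Trans-ethnic comparison.**  Directional-consistency counts (same allele
risk-increasing in both populations) with an exact binomial sign test,
Pearson correlations of OR and risk-allele-frequency vectors, and nominal
significance tallies (p ≤ 0.05).

**Power.**  Analytic power for the two-sided per-allele test under the
log-additive model: HWE genotype probabilities, penetrances from the
logistic model with the intercept solved for a 10% population prevalence,
case/control genotype distributions by Bayes inversion, and a Wald/score
noncentrality from the expected Fisher information of the case-control
mixture.

**Synthetic cohorts.**  `simulate_cohort` draws genotypes from (optionally
perturbed) HWE proportions within strata, assigns disease through the
log-additive logistic model with its intercept calibrated by bisection so
population prevalence hits the target exactly, and rejection-samples cases
and controls — so every estimator above can be validated against known
truth.

## Worked example

```python
import numpy as np, pandas as pd
import t2drep as t

ann = t.load_table1()                 # packaged 36-SNP result table
rows = t.build_comparison(ann)
t.count_consistent(rows)              # -> (31, 36)
t.binomial_sign_test(31, 36)          # -> 6.46e-06
t.nominal_counts(rows)                # -> (n_adjusted=16, n_cmh=17, n_overlap=14)

# simulate a cohort whose truth is the published panel: 830 / 1497
cohort = t.simulate_cohort(t.config_from_annotations(ann, seed=7))
res = t.run_association_panel(cohort, ann)
res.loc[res.snp_id == "rs7903146",
        ["risk_allele", "raf", "or_adjusted", "p_adjusted", "or_cmh"]]
#   risk_allele    raf  or_adjusted  p_adjusted  or_cmh
#             T  0.356       1.3856     1.5e-06   1.348

w = pd.Series(np.log(ann["or_adjusted"].to_numpy()), index=ann["snp_id"])
scores = t.compute_grs(cohort, w, x_snps=t.x_snp_ids(ann))
t.grs_association(cohort, scores)
# per-unit OR 1.109 (95% CI 1.088-1.130), p = 3.8e-26, n = 2327
t.quintile_analysis(cohort, scores)[["quintile", "odds_ratio"]]
# quintiles Q1..Q5 -> 1.00, 1.64, 1.99, 2.78, 4.49

t.analytic_power(t.PowerRequest(raf=0.34, per_allele_or=1.38,
                                n_cases=830, n_controls=1497))
# analytic_power=0.999, case RAF 0.407, control RAF 0.333
```

The first block reproduces the published counting claims exactly: 16 of 36
SNPs nominally associated in the adjusted analysis, 17 in the CMH analysis
(14 overlapping), and 31 of 36 odds ratios directionally consistent with
the European reference (exact one-sided binomial p = 6.5×10⁻⁶).  The
simulated blocks recover the panel's effect sizes and show the risk-score
gradient: individuals in the top GRS quintile have several-fold higher
odds of T2D than the bottom quintile.

A command-line interface mirrors the library:

```bash
t2drep simulate sim.yaml --out cohort.tsv
t2drep qc cohort.tsv --out clean.tsv --report qc.json
t2drep assoc clean.tsv --out association.tsv
t2drep grs clean.tsv --weights-file reference.tsv --out scores.tsv
t2drep compare                       # counting claims from the packaged table
t2drep power --raf 0.34 --or 1.38 --n-cases 830 --n-controls 1497
t2drep run run.yaml                  # full pipeline with manifest
```

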