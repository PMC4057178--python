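"""Per-SNP case-control association.

Two analyses per SNP, both oriented to the risk allele:

* a log-additive (per-allele) logistic regression of case status on risk
  allele dosage, adjusted for age and sex, with Wald CIs and p-values;
* a Cochran–Mantel–Haenszel test on allelic 2x2 tables stratified by
  ethnolinguistic subgroup (2 alleles per diploid sample, 1 per hemizygous
  male X genotype), with the Mantel–Haenszel pooled odds ratio, a
  Robins–Breslow–Greenland 95% CI, and the 1-df CMH chi-square without
  continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .annotations import x_snp_ids
from .cohort import ploidy, snp_columns

__all__ = [
    "MonomorphicError",
    "LogisticFit",
    "CmhFit",
    "orient_to_risk_allele",
    "fit_logistic_additive",
    "cmh_test",
    "run_association_panel",
    "AssociationPanel",
]


class MonomorphicError(ValueError):
    """The SNP has no dosage variation in the analysis sample."""


@dataclass(frozen=True)
class LogisticFit:
    """Per-allele logistic regression result for one SNP."""

    odds_ratio: float
    ci_lo: float
    ci_hi: float
    p_value: float
    beta: float
    se: float
    n_used: int
    converged: bool
    dropped_covariates: tuple[str, ...] = ()
    message: str = ""


@dataclass(frozen=True)
class CmhFit:
    """Stratified allelic Mantel–Haenszel result for one SNP."""

    odds_ratio: float
    ci_lo: float
    ci_hi: float
    p_value: float
    chi_square: float
    n_used: int
    n_strata_used: int
    notes: tuple[str, ...] = ()


def orient_to_risk_allele(
    dosages: pd.Series,
    annotation: pd.Series,
    sex: pd.Series | None = None,
    which: str = "study",
) -> pd.Series:
    """Re-code dosages so they count the designated risk allele.

    Stored dosages count ``effect_allele``.  If the risk allele is the
    other allele the dosage is complemented: ``2 - d`` for diploid
    genotypes, ``1 - d`` for hemizygous male X genotypes (``sex`` required
    for X SNPs).  Missing stays missing.
    """
    risk = annotation[f"risk_allele_{which}"]
    if risk == annotation["effect_allele"]:
        return dosages
    if risk != annotation["other_allele"]:
        raise ValueError(
            f"{annotation['snp_id']}: risk allele {risk!r} is not one of the SNP's "
            f"alleles ({annotation['effect_allele']}/{annotation['other_allele']})"
        )
    is_x = str(annotation["chromosome"]).upper() == "X"
    if is_x:
        if sex is None:
            raise ValueError("sex is required to orient an X-chromosome SNP")
        max_dose = np.where(sex.to_numpy() == "M", 1.0, 2.0)
    else:
        max_dose = 2.0
    return pd.Series(max_dose - dosages.to_numpy(dtype=float), index=dosages.index, name=dosages.name)


def _design_matrix(cohort: pd.DataFrame, dosage: pd.Series, covariates) -> pd.DataFrame:
    X = pd.DataFrame({"dosage": dosage.to_numpy(dtype=float)}, index=cohort.index)
    for cov in covariates:
        if cov == "sex":
            X["sex"] = (cohort["sex"] == "M").astype(float)
        else:
            X[cov] = cohort[cov].to_numpy(dtype=float)
    return sm.add_constant(X, has_constant="add")


def fit_logistic_additive(
    cohort: pd.DataFrame,
    snp_id: str,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> LogisticFit:
    """Maximum-likelihood log-additive logistic fit for one SNP.

    Complete-case per SNP (rows with a missing dosage or covariate are
    dropped).  Covariates that make the design rank-deficient (e.g. sex
    against an all-female X genotype subset) are dropped and recorded.
    Separation or non-convergence yields a flagged result rather than a
    silent NA; a dosage with no variation raises :class:`MonomorphicError`.
    """
    cols = [snp_id] + [c for c in covariates if c != "sex"]
    sub = cohort.dropna(subset=cols)
    y = sub["status"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"{snp_id}: need at least one case and one control")
    d = sub[snp_id]
    if d.nunique() < 2:
        raise MonomorphicError(f"{snp_id}: dosage has no variation in the analysis sample")
    X = _design_matrix(sub, d, covariates)
    dropped = []
    # drop covariates (never the dosage) until the design has full rank
    while np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        drop = [c for c in X.columns if c not in ("const", "dosage")]
        if not drop:
            break
        dropped.append(drop[-1])
        X = X.drop(columns=drop[-1])
    try:
        res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100, tol=1e-10)
        converged = bool(res.mle_retvals.get("converged", True))
        message = "" if converged else "did not converge in 100 iterations"
    except Exception as exc:  # perfect separation, singular Hessian
        return LogisticFit(
            odds_ratio=np.nan, ci_lo=np.nan, ci_hi=np.nan, p_value=np.nan,
            beta=np.nan, se=np.nan, n_used=len(sub), converged=False,
            dropped_covariates=tuple(dropped), message=f"{type(exc).__name__}: {exc}",
        )
    beta = float(res.params["dosage"])
    se = float(res.bse["dosage"])
    lo, hi = res.conf_int().loc["dosage"]
    return LogisticFit(
        odds_ratio=float(np.exp(beta)),
        ci_lo=float(np.exp(lo)),
        ci_hi=float(np.exp(hi)),
        p_value=float(res.pvalues["dosage"]),
        beta=beta,
        se=se,
        n_used=len(sub),
        converged=converged,
        dropped_covariates=tuple(dropped),
        message=message,
    )


def _allelic_table(sub: pd.DataFrame, snp_id: str, x_snps) -> np.ndarray:
    """2x2 risk-allele count table [case, control] x [risk, other]."""
    d = sub[snp_id].to_numpy(dtype=float)
    ok = ~np.isnan(d)
    pl = ploidy(sub, snp_id, x_snps)
    y = sub["status"].to_numpy()
    table = np.empty((2, 2))
    for i, grp in enumerate((1, 0)):
        m = ok & (y == grp)
        risk = d[m].sum()
        total = pl[m].sum()
        table[i] = (risk, total - risk)
    return table


def cmh_test(
    cohort: pd.DataFrame,
    snp_id: str,
    stratum_field: str = "stratum",
    x_snps=(),
) -> CmhFit:
    """Cochran–Mantel–Haenszel test over per-stratum allelic 2x2 tables.

    Strata with an all-zero margin are skipped with a note; if no usable
    stratum remains the pooled odds ratio is undefined and a ``ValueError``
    is raised.  A single usable stratum degenerates to the ordinary 2x2
    allelic odds ratio.
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    tables, notes, n_used = [], [], 0
    for label, sub in cohort.groupby(stratum_field, sort=True):
        t = _allelic_table(sub, snp_id, x_snps)
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            notes.append(f"stratum {label!r} skipped (zero margin)")
            continue
        tables.append(t)
        n_used += int(sub[snp_id].notna().sum())
    if not tables:
        raise ValueError(f"{snp_id}: all strata have a zero margin; pooled OR undefined")
    st = StratifiedTable([t.astype(float) for t in tables])
    res = st.test_null_odds(correction=False)
    lo, hi = st.oddsratio_pooled_confint(alpha=0.05)
    return CmhFit(
        odds_ratio=float(st.oddsratio_pooled),
        ci_lo=float(lo),
        ci_hi=float(hi),
        p_value=float(res.pvalue),
        chi_square=float(res.statistic),
        n_used=n_used,
        n_strata_used=len(tables),
        notes=tuple(notes),
    )


def _combined_raf(cohort: pd.DataFrame, snp_id: str, x_snps) -> float:
    d = cohort[snp_id].to_numpy(dtype=float)
    ok = ~np.isnan(d)
    pl = ploidy(cohort, snp_id, x_snps)
    total = pl[ok].sum()
    return float(d[ok].sum() / total) if total else float("nan")


def run_association_panel(
    cohort: pd.DataFrame,
    annotations: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
    stratum_field: str = "stratum",
    analyses: tuple[str, ...] = ("logistic", "cmh"),
) -> pd.DataFrame:
    """Run both per-SNP analyses for every annotated SNP in the cohort.

    Returns one row per SNP in annotation order with the combined-sample
    risk allele frequency, adjusted-logistic and CMH odds ratios, 95% CIs
    and p-values.  Per-SNP failures are recorded in the ``note`` column and
    the run continues.
    """
    x_snps = x_snp_ids(annotations)
    present = set(snp_columns(cohort))
    rows = []
    for _, ann in annotations.iterrows():
        snp = ann["snp_id"]
        if snp not in present:
            continue
        row = {
            "snp_id": snp,
            "gene": ann.get("gene", ""),
            "chromosome": ann["chromosome"],
            "risk_allele": ann["risk_allele_study"],
        }
        notes = []
        oriented = cohort.copy()
        try:
            oriented[snp] = orient_to_risk_allele(cohort[snp], ann, sex=cohort["sex"])
        except ValueError as exc:
            notes.append(str(exc))
            oriented = None
        if oriented is not None:
            row["raf"] = _combined_raf(oriented, snp, x_snps)
            row["n_used"] = int(oriented[snp].notna().sum())
            if "logistic" in analyses:
                try:
                    fit = fit_logistic_additive(oriented, snp, covariates=covariates)
                    row.update(
                        or_adjusted=fit.odds_ratio,
                        ci_lo_adjusted=fit.ci_lo,
                        ci_hi_adjusted=fit.ci_hi,
                        p_adjusted=fit.p_value,
                    )
                    if fit.message:
                        notes.append(f"logistic: {fit.message}")
                    if fit.dropped_covariates:
                        notes.append(f"logistic dropped covariates: {fit.dropped_covariates}")
                except (ValueError, MonomorphicError) as exc:
                    notes.append(f"logistic: {exc}")
            if "cmh" in analyses:
                try:
                    fit = cmh_test(oriented, snp, stratum_field=stratum_field, x_snps=x_snps)
                    row.update(
                        or_cmh=fit.odds_ratio,
                        ci_lo_cmh=fit.ci_lo,
                        ci_hi_cmh=fit.ci_hi,
                        p_cmh=fit.p_value,
                    )
                    notes.extend(fit.notes)
                except ValueError as exc:
                    notes.append(f"cmh: {exc}")
        row["note"] = "; ".join(notes)
        rows.append(row)
    columns = [
        "snp_id", "gene", "chromosome", "risk_allele", "raf", "n_used",
        "or_adjusted", "ci_lo_adjusted", "ci_hi_adjusted", "p_adjusted",
        "or_cmh", "ci_lo_cmh", "ci_hi_cmh", "p_cmh", "note",
    ]
    out = pd.DataFrame(rows)
    for col in columns:
        if col not in out.columns:
            out[col] = np.nan
    return out[columns]


class AssociationPanel(BaseEstimator):
    """Estimator facade over :func:`run_association_panel`.

    After ``fit(cohort, annotations)`` the per-SNP table is in ``results_``.
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = ("age", "sex"),
        stratum_field: str = "stratum",
        analyses: tuple[str, ...] = ("logistic", "cmh"),
    ):
        self.covariates = covariates
        self.stratum_field = stratum_field
        self.analyses = analyses

    def fit(self, cohort: pd.DataFrame, annotations: pd.DataFrame):
        self.results_ = run_association_panel(
            cohort,
            annotations,
            covariates=tuple(self.covariates),
            stratum_field=self.stratum_field,
            analyses=tuple(self.analyses),
        )
        self.n_snps_ = len(self.results_)
        return self
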