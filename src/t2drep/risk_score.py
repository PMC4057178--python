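"""Weighted genetic risk score (GRS).

The score for an individual is the weighted sum of risk-allele dosages,

    raw = sum_i w_i * g_i,        w_i = ln(reference per-allele OR_i),

over the SNPs with a non-missing genotype, rescaled to the full panel so
that one unit of the score corresponds to one average-effect risk allele:

    rescaled = raw * N / sum_{available i} w_i .

X-chromosome genotypes enter on the X-inactivation scale: male dosages
{0, 1} map to {0, 1} and female dosages {0, 1, 2} map to {0, 0.5, 1}.
Individuals with genotypes for fewer than 80% of the panel (29 of 36 at
the default) are excluded from scoring.  The score relates to disease by a
per-unit odds ratio (logistic regression adjusted for age and sex) and by
quintile odds ratios versus the lowest quintile (additionally adjusted for
ethnolinguistic stratum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "code_x_dosage",
    "compute_grs",
    "grs_association",
    "quintile_analysis",
    "assign_quintiles",
    "weights_from_annotations",
    "GeneticRiskScore",
]


def code_x_dosage(dosage, sex):
    """Apply the random-X-inactivation analysis coding to an X SNP.

    Males: raw {0, 1} -> {0, 1}.  Females: raw {0, 1, 2} -> {0, 0.5, 1}.
    Missing is preserved.  Raw dosages outside the sex-specific range are
    an error.
    """
    d = np.asarray(dosage, dtype=float)
    s = np.asarray(sex)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    s = np.atleast_1d(s)
    ok = np.isnan(d) | np.where(s == "M", np.isin(d, (0.0, 1.0)), np.isin(d, (0.0, 1.0, 2.0)))
    if not ok.all():
        i = int(np.flatnonzero(~ok)[0])
        raise ValueError(f"raw X dosage {d[i]} out of range for sex {s[i]!r}")
    coded = np.where(s == "M", d, d / 2.0)
    if isinstance(dosage, pd.Series):
        return pd.Series(coded, index=dosage.index, name=dosage.name)
    return float(coded[0]) if scalar else coded


def weights_from_annotations(annotations: pd.DataFrame, column: str = "reference_or") -> pd.Series:
    """Per-SNP weights w = ln(OR) from an annotation column of odds ratios."""
    ors = annotations.set_index("snp_id")[column]
    if ors.isna().any():
        missing = ors.index[ors.isna()].tolist()
        raise ValueError(f"no {column} for: {missing}")
    if (ors <= 0).any():
        raise ValueError(f"{column} must be positive")
    return np.log(ors.astype(float)).rename("w")


def compute_grs(
    cohort: pd.DataFrame,
    weights: pd.Series,
    x_snps=(),
    min_fraction: float = 0.8,
    rescale: str = "weight_sum",
) -> pd.DataFrame:
    """Per-individual raw and rescaled weighted risk scores.

    Parameters
    ----------
    weights : Series of w = ln(OR), indexed by snp_id; must cover every
        scored SNP (the score is computed over ``weights.index``).
    min_fraction : availability floor; individuals with fewer than
        ``ceil(min_fraction * N)`` non-missing genotypes are excluded.
    rescale : ``"weight_sum"`` (default) rescales by N / sum of available
        weights; ``"snp_count"`` rescales by the SNP-count ratio
        (N / n_available) on the mean-weight scale.  The two coincide for
        complete data.

    Returns a frame with sample_id, n_available, raw_score, rescaled_score
    and a ``scored`` flag.  Individuals whose available weights sum to <= 0
    are flagged unscorable.
    """
    if rescale not in ("weight_sum", "snp_count"):
        raise ValueError("rescale must be 'weight_sum' or 'snp_count'")
    snps = list(weights.index)
    missing_cols = [s for s in snps if s not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort lacks genotype columns for: {missing_cols}")
    g = cohort[snps].to_numpy(dtype=float)
    x_set = set(x_snps) & set(snps)
    if x_set:
        sex = cohort["sex"].to_numpy()
        for j, snp in enumerate(snps):
            if snp in x_set:
                g[:, j] = code_x_dosage(g[:, j], sex)
    w = weights.to_numpy(dtype=float)
    avail = ~np.isnan(g)
    n_avail = avail.sum(axis=1)
    n_total = len(snps)
    floor = math.ceil(min_fraction * n_total)
    raw = np.nansum(g * w, axis=1)
    w_avail = (avail * w).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if rescale == "weight_sum":
            rescaled = raw * n_total / w_avail
        else:
            mean_w = w.mean()
            rescaled = raw * n_total / (n_avail * mean_w)
    scored = (n_avail >= floor) & (w_avail > 0)
    unscorable = (n_avail >= floor) & (w_avail <= 0)
    rescaled = np.where(scored, rescaled, np.nan)
    raw = np.where(n_avail > 0, raw, 0.0)
    return pd.DataFrame(
        {
            "sample_id": cohort["sample_id"].to_numpy(),
            "n_available": n_avail,
            "raw_score": raw,
            "rescaled_score": rescaled,
            "scored": scored,
            "unscorable_weights": unscorable,
        }
    )


def assign_quintiles(scores: np.ndarray, n_groups: int = 5) -> np.ndarray:
    """Pooled-distribution quantile groups of near-equal size (1-based).

    Groups are cut by rank so sizes differ by at most one before tie
    adjustment; tied score values spanning a boundary all take the lower
    group.  Degenerate ties (any group left empty) are an error.
    """
    s = np.asarray(scores, dtype=float)
    if np.isnan(s).any():
        raise ValueError("scores must be non-missing")
    n = len(s)
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} scored individuals")
    order = np.argsort(s, kind="mergesort")
    q = np.empty(n, dtype=int)
    q[order] = np.floor(np.arange(n) * n_groups / n).astype(int) + 1
    df = pd.DataFrame({"s": s, "q": q})
    q = df.groupby("s")["q"].transform("min").to_numpy()
    if len(np.unique(q)) < n_groups:
        raise ValueError("ties collapse the score distribution; quintiles are degenerate")
    return q


def _logit(y, X):
    res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100, tol=1e-10)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic regression did not converge")
    return res


@dataclass(frozen=True)
class GrsAssociation:
    per_unit_or: float
    ci_lo: float
    ci_hi: float
    p_value: float
    n_used: int


def grs_association(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> GrsAssociation:
    """Per-unit odds ratio of T2D per weighted risk allele.

    Logistic regression of status on the rescaled score, adjusted for age
    and sex, over scored individuals (at least 50 required).
    """
    merged = cohort.merge(scores.loc[scores["scored"], ["sample_id", "rescaled_score"]], on="sample_id")
    if len(merged) < 50:
        raise ValueError(f"only {len(merged)} scored individuals; need >= 50")
    X = pd.DataFrame({"grs": merged["rescaled_score"].to_numpy()})
    for cov in covariates:
        X[cov] = (merged["sex"] == "M").astype(float) if cov == "sex" else merged[cov].to_numpy(dtype=float)
    X = sm.add_constant(X, has_constant="add")
    res = _logit(merged["status"].to_numpy(dtype=float), X)
    lo, hi = res.conf_int().loc["grs"]
    return GrsAssociation(
        per_unit_or=float(np.exp(res.params["grs"])),
        ci_lo=float(np.exp(lo)),
        ci_hi=float(np.exp(hi)),
        p_value=float(res.pvalues["grs"]),
        n_used=len(merged),
    )


def quintile_analysis(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "stratum"),
    n_groups: int = 5,
) -> pd.DataFrame:
    """Odds ratios for GRS quintiles Q2..Q5 versus the lowest quintile.

    Quintile cut-points come from the pooled cases+controls score
    distribution.  The logistic model uses quintile indicators (Q1 as the
    reference) adjusted, following the published analysis, for age, sex and
    ethnolinguistic stratum.  Requires at least 100 scored individuals.
    """
    merged = cohort.merge(scores.loc[scores["scored"], ["sample_id", "rescaled_score"]], on="sample_id")
    if len(merged) < 100:
        raise ValueError(f"only {len(merged)} scored individuals; need >= 100")
    q = assign_quintiles(merged["rescaled_score"].to_numpy(), n_groups=n_groups)
    X = pd.DataFrame(index=merged.index)
    for k in range(2, n_groups + 1):
        X[f"Q{k}"] = (q == k).astype(float)
    for cov in covariates:
        if cov == "sex":
            X["sex"] = (merged["sex"] == "M").astype(float)
        elif cov == "stratum":
            dummies = pd.get_dummies(merged["stratum"], prefix="stratum", drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = merged[cov].to_numpy(dtype=float)
    X = sm.add_constant(X, has_constant="add")
    res = _logit(merged["status"].to_numpy(dtype=float), X)
    rows = [{"quintile": 1, "odds_ratio": 1.0, "ci_lo": np.nan, "ci_hi": np.nan,
             "p_value": np.nan, "n": int((q == 1).sum()), "n_cases": int(merged.loc[q == 1, "status"].sum())}]
    ci = res.conf_int()
    for k in range(2, n_groups + 1):
        name = f"Q{k}"
        rows.append(
            {
                "quintile": k,
                "odds_ratio": float(np.exp(res.params[name])),
                "ci_lo": float(np.exp(ci.loc[name, 0])),
                "ci_hi": float(np.exp(ci.loc[name, 1])),
                "p_value": float(res.pvalues[name]),
                "n": int((q == k).sum()),
                "n_cases": int(merged.loc[q == k, "status"].sum()),
            }
        )
    return pd.DataFrame(rows)


class GeneticRiskScore(BaseEstimator, TransformerMixin):
    """Transformer computing per-individual weighted risk scores.

    Parameters
    ----------
    weights : mapping/Series of per-SNP *odds ratios* (not logs); stored as
        w = ln(OR) in ``weights_`` at fit time.
    min_fraction : genotype-availability floor (default 0.8).
    rescale : missing-data rescaling dialect, ``"weight_sum"`` or
        ``"snp_count"``.
    x_snps : ids of X-chromosome SNPs (X-inactivation coding applies).
    """

    def __init__(self, weights=None, min_fraction: float = 0.8,
                 rescale: str = "weight_sum", x_snps: tuple = ()):
        self.weights = weights
        self.min_fraction = min_fraction
        self.rescale = rescale
        self.x_snps = x_snps

    def fit(self, cohort: pd.DataFrame, y=None):
        if self.weights is None:
            raise ValueError("weights (per-SNP odds ratios) are required")
        ors = pd.Series(self.weights, dtype=float)
        if (ors <= 0).any():
            raise ValueError("odds-ratio weights must be positive")
        missing = [s for s in ors.index if s not in cohort.columns]
        if missing:
            raise ValueError(f"cohort lacks genotype columns for: {missing}")
        self.weights_ = np.log(ors).rename("w")
        self.n_snps_ = len(ors)
        return self

    def transform(self, cohort: pd.DataFrame) -> pd.DataFrame:
        return compute_grs(
            cohort,
            self.weights_,
            x_snps=tuple(self.x_snps),
            min_fraction=self.min_fraction,
            rescale=self.rescale,
        )

    def associate(self, cohort: pd.DataFrame, scores: pd.DataFrame | None = None) -> GrsAssociation:
        if scores is None:
            scores = self.transform(cohort)
        return grs_association(cohort, scores)

    def quintiles(self, cohort: pd.DataFrame, scores: pd.DataFrame | None = None) -> pd.DataFrame:
        if scores is None:
            scores = self.transform(cohort)
        return quintile_analysis(cohort, scores)
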