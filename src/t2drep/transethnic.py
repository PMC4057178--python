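"""Trans-ethnic consistency of per-SNP estimates.

Compares study odds ratios and risk allele frequencies against a reference
population (Europeans in the motivating study): directional-consistency
counts with an exact binomial sign test, Pearson correlations of the OR and
RAF vectors, tallies of loci where the study estimate exceeds the
reference, and nominal-significance counts in the two association analyses.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_comparison",
    "count_consistent",
    "binomial_sign_test",
    "compare_effect_sizes",
    "compare_allele_frequencies",
    "count_nominal",
    "nominal_counts",
    "NominalCounts",
    "VectorComparison",
]

NOMINAL_ALPHA = 0.05  # inclusive: p <= 0.05 counts as nominal


class VectorComparison(NamedTuple):
    pearson_r: float
    p_value: float
    n_study_greater: int
    n: int


class NominalCounts(NamedTuple):
    n_adjusted: int
    n_cmh: int
    n_overlap: int


def build_comparison(annotations: pd.DataFrame, or_column: str = "or_adjusted") -> pd.DataFrame:
    """Assemble per-SNP comparison rows from an annotation/result table.

    ``directionally_consistent`` means the risk alleles match between the
    two populations and the study OR, oriented to the reference risk
    allele, exceeds 1.  A printed OR of exactly 1.00 is treated as
    consistent by default (see :func:`count_consistent`); the flag here
    records strict inequality and the tie separately.
    """
    out = pd.DataFrame(
        {
            "snp_id": annotations["snp_id"],
            "study_or": annotations[or_column].astype(float),
            "reference_or": annotations.get("reference_or", np.nan),
            "study_raf": annotations.get("raf_study", np.nan),
            "reference_raf": annotations.get("reference_raf", np.nan),
            "risk_alleles_match": (
                annotations["risk_allele_study"] == annotations["risk_allele_reference"]
            ),
        }
    )
    # orient the study OR to the reference risk allele
    out["study_or_ref_oriented"] = np.where(
        out["risk_alleles_match"], out["study_or"], 1.0 / out["study_or"]
    )
    if "p_adjusted" in annotations.columns:
        out["nominally_significant_adjusted"] = annotations["p_adjusted"] <= NOMINAL_ALPHA
    if "p_cmh" in annotations.columns:
        out["nominally_significant_cmh"] = annotations["p_cmh"] <= NOMINAL_ALPHA
    return out


def count_consistent(rows: pd.DataFrame, ties: str = "consistent") -> tuple[int, int]:
    """(k, n): SNPs whose study effect is directionally consistent.

    A row is consistent when the reference-oriented study OR is above 1.
    ``ties`` decides reported ORs of exactly 1.00: ``"consistent"`` (the
    default; printed two-decimal precision masks an OR marginally above 1)
    or ``"strict"`` (a tie is not evidence of the same direction).
    """
    if ties not in ("consistent", "strict"):
        raise ValueError("ties must be 'consistent' or 'strict'")
    if len(rows) == 0:
        return (0, 0)
    or_ref = rows["study_or_ref_oriented"].astype(float)
    if not np.isfinite(or_ref).all():
        raise ValueError("comparison rows contain non-finite odds ratios")
    if ties == "consistent":
        consistent = or_ref >= 1.0
    else:
        consistent = or_ref > 1.0
    return (int(consistent.sum()), int(len(rows)))


def binomial_sign_test(
    k: int, n: int, null_p: float = 0.5, alternative: str = "greater"
) -> float:
    """Exact binomial tail probability for k consistent results out of n.

    For the fair-coin null the one-sided tail is computed in exact rational
    arithmetic, P(X >= k) = sum_{i>=k} C(n, i) / 2^n; for other nulls the
    scipy binomial survival function is used.  ``alternative`` is
    ``"greater"`` (default, enrichment of consistency) or ``"two-sided"``.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    if alternative == "two-sided":
        return float(stats.binomtest(k, n, null_p, alternative="two-sided").pvalue)
    if null_p == 0.5:
        tail = Fraction(sum(comb(n, i) for i in range(k, n + 1)), 2**n)
        return float(tail)
    return float(stats.binom.sf(k - 1, n, null_p))


def _compare(rows: pd.DataFrame, study_col: str, ref_col: str, log_scale: bool) -> VectorComparison:
    sub = rows.dropna(subset=[study_col, ref_col])
    x = sub[study_col].to_numpy(dtype=float)
    y = sub[ref_col].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 paired values, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors; correlation undefined")
    n_greater = int((x > y).sum())
    if log_scale:
        x, y = np.log(x), np.log(y)
    r, p = stats.pearsonr(x, y)
    return VectorComparison(float(r), float(p), n_greater, len(x))


def compare_effect_sizes(rows: pd.DataFrame, scale: str = "raw") -> VectorComparison:
    """Pearson correlation of study vs reference odds ratios.

    ``scale="raw"`` (default, matching scatter plots of OR point
    estimates) or ``"log"``.  Also tallies loci where the study OR exceeds
    the reference OR (always on the raw scale).
    """
    if scale not in ("raw", "log"):
        raise ValueError("scale must be 'raw' or 'log'")
    return _compare(rows, "study_or", "reference_or", log_scale=(scale == "log"))


def compare_allele_frequencies(rows: pd.DataFrame) -> VectorComparison:
    """Pearson correlation of study vs reference risk allele frequencies."""
    return _compare(rows, "study_raf", "reference_raf", log_scale=False)


def count_nominal(rows: pd.DataFrame, which_analysis: str) -> int:
    """Count rows nominally significant (p <= 0.05) in one analysis."""
    col = {"adjusted": "nominally_significant_adjusted", "cmh": "nominally_significant_cmh"}
    if which_analysis not in col:
        raise ValueError("which_analysis must be 'adjusted' or 'cmh'")
    return int(rows[col[which_analysis]].sum())


def nominal_counts(rows: pd.DataFrame) -> NominalCounts:
    """Nominal-significance counts in both analyses and their overlap."""
    adj = rows["nominally_significant_adjusted"].astype(bool)
    cmh = rows["nominally_significant_cmh"].astype(bool)
    return NominalCounts(int(adj.sum()), int(cmh.sum()), int((adj & cmh).sum()))
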