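"""Sample- and SNP-level quality control.

Reproduces the exclusion rules of a candidate-SNP case-control study and
their bookkeeping: case-definition filtering (missing or positive GADA,
early insulin treatment, mitochondrial diabetes), removal of samples with a
low (<80%) overall genotype call rate, and removal of SNPs out of
Hardy–Weinberg equilibrium in controls (p < 0.001).

Every filter returns a :class:`QcReport` whose counts satisfy the
bookkeeping identity ``n_input = n_remaining + sum(excluded per reason)``;
each excluded id appears under exactly one reason (first matching rule
wins, in the documented order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .annotations import x_snp_ids
from .cohort import call_rates, snp_columns

__all__ = [
    "QcConfig",
    "QcReport",
    "HweResult",
    "hwe_test",
    "hwe_exact_test",
    "apply_case_definition",
    "filter_sample_call_rate",
    "filter_hwe",
    "CaseDefinitionFilter",
    "CallRateFilter",
    "HWEFilter",
]


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for the QC stage.

    sample_call_rate_min : samples strictly below this fraction of
        non-missing calls are removed (default 0.80).
    hwe_alpha : SNPs with an HWE p-value strictly below this are removed
        (default 0.001).
    hwe_population : which samples the HWE test is computed in
        ("controls", the default, or "all").
    hwe_exact : use the mid-p-free exact conditional test instead of the
        asymptotic chi-square (off by default).
    """

    sample_call_rate_min: float = 0.80
    hwe_alpha: float = 0.001
    hwe_population: str = "controls"
    hwe_exact: bool = False

    def __post_init__(self):
        if not 0.0 < self.sample_call_rate_min <= 1.0:
            raise ValueError("sample_call_rate_min must be in (0, 1]")
        if not 0.0 < self.hwe_alpha <= 1.0:
            raise ValueError("hwe_alpha must be in (0, 1]")
        if self.hwe_population not in ("controls", "all"):
            raise ValueError("hwe_population must be 'controls' or 'all'")


@dataclass
class QcReport:
    """Bookkeeping for one exclusion step."""

    step: str
    n_input: int
    excluded: dict[str, list] = field(default_factory=dict)
    n_remaining: int = 0
    details: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {reason: len(ids) for reason, ids in self.excluded.items()}

    @property
    def n_excluded(self) -> int:
        return sum(len(ids) for ids in self.excluded.values())

    def check(self) -> None:
        """Assert the bookkeeping identity input = remaining + excluded."""
        if self.n_input != self.n_remaining + self.n_excluded:
            raise AssertionError(
                f"{self.step}: {self.n_input} != {self.n_remaining} + {self.n_excluded}"
            )
        seen: set = set()
        for ids in self.excluded.values():
            overlap = seen & set(ids)
            if overlap:
                raise AssertionError(f"{self.step}: ids in two reason buckets: {overlap}")
            seen |= set(ids)

    def to_json(self, **kwargs) -> str:
        payload = {
            "step": self.step,
            "n_input": self.n_input,
            "n_remaining": self.n_remaining,
            "excluded_counts": self.counts,
            "excluded_ids": {k: list(map(str, v)) for k, v in self.excluded.items()},
            "details": {
                k: (
                    v.to_dict(orient="records")
                    if isinstance(v, pd.DataFrame)
                    else v.to_dict() if isinstance(v, pd.Series) else v
                )
                for k, v in self.details.items()
            },
        }
        return json.dumps(payload, default=float, **kwargs)

    def __str__(self) -> str:
        lines = [f"[{self.step}] input: {self.n_input}"]
        for reason, ids in self.excluded.items():
            lines.append(f"  - excluded ({reason}): {len(ids)}")
        lines.append(f"  remaining: {self.n_remaining}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# case definition


def apply_case_definition(cohort: pd.DataFrame) -> tuple[pd.DataFrame, QcReport]:
    """Drop cases that fail the clinical T2D definition.

    Rules are applied to cases only, in order, each sample counted once:

    1. ``missing_gada`` — GADA titre not measured (flag is NA);
    2. ``gada_positive`` — autoantibody positive (flag = 1);
    3. ``early_insulin`` — insulin within 6 months of diagnosis (flag = 1);
    4. ``mitochondrial`` — mitochondrial diabetes diagnosis (flag = 1).

    Controls pass through untouched.
    """
    is_case = cohort["status"] == 1
    gada = cohort["gada_positive"]
    reasons = {
        "missing_gada": is_case & gada.isna(),
        "gada_positive": is_case & gada.notna() & (gada == 1),
        "early_insulin": is_case & (cohort["early_insulin"] == 1),
        "mitochondrial": is_case & (cohort["mitochondrial"] == 1),
    }
    excluded: dict[str, list] = {}
    taken = pd.Series(False, index=cohort.index)
    for reason, mask in reasons.items():
        mask = mask & ~taken
        excluded[reason] = cohort.loc[mask, "sample_id"].tolist()
        taken |= mask
    kept = cohort.loc[~taken].reset_index(drop=True)
    report = QcReport(
        step="case_definition",
        n_input=len(cohort),
        excluded=excluded,
        n_remaining=len(kept),
        details={"n_cases_remaining": int((kept["status"] == 1).sum())},
    )
    report.check()
    return kept, report


# ---------------------------------------------------------------------------
# sample call rate


def filter_sample_call_rate(
    cohort: pd.DataFrame, config: QcConfig = QcConfig()
) -> tuple[pd.DataFrame, QcReport]:
    """Remove samples whose overall call rate is strictly below threshold.

    The denominator is all genotyped SNP columns present in the table (the
    pre-HWE panel: sample filtering happens before SNP filtering).
    """
    rates = call_rates(cohort)
    low = rates.to_numpy() < config.sample_call_rate_min
    kept = cohort.loc[~low].reset_index(drop=True)
    report = QcReport(
        step="sample_call_rate",
        n_input=len(cohort),
        excluded={"low_call_rate": cohort.loc[low, "sample_id"].tolist()},
        n_remaining=len(kept),
        details={
            "threshold": config.sample_call_rate_min,
            "call_rates": rates,
            "n_cases_remaining": int((kept["status"] == 1).sum()),
            "n_controls_remaining": int((kept["status"] == 0).sum()),
        },
    )
    report.check()
    return kept, report


# ---------------------------------------------------------------------------
# Hardy–Weinberg equilibrium


class HweResult(NamedTuple):
    chi_square: float
    p_value: float
    monomorphic: bool = False


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> HweResult:
    """1-df goodness-of-fit chi-square against Hardy–Weinberg proportions.

    The allele frequency is estimated from the counts themselves, leaving
    one degree of freedom.  A monomorphic SNP is a defined degenerate case:
    chi-square 0, p = 1, flagged.
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("at least one genotype observation is required")
    p = (2 * counts[2] + counts[1]) / (2 * n)
    if p == 0.0 or p == 1.0:
        return HweResult(0.0, 1.0, monomorphic=True)
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return HweResult(chi2, float(stats.chi2.sf(chi2, df=1)), monomorphic=False)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> HweResult:
    """Exact conditional HWE test (sum of hypergeometric-type probabilities
    of heterozygote counts at least as improbable as the observed one)."""
    counts = [int(n_hom_ref), int(n_het), int(n_hom_alt)]
    if min(counts) < 0 or sum(counts) == 0:
        raise ValueError("invalid genotype counts")
    n = sum(counts)
    n_alt = 2 * counts[2] + counts[1]
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return HweResult(0.0, 1.0, monomorphic=True)
    het_obs = counts[1]
    hets = range(n_minor % 2, n_minor + 1, 2)
    logprobs = {}
    from scipy.special import gammaln

    for h in hets:
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        logprobs[h] = (
            h * np.log(2)
            + gammaln(n + 1)
            - gammaln(hom_min + 1)
            - gammaln(h + 1)
            - gammaln(hom_maj + 1)
            + gammaln(n_minor + 1)
            + gammaln(2 * n - n_minor + 1)
            - gammaln(2 * n + 1)
        )
    mx = max(logprobs.values())
    probs = {h: float(np.exp(lp - mx)) for h, lp in logprobs.items()}
    total = sum(probs.values())
    p_obs = probs[het_obs]
    p_value = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total
    return HweResult(float("nan"), min(1.0, p_value), monomorphic=False)


def hwe_table(
    cohort: pd.DataFrame,
    snps: list[str] | None = None,
    x_snps: list[str] = (),
    population: str = "controls",
    exact: bool = False,
) -> pd.DataFrame:
    """Per-SNP HWE statistics in the configured population.

    X-chromosome SNPs are excluded from the pooled test (hemizygous male
    genotypes are not a diploid class); a females-only test is reported for
    them instead, marked in the ``population`` column.
    """
    if population == "controls":
        sub = cohort[cohort["status"] == 0]
        if len(sub) == 0:
            raise ValueError("HWE in controls requested but the cohort has no controls")
    else:
        sub = cohort
    rows = []
    test = hwe_exact_test if exact else hwe_test
    x_set = set(x_snps)
    for snp in snps if snps is not None else snp_columns(cohort):
        pop_label = population
        data = sub
        if snp in x_set:
            data = sub[sub["sex"] == "F"]
            pop_label = f"{population}:females"
        d = data[snp].dropna()
        counts = [(d == g).sum() for g in (0, 1, 2)]
        res = test(*counts)
        rows.append(
            {
                "snp_id": snp,
                "n": int(d.shape[0]),
                "chi_square": res.chi_square,
                "p_value": res.p_value,
                "monomorphic": res.monomorphic,
                "population": pop_label,
            }
        )
    return pd.DataFrame(rows)


def filter_hwe(
    cohort: pd.DataFrame,
    annotations: pd.DataFrame,
    config: QcConfig = QcConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, QcReport]:
    """Drop SNPs violating HWE (p < alpha) in the configured population.

    Returns the cohort without the dropped genotype columns, the annotation
    table without the dropped rows, and the report (the full per-SNP HWE
    table sits in ``report.details['hwe']``).
    """
    snps = [s for s in snp_columns(cohort) if s in set(annotations["snp_id"])]
    table = hwe_table(
        cohort,
        snps=snps,
        x_snps=x_snp_ids(annotations),
        population=config.hwe_population,
        exact=config.hwe_exact,
    )
    failed = table.loc[table["p_value"] < config.hwe_alpha, "snp_id"].tolist()
    kept_cohort = cohort.drop(columns=failed)
    kept_ann = annotations[~annotations["snp_id"].isin(failed)].reset_index(drop=True)
    report = QcReport(
        step="hwe",
        n_input=len(snps),
        excluded={"hwe_violation": failed},
        n_remaining=len(snps) - len(failed),
        details={"alpha": config.hwe_alpha, "population": config.hwe_population, "hwe": table},
    )
    report.check()
    return kept_cohort, kept_ann, report


# ---------------------------------------------------------------------------
# scikit-learn style filter facade


class _ReportingFilter(BaseEstimator):
    """Stateless row/column filter with a ``report_`` attribute."""

    def fit(self, X: pd.DataFrame, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


class CaseDefinitionFilter(_ReportingFilter):
    """Transformer applying the clinical case-definition exclusions."""

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out, self.report_ = apply_case_definition(X)
        return out


class CallRateFilter(_ReportingFilter):
    """Transformer removing samples with call rate < ``min_call_rate``."""

    def __init__(self, min_call_rate: float = 0.80):
        self.min_call_rate = min_call_rate

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out, self.report_ = filter_sample_call_rate(
            X, QcConfig(sample_call_rate_min=self.min_call_rate)
        )
        return out


class HWEFilter(_ReportingFilter):
    """Transformer dropping SNP columns out of HWE in controls (or all).

    Needs the annotation table to know which SNPs are X-linked; after
    ``transform`` the filtered annotations are in ``annotations_``.
    """

    def __init__(self, annotations=None, alpha: float = 0.001, population: str = "controls", exact: bool = False):
        self.annotations = annotations
        self.alpha = alpha
        self.population = population
        self.exact = exact

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.annotations is None:
            raise ValueError("HWEFilter requires an annotation table")
        cfg = QcConfig(hwe_alpha=self.alpha, hwe_population=self.population, hwe_exact=self.exact)
        out, self.annotations_, self.report_ = filter_hwe(X, self.annotations, cfg)
        return out
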