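"""Analytic power for unmatched case-control association, log-additive model.

The disease model is logistic in the risk-allele count g in {0, 1, 2}:
P(D | g) = expit(a + g ln OR), with the intercept a solved so the
population prevalence (over Hardy–Weinberg genotype proportions) equals K.
Case and control genotype distributions follow by Bayes inversion.  Power
for the two-sided alpha-level Wald/score test of the per-allele log OR is
computed from the noncentrality of the prospective logistic likelihood
evaluated under the case-control sampling design: the retrospective sample
is analysed prospectively (the standard logistic equivalence), the
intercept shifts by the sampling-fraction log-odds, and the slope variance
comes from the expected Fisher information of the case-control genotype
mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PowerRequest",
    "PowerResult",
    "expected_genotype_distributions",
    "analytic_power",
    "power_panel",
    "PowerCalculator",
]

GENOTYPES = np.array([0.0, 1.0, 2.0])


@dataclass(frozen=True)
class PowerRequest:
    """Design parameters for one power calculation."""

    raf: float
    per_allele_or: float
    n_cases: int
    n_controls: int
    prevalence: float = 0.10
    alpha: float = 0.05
    two_sided: bool = True

    def __post_init__(self):
        for name in ("raf", "prevalence", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.per_allele_or <= 0:
            raise ValueError("per_allele_or must be positive")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")


@dataclass(frozen=True)
class PowerResult:
    analytic_power: float
    expected_case_raf: float
    expected_control_raf: float
    noncentrality: float


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _solve_intercept(weights: np.ndarray, values: np.ndarray, target: float) -> float:
    """Solve sum_i weights_i * expit(a + values_i) = target by bisection."""
    def f(a):
        return float(weights @ _expit(a + values)) - target

    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"target probability {target} unreachable")
    return optimize.brentq(f, lo, hi, xtol=1e-13)


def expected_genotype_distributions(req: PowerRequest) -> tuple[np.ndarray, np.ndarray]:
    """Expected genotype distributions (g = 0, 1, 2) in cases and controls.

    Population genotype probabilities are Hardy–Weinberg in the risk allele
    frequency; penetrances come from the log-additive logistic model with
    the intercept solved for the target prevalence; case and control
    distributions follow by Bayes inversion and each sums to 1.
    """
    p = req.raf
    pop = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    beta = np.log(req.per_allele_or)
    a = _solve_intercept(pop, beta * GENOTYPES, req.prevalence)
    pen = _expit(a + beta * GENOTYPES)
    k = float(pop @ pen)
    cases = pop * pen / k
    controls = pop * (1.0 - pen) / (1.0 - k)
    return cases, controls


def analytic_power(req: PowerRequest) -> PowerResult:
    """Asymptotic power of the per-allele test at the requested design.

    The noncentrality is |ln OR| / SE(ln OR), with the standard error from
    the inverse expected information of the prospective logistic fit over
    the case-control genotype mixture.  At OR = 1 the power equals alpha
    exactly.
    """
    cases, controls = expected_genotype_distributions(req)
    n1, n0 = req.n_cases, req.n_controls
    n = n1 + n0
    w1 = n1 / n
    mix = w1 * cases + (1 - w1) * controls
    beta = np.log(req.per_allele_or)
    # intercept of the prospective fit within the case-control sample
    a_star = _solve_intercept(mix, beta * GENOTYPES, w1)
    mu = _expit(a_star + beta * GENOTYPES)
    v = mix * mu * (1.0 - mu)
    info = np.array(
        [
            [v.sum(), float(v @ GENOTYPES)],
            [float(v @ GENOTYPES), float(v @ GENOTYPES**2)],
        ]
    )
    var_beta = float(np.linalg.inv(info)[1, 1]) / n
    ncp = abs(beta) / np.sqrt(var_beta)
    if req.two_sided:
        z = stats.norm.ppf(1.0 - req.alpha / 2.0)
        power = float(stats.norm.sf(z - ncp) + stats.norm.cdf(-z - ncp))
    else:
        z = stats.norm.ppf(1.0 - req.alpha)
        power = float(stats.norm.sf(z - ncp))
    return PowerResult(
        analytic_power=power,
        expected_case_raf=float(cases @ GENOTYPES) / 2.0,
        expected_control_raf=float(controls @ GENOTYPES) / 2.0,
        noncentrality=float(ncp),
    )


def power_panel(
    annotations: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    prevalence: float = 0.10,
    alpha: float = 0.05,
    two_sided: bool = True,
    or_column: str = "reference_or",
    raf_column: str = "reference_raf",
) -> pd.DataFrame:
    """Per-SNP analytic power from an annotation table.

    Rows with a missing reference OR or RAF are flagged in the ``note``
    column and the run continues.
    """
    rows = []
    for _, ann in annotations.iterrows():
        row = {"snp_id": ann["snp_id"], "raf": ann.get(raf_column), "per_allele_or": ann.get(or_column)}
        if pd.isna(row["raf"]) or pd.isna(row["per_allele_or"]):
            row.update(power=np.nan, noncentrality=np.nan, note="missing reference OR/RAF")
        else:
            res = analytic_power(
                PowerRequest(
                    raf=float(row["raf"]),
                    per_allele_or=float(row["per_allele_or"]),
                    n_cases=n_cases,
                    n_controls=n_controls,
                    prevalence=prevalence,
                    alpha=alpha,
                    two_sided=two_sided,
                )
            )
            row.update(power=res.analytic_power, noncentrality=res.noncentrality, note="")
        rows.append(row)
    return pd.DataFrame(rows)


class PowerCalculator:
    """Convenience wrapper holding shared design parameters."""

    def __init__(self, prevalence: float = 0.10, alpha: float = 0.05, two_sided: bool = True):
        self.prevalence = prevalence
        self.alpha = alpha
        self.two_sided = two_sided

    def power(self, raf: float, per_allele_or: float, n_cases: int, n_controls: int) -> PowerResult:
        return analytic_power(
            PowerRequest(
                raf=raf,
                per_allele_or=per_allele_or,
                n_cases=n_cases,
                n_controls=n_controls,
                prevalence=self.prevalence,
                alpha=self.alpha,
                two_sided=self.two_sided,
            )
        )

    def panel(self, annotations: pd.DataFrame, n_cases: int, n_controls: int, **kwargs) -> pd.DataFrame:
        return power_panel(
            annotations,
            n_cases,
            n_controls,
            prevalence=self.prevalence,
            alpha=self.alpha,
            two_sided=self.two_sided,
            **kwargs,
        )
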