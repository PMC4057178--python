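"""Synthetic case-control cohort generator.

Emulates an unmatched candidate-SNP case-control study: genotypes are drawn
from Hardy–Weinberg proportions within ethnolinguistic strata, disease is
assigned by a log-additive logistic model whose intercept is calibrated so
the *population* prevalence matches a target (default 10%), and the
case-control sample is obtained by rejection sampling from that population —
the way a clinic case series plus a cross-sectional control survey arise.

The defaults mirror the study design this package analyses: 830 cases and
1497 controls, three ethnolinguistic strata (86.3% / 5.4% / 8.3%), young
cases and older controls, and one hemizygous X-chromosome SNP coded {0, 1}
in males at simulation time.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import META_COLUMNS

__all__ = [
    "SimSnp",
    "Stratum",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_population",
    "tune_intercept",
    "expected_prevalence",
    "config_from_annotations",
    "config_from_yaml",
    "config_to_yaml",
]

#: Allele-frequency clip bounds for stratum offsets.
_RAF_CLIP = (0.01, 0.99)
#: Intercept search bracket on the log-odds scale.
_INTERCEPT_BRACKET = (-30.0, 30.0)
#: Grid step for the exact linear-predictor distribution (log-odds units).
_GRID_STEP = 1e-4


@dataclass(frozen=True)
class SimSnp:
    """Simulation truth for one SNP.

    ``risk_allele_freq`` is the population frequency of the risk allele and
    ``per_allele_or`` the true log-additive odds ratio per risk allele.
    ``hwe_violation_factor`` multiplies the heterozygote class (1 = HWE;
    <1 heterozygote deficit, >1 excess) before renormalisation.
    """

    snp_id: str
    risk_allele_freq: float
    per_allele_or: float
    chromosome: str = "1"
    hwe_violation_factor: float = 1.0
    effect_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self):
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ValueError(f"{self.snp_id}: risk_allele_freq must be in (0, 1)")
        if self.per_allele_or <= 0:
            raise ValueError(f"{self.snp_id}: per_allele_or must be positive")
        if self.hwe_violation_factor < 0:
            raise ValueError(f"{self.snp_id}: hwe_violation_factor must be >= 0")

    @property
    def is_x(self) -> bool:
        return str(self.chromosome).upper() == "X"


@dataclass(frozen=True)
class Stratum:
    """An ethnolinguistic stratum.

    ``raf_offset`` shifts risk-allele frequencies additively (scalar, or a
    per-SNP mapping), clipped to (0.01, 0.99); ``disease_log_or`` shifts the
    disease intercept for members of the stratum.  Together they induce the
    stratum confounding a CMH analysis exists to remove.
    """

    label: str
    proportion: float
    raf_offset: float | Mapping[str, float] = 0.0
    disease_log_or: float = 0.0

    def offset_for(self, snp_id: str) -> float:
        if isinstance(self.raf_offset, Mapping):
            return float(self.raf_offset.get(snp_id, 0.0))
        return float(self.raf_offset)


DEFAULT_STRATA = (
    Stratum("Sinhalese", 0.863),
    Stratum("Tamil", 0.054),
    Stratum("Muslim", 0.083),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a simulated case-control study."""

    n_cases: int
    n_controls: int
    snps: Sequence[SimSnp]
    seed: int
    prevalence: float = 0.10
    strata: Sequence[Stratum] = DEFAULT_STRATA
    missing_rate: float = 0.0
    bad_sample_rate: float = 0.0
    sex_ratio: float = 0.44  # proportion male
    case_age_range: tuple[float, float] = (20.0, 60.0)
    control_age_range: tuple[float, float] = (25.0, 75.0)

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not self.snps:
            raise ValueError("at least one SNP is required")
        total = sum(s.proportion for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stratum proportions sum to {total}, not 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.bad_sample_rate <= 1.0:
            raise ValueError("bad_sample_rate must be in [0, 1]")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in config")
        # normalise sequence fields so configs compare equal across
        # construction routes (YAML round trips load lists)
        object.__setattr__(self, "snps", tuple(self.snps))
        object.__setattr__(self, "strata", tuple(self.strata))
        object.__setattr__(self, "case_age_range", tuple(self.case_age_range))
        object.__setattr__(self, "control_age_range", tuple(self.control_age_range))

    @property
    def x_snps(self) -> list[str]:
        return [s.snp_id for s in self.snps if s.is_x]


def genotype_probs(p: float, hwe_factor: float = 1.0) -> np.ndarray:
    """Genotype class probabilities (g = 0, 1, 2 risk alleles).

    Hardy–Weinberg proportions ((1-p)^2, 2p(1-p), p^2) with the heterozygote
    class multiplied by ``hwe_factor`` and the vector renormalised.
    """
    q = 1.0 - p
    probs = np.array([q * q, hwe_factor * 2.0 * p * q, p * p])
    return probs / probs.sum()


def _stratum_raf(snp: SimSnp, stratum: Stratum) -> float:
    return float(np.clip(snp.risk_allele_freq + stratum.offset_for(snp.snp_id), *_RAF_CLIP))


def _cell_lp_pmf(config: SimulationConfig, stratum: Stratum, sex: str) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of the genetic linear predictor sum(ln OR * g) in one
    stratum-by-sex cell, on a fixed grid (step 1e-4 log-odds units)."""
    pmf = np.ones(1)
    base = 0.0
    for snp in config.snps:
        w = np.log(snp.per_allele_or)
        p = _stratum_raf(snp, stratum)
        atoms: dict[int, float] = {}
        if snp.is_x and sex == "M":
            pairs = [(0, 1.0 - p), (int(round(w / _GRID_STEP)), p)]
        else:
            probs = genotype_probs(p, snp.hwe_violation_factor)
            pairs = [
                (0, probs[0]),
                (int(round(w / _GRID_STEP)), probs[1]),
                (int(round(2.0 * w / _GRID_STEP)), probs[2]),
            ]
        for k, v in pairs:
            atoms[k] = atoms.get(k, 0.0) + v
        lo = min(atoms)
        shifted = {k - lo: v for k, v in atoms.items()}
        base += lo * _GRID_STEP
        width = max(shifted)
        new = np.zeros(len(pmf) + width)
        for k, v in shifted.items():
            if v > 0.0:
                new[k : k + len(pmf)] += v * pmf
        pmf = new
    values = base + _GRID_STEP * np.arange(len(pmf))
    return values, pmf


def _expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _cells(config: SimulationConfig):
    """(weight, disease log-odds offset, lp values, lp pmf) per cell."""
    has_x = any(s.is_x for s in config.snps)
    cells = []
    for stratum in config.strata:
        if has_x:
            sexes = [("M", config.sex_ratio), ("F", 1.0 - config.sex_ratio)]
        else:
            sexes = [(None, 1.0)]
        for sex, sex_w in sexes:
            if sex_w <= 0.0:
                continue
            values, pmf = _cell_lp_pmf(config, stratum, sex or "F")
            cells.append((stratum.proportion * sex_w, stratum.disease_log_or, values, pmf))
    return cells


def expected_prevalence(config: SimulationConfig, intercept: float) -> float:
    """Exact population disease probability for a given model intercept."""
    total = 0.0
    for weight, offset, values, pmf in _cells(config):
        total += weight * float(pmf @ _expit(intercept + offset + values))
    return total


def tune_intercept(config: SimulationConfig, tol: float = 1e-6) -> float:
    """Bisect the logistic intercept so expected prevalence equals the target.

    Raises
    ------
    ValueError
        If the target prevalence is unreachable for the configured odds
        ratios and allele frequencies within the search bracket.
    """
    cells = _cells(config)

    def expectation(b0: float) -> float:
        return sum(w * float(pmf @ _expit(b0 + off + vals)) for w, off, vals, pmf in cells)

    lo, hi = _INTERCEPT_BRACKET
    e_lo, e_hi = expectation(lo), expectation(hi)
    if not e_lo <= config.prevalence <= e_hi:
        raise ValueError(
            f"prevalence {config.prevalence} unreachable: attainable range "
            f"[{e_lo:.3g}, {e_hi:.3g}] for the given ORs and allele frequencies"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        e_mid = expectation(mid)
        if abs(e_mid - config.prevalence) < tol:
            return mid
        if e_mid < config.prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_genotypes(
    config: SimulationConfig, stratum_idx: np.ndarray, male: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Vectorised genotype draw for a batch, per stratum-specific RAF."""
    n = len(stratum_idx)
    out = {}
    for snp in config.snps:
        rafs = np.array([_stratum_raf(snp, s) for s in config.strata])
        cums = np.array(
            [np.cumsum(genotype_probs(raf, snp.hwe_violation_factor)) for raf in rafs]
        )
        u = rng.random(n)
        c = cums[stratum_idx]
        g = (u > c[:, 0]).astype(np.int64) + (u > c[:, 1]).astype(np.int64)
        if snp.is_x:
            p = rafs[stratum_idx]
            g = np.where(male, (u < p).astype(np.int64), g)
        out[snp.snp_id] = g
    return out


def simulate_population(
    config: SimulationConfig, n: int, rng: np.random.Generator, intercept: float | None = None
) -> pd.DataFrame:
    """Draw *n* individuals from the prevalence-calibrated population.

    Returns stratum, sex, genotypes and disease status *before* any
    case-control ascertainment, missingness or flag assignment; used
    internally by the rejection sampler and directly by calibration tests.
    """
    if intercept is None:
        intercept = tune_intercept(config)
    props = np.array([s.proportion for s in config.strata])
    stratum_idx = rng.choice(len(props), size=n, p=props / props.sum())
    male = rng.random(n) < config.sex_ratio
    geno = _draw_genotypes(config, stratum_idx, male, rng)
    lp = np.full(n, intercept)
    offsets = np.array([s.disease_log_or for s in config.strata])
    lp += offsets[stratum_idx]
    for snp in config.snps:
        lp += np.log(snp.per_allele_or) * geno[snp.snp_id]
    status = (rng.random(n) < _expit(lp)).astype(np.int64)
    df = pd.DataFrame(
        {
            "status": status,
            "sex": np.where(male, "M", "F"),
            "stratum": [config.strata[i].label for i in stratum_idx],
        }
    )
    for snp in config.snps:
        df[snp.snp_id] = geno[snp.snp_id]
    return df


def simulate_cohort(config: SimulationConfig, max_draws: int | None = None) -> pd.DataFrame:
    """Simulate a full case-control cohort table.

    Rejection-samples the calibrated population until ``n_cases`` cases and
    ``n_controls`` controls are collected, then assigns ages (young cases,
    older controls), applies per-call missingness, and degrades a
    deterministic number of "bad" samples (round(bad_sample_rate * n)) to a
    call rate strictly below 0.8.

    Raises
    ------
    RuntimeError
        If the population draw cap is exceeded before both groups fill.
    """
    rng = np.random.default_rng(config.seed)
    intercept = tune_intercept(config)
    n_total = config.n_cases + config.n_controls
    if max_draws is None:
        max_draws = int(
            20 * (config.n_cases / config.prevalence + config.n_controls / (1 - config.prevalence))
            + 10_000
        )
    cases, controls = [], []
    drawn = 0
    need_cases, need_controls = config.n_cases, config.n_controls
    while need_cases > 0 or need_controls > 0:
        batch = int(
            min(
                max_draws - drawn,
                max(
                    2000,
                    1.3 * need_cases / config.prevalence,
                    1.3 * need_controls / (1 - config.prevalence),
                ),
            )
        )
        if batch <= 0:
            raise RuntimeError(
                f"rejection sampling exceeded the draw cap of {max_draws} individuals "
                f"({len(cases)}/{config.n_cases} cases, "
                f"{len(controls)}/{config.n_controls} controls collected)"
            )
        pop = simulate_population(config, batch, rng, intercept=intercept)
        drawn += batch
        if need_cases > 0:
            got = pop[pop["status"] == 1].head(need_cases)
            cases.append(got)
            need_cases -= len(got)
        if need_controls > 0:
            got = pop[pop["status"] == 0].head(need_controls)
            controls.append(got)
            need_controls -= len(got)
    df = pd.concat(cases + controls, ignore_index=True)

    lo, hi = config.case_age_range
    clo, chi = config.control_age_range
    age = np.where(
        df["status"] == 1,
        rng.uniform(lo, hi, size=n_total),
        rng.uniform(clo, chi, size=n_total),
    ).round(1)
    df.insert(1, "age", age)
    df.insert(0, "sample_id", [f"S{i:05d}" for i in range(1, n_total + 1)])
    df["gada_positive"] = 0
    df["early_insulin"] = 0
    df["mitochondrial"] = 0

    snp_ids = [s.snp_id for s in config.snps]
    geno = df[snp_ids].to_numpy(dtype=float)
    if config.missing_rate > 0:
        geno[rng.random(geno.shape) < config.missing_rate] = np.nan
    n_bad = int(round(config.bad_sample_rate * n_total))
    if n_bad > 0:
        n_snps = len(snp_ids)
        min_missing = int(np.floor(0.2 * n_snps)) + 1  # forces call rate < 0.8
        bad_rows = rng.choice(n_total, size=n_bad, replace=False)
        for row in bad_rows:
            k = int(rng.integers(min_missing, n_snps + 1))
            cols = rng.choice(n_snps, size=k, replace=False)
            geno[row, cols] = np.nan
    df[snp_ids] = geno
    return df[META_COLUMNS + snp_ids]


def config_from_annotations(
    annotations: pd.DataFrame,
    seed: int,
    n_cases: int = 830,
    n_controls: int = 1497,
    or_column: str = "or_adjusted",
    raf_column: str = "raf_study",
    **kwargs,
) -> SimulationConfig:
    """Build a config whose simulation truth is an annotation table's
    published RAFs and odds ratios (one SimSnp per row)."""
    snps = [
        SimSnp(
            snp_id=row["snp_id"],
            chromosome=str(row["chromosome"]),
            risk_allele_freq=float(row[raf_column]),
            per_allele_or=float(row[or_column]),
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
        )
        for _, row in annotations.iterrows()
    ]
    return SimulationConfig(n_cases=n_cases, n_controls=n_controls, snps=snps, seed=seed, **kwargs)


def config_from_yaml(path, seed: int | None = None) -> SimulationConfig:
    """Load a SimulationConfig from YAML; ``seed`` overrides / supplies one."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if seed is not None:
        raw["seed"] = seed
    if "seed" not in raw:
        raise ValueError("a seed is mandatory (in the file or as an argument)")
    raw["snps"] = [SimSnp(**s) for s in raw["snps"]]
    if "strata" in raw:
        raw["strata"] = [Stratum(**s) for s in raw["strata"]]
    for key in ("case_age_range", "control_age_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def config_to_yaml(config: SimulationConfig, path) -> None:
    raw = dataclasses.asdict(config)
    raw["strata"] = [dataclasses.asdict(s) for s in config.strata]
    raw["snps"] = [dataclasses.asdict(s) for s in config.snps]
    raw["case_age_range"] = list(config.case_age_range)
    raw["control_age_range"] = list(config.control_age_range)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
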