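"""SNP annotation tables.

One row per locus: lead SNP id, chromosome, effect/other alleles, the risk
allele in the study and reference populations, and (when supplied by the
user) the reference-population per-allele odds ratio and risk allele
frequency that drive genetic-risk-score weights and power calculations.

The shipped ``table1.tsv`` transcribes the study's published per-SNP
results for 36 loci (36 of 37 genotyped; one failed Hardy–Weinberg QC and
is not listed).  Its ``reference_or`` / ``reference_raf`` columns are
intentionally empty: the European values lived in supplementary material
that is not redistributed here, and must be merged in by the user.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = [
    "snp_id",
    "chromosome",
    "effect_allele",
    "other_allele",
    "risk_allele_study",
    "risk_allele_reference",
]

NUMERIC_COLUMNS = [
    "raf_study",
    "or_adjusted",
    "ci_lo_adjusted",
    "ci_hi_adjusted",
    "p_adjusted",
    "or_cmh",
    "ci_lo_cmh",
    "ci_hi_cmh",
    "p_cmh",
    "reference_or",
    "reference_raf",
]


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if ann["snp_id"].duplicated().any():
        dupes = ann.loc[ann["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_id entries: {dupes}")
    for col in ("risk_allele_study", "risk_allele_reference"):
        ok = (ann[col] == ann["effect_allele"]) | (ann[col] == ann["other_allele"])
        if not ok.all():
            bad = ann.loc[~ok, "snp_id"].tolist()
            raise ValueError(f"{col} not among the SNP's two alleles for: {bad}")
    if "reference_or" in ann.columns:
        vals = ann["reference_or"].dropna()
        if (vals <= 0).any():
            raise ValueError("reference_or must be positive")
    return ann


def load_annotations(path) -> pd.DataFrame:
    """Read a tab-separated annotation table and validate it."""
    ann = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col in NUMERIC_COLUMNS:
        if col in ann.columns:
            ann[col] = pd.to_numeric(ann[col], errors="raise")
    return validate_annotations(ann)


def load_table1() -> pd.DataFrame:
    """The packaged transcription of the study's per-SNP result table.

    Contains, per SNP: risk alleles in both populations, combined-sample
    risk allele frequency, and the age/sex-adjusted logistic and
    ethnicity-stratified CMH odds ratios with 95% CIs and p-values.
    ``reference_or``/``reference_raf`` are NA (user-supplied input).
    """
    with resources.files("t2drep.data").joinpath("table1.tsv").open("r") as fh:
        return load_annotations(fh)


def x_snp_ids(ann: pd.DataFrame) -> list[str]:
    """SNP ids annotated on the X chromosome."""
    chrom = ann["chromosome"].astype(str).str.upper()
    return ann.loc[chrom == "X", "snp_id"].tolist()


def merge_reference(ann: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Fill ``reference_or``/``reference_raf`` from a table keyed by snp_id."""
    ref = reference.set_index("snp_id")
    out = ann.copy()
    for col in ("reference_or", "reference_raf"):
        if col in ref.columns:
            filled = out["snp_id"].map(ref[col])
            out[col] = np.where(out.get(col, pd.Series(np.nan)).isna(), filled, out[col])
    return validate_annotations(out)
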