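"""Individual-level cohort tables.

A cohort is a :class:`pandas.DataFrame` with one row per sample. The first
eight columns are fixed metadata (:data:`META_COLUMNS`); every remaining
column is a SNP holding a risk/effect-allele dosage.  Autosomal dosages and
female X dosages live in {0, 1, 2}; male X dosages are hemizygous and live
in {0, 1}.  Missing genotype calls are ``NaN`` in memory and ``NA`` on disk.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

#: Fixed metadata columns, in file order.  ``status`` is 1 = case, 0 = control;
#: ``gada_positive`` may be missing (GADA titre not measured).
META_COLUMNS = [
    "sample_id",
    "status",
    "age",
    "sex",
    "stratum",
    "gada_positive",
    "early_insulin",
    "mitochondrial",
]

_FLAG_COLUMNS = ["gada_positive", "early_insulin", "mitochondrial"]


class CohortParseError(ValueError):
    """A cohort file violated the format contract.

    Carries the offending 1-based file line (header = line 1) and column
    name so the message pinpoints the bad cell.
    """

    def __init__(self, message: str, line: int | None = None, column: str | None = None):
        loc = ""
        if line is not None:
            loc += f" (line {line}"
            if column is not None:
                loc += f", column {column!r}"
            loc += ")"
        super().__init__(message + loc)
        self.line = line
        self.column = column


def snp_columns(cohort: pd.DataFrame) -> list[str]:
    """Return the genotype (non-metadata) column names, in table order."""
    return [c for c in cohort.columns if c not in META_COLUMNS]


def ploidy(cohort: pd.DataFrame, snp_id: str, x_snps: Iterable[str] = ()) -> np.ndarray:
    """Alleles carried per sample at one SNP: 2, except 1 for males on X."""
    if snp_id in set(x_snps):
        return np.where(cohort["sex"].to_numpy() == "M", 1, 2)
    return np.full(len(cohort), 2)


def validate_cohort(
    cohort: pd.DataFrame,
    x_snps: Iterable[str] = (),
    valid_strata: Sequence[str] | None = None,
) -> None:
    """Check structural invariants, raising :class:`CohortParseError`.

    Line numbers in error messages assume the row order matches a file with
    a single header line (data row *i* of the frame is file line ``i + 2``).
    """
    missing = [c for c in META_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortParseError(f"missing required columns: {missing}")
    bad_status = ~cohort["status"].isin([0, 1])
    if bad_status.any():
        i = int(np.flatnonzero(bad_status)[0])
        raise CohortParseError("status must be 0 or 1", line=i + 2, column="status")
    bad_sex = ~cohort["sex"].isin(["M", "F"])
    if bad_sex.any():
        i = int(np.flatnonzero(bad_sex)[0])
        raise CohortParseError("sex must be 'M' or 'F'", line=i + 2, column="sex")
    if valid_strata is not None:
        bad = ~cohort["stratum"].isin(list(valid_strata))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise CohortParseError(
                f"unknown stratum {cohort['stratum'].iloc[i]!r}", line=i + 2, column="stratum"
            )
    x_set = set(x_snps)
    male = cohort["sex"].to_numpy() == "M"
    for snp in snp_columns(cohort):
        d = cohort[snp].to_numpy(dtype=float)
        ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
        if not ok.all():
            i = int(np.flatnonzero(~ok)[0])
            raise CohortParseError(
                f"dosage {cohort[snp].iloc[i]!r} outside {{0, 1, 2, NA}}",
                line=i + 2,
                column=snp,
            )
        if snp in x_set:
            bad = male & (d == 2.0)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise CohortParseError(
                    "male X-chromosome dosage must be 0 or 1 (hemizygous)",
                    line=i + 2,
                    column=snp,
                )


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as tab-separated text with ``NA`` for missing calls."""
    out = cohort.copy()
    for col in _FLAG_COLUMNS + snp_columns(out):
        # render 1.0 -> "1" so the round trip is textually stable
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort(
    path,
    x_snps: Iterable[str] = (),
    valid_strata: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a tab-separated cohort file, validating every dosage.

    Raises
    ------
    CohortParseError
        On missing columns, dosages outside the allowed set for the
        sample's sex and SNP chromosome, or (when ``valid_strata`` is
        given) an unrecognised stratum label.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        na_values=["NA"],
        keep_default_na=False,
        dtype={"sample_id": str, "sex": str, "stratum": str},
    )
    if "status" in df.columns:
        try:
            df["status"] = pd.to_numeric(df["status"])
        except ValueError as exc:
            raise CohortParseError(f"non-numeric status: {exc}") from exc
    for col in df.columns:
        if col in ("sample_id", "sex", "stratum"):
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except ValueError as exc:
            raise CohortParseError(f"non-numeric value in column {col!r}: {exc}", column=col) from exc
    validate_cohort(df, x_snps=x_snps, valid_strata=valid_strata)
    return df


def call_rates(cohort: pd.DataFrame) -> pd.Series:
    """Per-sample fraction of non-missing genotype calls."""
    snps = snp_columns(cohort)
    if not snps:
        raise ValueError("cohort has no SNP columns")
    rates = cohort[snps].notna().sum(axis=1) / len(snps)
    return pd.Series(rates.to_numpy(), index=cohort["sample_id"].to_numpy(), name="call_rate")


def write_plink(cohort: pd.DataFrame, annotations: pd.DataFrame, prefix: str) -> None:
    """Export to the PLINK text dialect (.ped / .map) for interoperability.

    Dosages are expanded to allele pairs using the annotation's effect and
    other alleles (dosage counts the effect allele); missing calls become
    ``0 0``.  Hemizygous male X genotypes are written as PLINK-style
    homozygotes.  The .map has chromosome, SNP id, 0 cM, and a dummy
    1-based position.
    """
    ann = annotations.set_index("snp_id")
    snps = [s for s in snp_columns(cohort) if s in ann.index]
    with open(f"{prefix}.map", "w") as fh:
        for pos, snp in enumerate(snps, start=1):
            chrom = ann.loc[snp, "chromosome"]
            fh.write(f"{chrom}\t{snp}\t0\t{pos}\n")
    buf = io.StringIO()
    sex_code = {"M": "1", "F": "2"}
    for _, row in cohort.iterrows():
        fields = [
            str(row["sample_id"]),
            str(row["sample_id"]),
            "0",
            "0",
            sex_code[row["sex"]],
            "2" if row["status"] == 1 else "1",
        ]
        for snp in snps:
            d = row[snp]
            eff = str(ann.loc[snp, "effect_allele"])
            oth = str(ann.loc[snp, "other_allele"])
            if pd.isna(d):
                fields += ["0", "0"]
            elif d == 0:
                fields += [oth, oth]
            elif d == 2:
                fields += [eff, eff]
            elif row["sex"] == "M" and str(ann.loc[snp, "chromosome"]) == "X":
                fields += [eff, eff]  # hemizygous carrier
            else:
                fields += [eff, oth]
        buf.write(" ".join(fields) + "\n")
    with open(f"{prefix}.ped", "w") as fh:
        fh.write(buf.getvalue())
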