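"""End-to-end replication pipeline.

Sequences simulate/ingest -> case definition -> call-rate filter -> HWE
filter -> per-SNP association -> genetic risk score -> trans-ethnic
comparison -> power, logging row counts at every stage and writing a run
manifest (seed, thresholds, config hash, package versions) alongside the
stage outputs.  All tabular interchange is TSV with explicit headers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import load_annotations, load_table1, merge_reference, x_snp_ids
from .association import run_association_panel
from .cohort import read_cohort, write_cohort
from .qc import QcConfig, apply_case_definition, filter_hwe, filter_sample_call_rate
from .risk_score import compute_grs, grs_association, quintile_analysis, weights_from_annotations
from .simulate import config_from_yaml, simulate_cohort
from .transethnic import (
    binomial_sign_test,
    build_comparison,
    compare_allele_frequencies,
    compare_effect_sizes,
    count_consistent,
    nominal_counts,
)
from .power import power_panel

log = logging.getLogger("t2drep")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    outdir: str
    seed: int
    annotations: str = "table1"  # path to TSV, or the packaged table
    cohort: str | None = None  # existing cohort TSV ...
    simulation: str | None = None  # ... or a simulation config YAML
    reference: str | None = None  # optional reference OR/RAF table
    qc: QcConfig = field(default_factory=QcConfig)
    grs_weight_column: str = "reference_or"
    grs_min_fraction: float = 0.8
    power_prevalence: float = 0.10
    power_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if seed is not None:
            raw["seed"] = seed
        if "qc" in raw:
            raw["qc"] = QcConfig(**raw["qc"])
        return cls(**raw)


def _config_digest(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, writing artifacts under ``config.outdir``.

    Returns the manifest dict.  A stage failure aborts with the stage name;
    artifacts written so far are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "t2drep",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_sha256_16": _config_digest(config),
        "stages": {},
    }
    stage = "load_annotations"
    try:
        if config.annotations == "table1":
            ann = load_table1()
        else:
            ann = load_annotations(config.annotations)
        if config.reference:
            ann = merge_reference(ann, pd.read_csv(config.reference, sep="\t"))

        stage = "cohort"
        if config.cohort:
            cohort_path = Path(config.cohort)
            if not cohort_path.exists():
                raise FileNotFoundError(f"cohort file not found: {cohort_path}")
            cohort = read_cohort(cohort_path, x_snps=x_snp_ids(ann))
        elif config.simulation:
            sim = config_from_yaml(config.simulation, seed=config.seed)
            cohort = simulate_cohort(sim)
            write_cohort(cohort, outdir / "cohort.tsv")
        else:
            raise ValueError("config must provide either 'cohort' or 'simulation'")
        manifest["stages"]["cohort"] = {"n_samples": len(cohort)}
        log.info("cohort: %d samples", len(cohort))

        stage = "qc"
        reports = []
        cohort, rep = apply_case_definition(cohort)
        reports.append(rep)
        cohort, rep = filter_sample_call_rate(cohort, config.qc)
        reports.append(rep)
        cohort, ann, rep = filter_hwe(cohort, ann, config.qc)
        reports.append(rep)
        qc_payload = []
        for rep in reports:
            rep.check()
            log.info("%s", rep)
            qc_payload.append(json.loads(rep.to_json()))
            manifest["stages"][rep.step] = {
                "n_input": rep.n_input,
                "n_remaining": rep.n_remaining,
                "excluded": rep.counts,
            }
        # trim the per-sample call-rate series out of the JSON artifact
        for payload in qc_payload:
            payload["details"].pop("call_rates", None)
        (outdir / "qc_report.json").write_text(json.dumps(qc_payload, indent=2))

        stage = "association"
        assoc = run_association_panel(cohort, ann)
        assoc.to_csv(outdir / "association.tsv", sep="\t", index=False, na_rep="NA")
        manifest["stages"]["association"] = {"n_snps": len(assoc)}

        stage = "grs"
        weight_col = config.grs_weight_column
        if weight_col not in ann.columns or ann[weight_col].isna().any():
            # no reference weights supplied: fall back to the study's own
            # adjusted ORs if present (sensible for simulated cohorts where
            # they are the design values), else skip with a note
            fallback = "or_adjusted" if "or_adjusted" in ann.columns else None
            if fallback and ann[fallback].notna().all():
                log.warning("grs: %s unavailable; weighting by %s", weight_col, fallback)
                weight_col = fallback
            else:
                weight_col = None
        if weight_col:
            weights = weights_from_annotations(ann, column=weight_col)
            scores = compute_grs(
                cohort, weights, x_snps=x_snp_ids(ann), min_fraction=config.grs_min_fraction
            )
            scores.to_csv(outdir / "grs_scores.tsv", sep="\t", index=False, na_rep="NA")
            summary = {"weight_column": weight_col, "n_scored": int(scores["scored"].sum())}
            try:
                fit = grs_association(cohort, scores)
                summary["per_unit"] = dataclasses.asdict(fit)
                quint = quintile_analysis(cohort, scores)
                summary["quintiles"] = quint.to_dict(orient="records")
            except (ValueError, RuntimeError) as exc:
                summary["note"] = str(exc)
            (outdir / "grs_summary.json").write_text(json.dumps(summary, indent=2, default=float))
            manifest["stages"]["grs"] = {"n_scored": summary["n_scored"]}
        else:
            manifest["stages"]["grs"] = {"skipped": "no usable weight column"}

        stage = "compare"
        source = ann if "p_adjusted" in ann.columns else ann.merge(
            assoc.rename(columns={"raf": "raf_study"}), on="snp_id", suffixes=("", "_fit")
        )
        rows = build_comparison(source)
        k, n = count_consistent(rows)
        compare_payload: dict = {
            "directionally_consistent": k,
            "n_snps": n,
            "sign_test_p": binomial_sign_test(k, n),
        }
        if {"nominally_significant_adjusted", "nominally_significant_cmh"} <= set(rows.columns):
            counts = nominal_counts(rows)
            compare_payload["nominal"] = counts._asdict()
        if rows["reference_or"].notna().all():
            compare_payload["or_correlation"] = compare_effect_sizes(rows)._asdict()
        if rows["reference_raf"].notna().all():
            compare_payload["raf_correlation"] = compare_allele_frequencies(rows)._asdict()
        (outdir / "comparison.json").write_text(json.dumps(compare_payload, indent=2, default=float))
        manifest["stages"]["compare"] = {"directionally_consistent": f"{k}/{n}"}

        stage = "power"
        n_cases = int((cohort["status"] == 1).sum())
        n_controls = int((cohort["status"] == 0).sum())
        or_col = "reference_or" if ann.get("reference_or") is not None and ann["reference_or"].notna().any() else "or_adjusted"
        raf_col = "reference_raf" if ann.get("reference_raf") is not None and ann["reference_raf"].notna().any() else "raf_study"
        panel = power_panel(
            ann, n_cases, n_controls,
            prevalence=config.power_prevalence, alpha=config.power_alpha,
            or_column=or_col, raf_column=raf_col,
        )
        panel.to_csv(outdir / "power.tsv", sep="\t", index=False, na_rep="NA")
        manifest["stages"]["power"] = {"n_snps": len(panel), "or_column": or_col}
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
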