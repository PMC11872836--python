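"""End-to-end seeded run: simulate -> clock -> ewas -> states -> enrich.

Every stage writes its table under the output directory and contributes to a
machine-readable ``report.json``; identical config + seed gives a
byte-identical report.
"""

from __future__ import annotations

import copy
import json
import logging
import math
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import clock, enrichment, ewas, meth_io, state_analysis
from .synthetic_methylome import SimulationDesign, simulate_annotation, simulate_cohort, simulate_truth

logger = logging.getLogger(__name__)

REPORT_VERSION = 1

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "alpha": 0.01,            # headline nominal threshold
    "secondary_alpha": 0.05,
    "trim": 0.05,
    "state_z_threshold": 1.645,
    "simulate": {},           # SimulationDesign overrides; None disables simulation
    "inputs": None,           # {"beta":..., "samples":..., "annotation":...}
    "clock": {
        "transform": "identity",
        "l1_ratio": 0.5,
        "lam": 0.01,
        "train_group_sizes": {"young": 10, "old_control": 10, "old_treated": 2},
    },
}


class PipelineError(RuntimeError):
    """A stage failed; the stage name is recorded."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (user or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else repr(v)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_full(config: dict | None = None, out_dir="epireverse_run",
             seed: int | None = None) -> dict:
    """Run every stage and return the report dict (also written as JSON)."""
    cfg = merge_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"report_version": REPORT_VERSION, "seed": cfg["seed"],
                    "config": cfg, "stages": {}}

    def stage(name):
        logger.info("stage %s ...", name)
        return _StageTimer(name, report)

    alpha = float(cfg["alpha"])

    # ---- inputs -----------------------------------------------------------
    with stage("simulate"):
        if cfg["inputs"] is not None:
            paths = cfg["inputs"]
            matrix = meth_io.read_beta_matrix(paths["beta"])
            samples = meth_io.read_sample_sheet(paths["samples"])
            annotation = meth_io.read_cpg_annotation(paths["annotation"])
            design = truth = None
            report["stages"]["simulate"] = {"mode": "loaded", "paths": dict(paths)}
        else:
            design = SimulationDesign(**(cfg["simulate"] or {}), seed=cfg["seed"]) \
                if "seed" not in (cfg["simulate"] or {}) \
                else SimulationDesign(**cfg["simulate"])
            annotation = simulate_annotation(design)
            truth = simulate_truth(design, annotation)
            matrix, samples, truth = simulate_cohort(design, annotation, truth)
            meth_io.write_beta_matrix(matrix, out / "beta.tsv")
            meth_io.write_sample_sheet(samples, out / "samples.csv")
            meth_io.write_cpg_annotation(annotation, out / "annotation.tsv")
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            report["stages"]["simulate"] = {
                "mode": "simulated", "n_cpgs": design.n_cpgs,
                "n_samples": len(samples.sample_ids),
            }

    # ---- clock ------------------------------------------------------------
    with stage("clock"):
        ccfg = cfg["clock"]
        if design is not None:
            train_design = copy.deepcopy(design)
            train_design.group_sizes = dict(ccfg["train_group_sizes"])
            train_mat, train_sheet, _ = simulate_cohort(
                train_design, annotation, truth, sample_seed=cfg["seed"] + 7919)
            training_mode = "independent_cohort"
        else:
            train_mat, train_sheet = matrix, samples
            training_mode = "in_sample"
        fit_ids = (train_sheet.ids_for_group("young")
                   + train_sheet.ids_for_group("old_control"))
        sub = train_mat.subset_samples(fit_ids)
        lifespan = float(train_sheet.frame["max_lifespan_years"].iloc[0])
        model = clock.fit_clock(
            sub, train_sheet.ages(fit_ids),
            transform=ccfg["transform"],
            max_lifespan_years=lifespan if ccfg["transform"] == "relative_age" else None,
            lam=ccfg["lam"], l1_ratio=ccfg["l1_ratio"], seed=cfg["seed"])
        meth_io.write_clock_coefficients(model, out / "clock_model.csv")
        predictions = clock.apply_clock(model, matrix)
        pd.DataFrame({"sample_id": matrix.sample_ids,
                      "predicted_age_years": predictions}).to_csv(
            out / "clock_predictions.tsv", sep="\t", index=False)
        comparison = clock.compare_groups(
            dict(zip(matrix.sample_ids, predictions)), samples,
            contrast=("old_control", "old_treated"))
        report["stages"]["clock"] = {
            "training": training_mode,
            "transform": ccfg["transform"],
            "n_terms": model.n_terms,
            "comparison": vars(comparison),
        }

    # ---- ewas -------------------------------------------------------------
    with stage("ewas"):
        age_scan = ewas.ewas_scan(matrix, samples, "age")
        treat_scan = ewas.ewas_scan(matrix, samples, "treatment")
        table = ewas.build_ewas_table(age_scan, treat_scan, alpha=alpha)
        overlap = ewas.overlap_summary(table["label"])
        rev_all = ewas.reversal_correlation(table["z_age"], table["z_treat"], "all")
        rev_sig = None
        zmask = table["label"] != "null"
        if int(zmask.sum()) >= 3:
            rev_sig = ewas.reversal_correlation(
                table["z_age"], table["z_treat"], "significant_either", alpha=alpha)
        for scan, name in ((age_scan, "age"), (treat_scan, "treatment")):
            _write_manhattan(scan, annotation, alpha, out / f"ewas_{name}.tsv")
        table.to_csv(out / "ewas_table.tsv", sep="\t", index=False)
        report["stages"]["ewas"] = {
            "alpha": alpha,
            "n_age_hits": int((age_scan["p"] < alpha).sum()),
            "n_treatment_hits": int((treat_scan["p"] < alpha).sum()),
            "overlap": overlap,
            "reversal_r_all": rev_all[0], "reversal_p_all": rev_all[1],
            "reversal_r_significant": None if rev_sig is None else rev_sig[0],
            "reversal_p_significant": None if rev_sig is None else rev_sig[1],
        }

    # ---- states -----------------------------------------------------------
    with stage("states"):
        summary = state_analysis.state_effects(
            matrix, annotation, samples, trim=float(cfg["trim"]))
        r_state, p_state, classes = state_analysis.state_reversal(
            summary, z_threshold=float(cfg["state_z_threshold"]))
        summary.table.to_csv(out / "state_summary.tsv", sep="\t", index=False)
        summary.table[["state", "z_age", "z_treat"]].to_csv(
            out / "state_scatter.tsv", sep="\t", index=False)
        report["stages"]["states"] = {
            "r": r_state, "p": p_state, "classes": classes,
            "n_eligible": int(summary.table["eligible"].sum()),
        }

    # ---- enrichment -------------------------------------------------------
    with stage("enrich"):
        merged = age_scan.set_index("cpg_id")
        hits = merged[merged["p"] < alpha]
        gain_hits = list(hits[hits["z"] > 0].index)
        loss_hits = list(hits[hits["z"] < 0].index)
        background = annotation.subset(list(merged.index))
        enrich_report = {}
        for name, ids in (("gain", gain_hits), ("loss", loss_hits)):
            if not ids:
                enrich_report[name] = None
                continue
            tss = enrichment.tss_position_enrichment(ids, background, direction=name)
            states = enrichment.state_enrichment(ids, background, direction=name)
            tss.to_csv(out / f"enrich_tss_{name}.tsv", sep="\t", index=False)
            states.to_csv(out / f"enrich_states_{name}.tsv", sep="\t", index=False)
            enrich_report[name] = {
                "n_hits": len(ids),
                "tss": tss[["bin", "odds_ratio", "p", "stars"]].to_dict("records"),
                "states": states[["state", "fold", "p", "stars"]].to_dict("records"),
            }
        ann_idx = background.indexed().loc[list(merged.index)]
        diff, t_isl, p_isl = enrichment.island_status_comparison(
            merged["z"].to_numpy(), ann_idx["island"].to_numpy())
        enrich_report["island"] = {"mean_difference": diff, "t": t_isl, "p": p_isl}
        report["stages"]["enrich"] = enrich_report

    report_path = out / "report.json"
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("report written to %s", report_path)
    return report


def _write_manhattan(scan: pd.DataFrame, annotation, alpha: float, path) -> None:
    ann = annotation.indexed()
    df = scan.join(ann[["chrom", "start"]], on="cpg_id")
    df["significant"] = df["p"] < alpha
    df["direction"] = np.where(df["z"] > 0, "gain", "loss")
    cols = ["cpg_id", "chrom", "start", "z", "p", "significant", "direction"]
    df[cols].rename(columns={"start": "pos"}).to_csv(path, sep="\t", index=False)


class _StageTimer:
    def __init__(self, name: str, report: dict):
        self.name = name
        self.report = report

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.t0
        logger.info("stage %s finished in %.2fs", self.name, elapsed)
        if exc is not None:
            raise PipelineError(self.name, exc) from exc
        return False
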