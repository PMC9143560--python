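"""End-to-end orchestration: synth/load -> preprocess -> fit -> score -> eval.

A single :class:`RunConfig` (YAML-loadable) drives the run; every stage
writes plain-text artifacts (TSV/CSV/JSON) into the output directory and
the final manifest records each artifact with a SHA-256 hash, so a rerun
with the same config and seeds is bit-identical.

Sensitivity toggles: ``swap`` reruns the pipeline with the cohort roles
exchanged; ``extreme_weight_factor`` up-weights the outcome's extreme
quintiles in both stages of the penalized fit (ridge initialization and
the L1 stage).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from . import synthdata as sd
from .adalasso import AdaptiveLasso
from .pathway import read_pathways, run_ora
from .score import (apply_metss, build_metss, eval_models, expand_covariates,
                    extreme_quintile_weights, predicted_vs_observed)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "swap_cohorts", "run_cohort_pair"]

DEFAULT_COVARIATES = ["sex", "age", "height_cm", "race", "bmi",
                      "smoking_status", "pack_years", "site"]


@dataclass
class RunConfig:
    """Configuration for a full run.

    Either ``train_values``/``train_clinical``/``valid_values``/
    ``valid_clinical`` point at cohort files, or ``synth`` holds inline
    :class:`~metss.synthdata.SynthConfig` fields and the cohorts are
    generated.
    """

    out_dir: str = "metss_run"
    synth: dict | None = None
    train_values: str | None = None
    train_clinical: str | None = None
    valid_values: str | None = None
    valid_clinical: str | None = None
    outcomes: list = field(default_factory=lambda: ["fev1"])
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    batch_col: str = "batch"
    missing_low: float = 0.20
    missing_high: float = 0.80
    knn_k: int = 10
    folds: int = 10
    seed: int = 0
    n_lambda: int = 100
    extreme_weight_factor: float | None = None
    swap: bool = False
    pathway_gmt: str | None = None
    pathway_edges_dir: str | None = None
    qc_sd_limit: float = 3.0

    def __post_init__(self):
        if not (0 <= self.missing_low < self.missing_high <= 1):
            raise ValueError("missingness thresholds must satisfy 0<=low<high<=1")
        if self.synth is None and not (self.train_values and self.valid_values):
            raise ValueError("config needs either synth settings or cohort files")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        return cls(**obj)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_cohort(values_path, clinical_path, batch_col) -> sd.CohortData:
    clin = pd.read_csv(clinical_path, index_col="sample_id")
    matrix = pp.read_abundance_tsv(values_path, clin, batch_col=batch_col)
    return sd.CohortData(abundance=matrix, clinical=clin)


def _get_cohorts(config: RunConfig, out: Path):
    """Load or synthesize the two cohorts; write synth artifacts if generated."""
    if config.synth is not None:
        scfg = sd.SynthConfig(**{**config.synth,
                                 "seed": config.synth.get("seed", config.seed),
                                 "outcomes": tuple(config.outcomes)})
        train, valid, truth = sd.generate_cohort_pair(scfg)
        sd.write_cohort(train, out / "train_abundance.tsv", out / "train_clinical.csv")
        sd.write_cohort(valid, out / "valid_abundance.tsv", out / "valid_clinical.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump({o: json.loads(t.to_json()) for o, t in truth.items()}, fh)
        return train, valid, truth
    train = _load_cohort(config.train_values, config.train_clinical, config.batch_col)
    valid = _load_cohort(config.valid_values, config.valid_clinical, config.batch_col)
    return train, valid, None


def run_cohort_pair(train: sd.CohortData, valid: sd.CohortData,
                    config: RunConfig, out: Path | None = None,
                    tag: str = "") -> dict:
    """Preprocess, fit, score and evaluate one train/valid assignment.

    Returns a dict of in-memory results keyed by outcome; writes artifacts
    when ``out`` is given.
    """
    # preprocessing ----------------------------------------------------
    tr_norm = pp.batch_median_normalize(train.abundance)
    kept_tr, removed_tr = pp.subject_qc_filter(tr_norm, sd_limit=config.qc_sd_limit)
    va_norm = pp.batch_median_normalize(valid.abundance)
    kept_va, removed_va = pp.subject_qc_filter(va_norm, sd_limit=config.qc_sd_limit)
    logger.info("%sQC removed %d training and %d validation subject(s)",
                tag, len(removed_tr), len(removed_va))
    tr_mat = train.abundance.subset_samples(kept_tr)
    va_mat = valid.abundance.subset_samples(kept_va)
    tr_clin = train.clinical.loc[kept_tr]
    va_clin = valid.clinical.loc[kept_va]

    cat_tr = pp.categorize_missingness(tr_mat, config.missing_low, config.missing_high)
    cat_va = pp.categorize_missingness(va_mat, config.missing_low, config.missing_high)
    plan = pp.harmonize(cat_tr, cat_va)
    counts = plan["handling"].value_counts().to_dict()
    logger.info("%sharmonized features: %s", tag, counts)

    tr_design = pp.make_design(tr_mat, plan=plan, k=config.knn_k)
    va_design = pp.make_design(va_mat, recipe=tr_design.recipe)

    compare = pp.cohort_compare(tr_clin, va_clin)

    results = {"qc": {"train_removed": removed_tr, "valid_removed": removed_va},
               "plan_counts": counts, "cohort_compare": compare,
               "outcomes": {}}

    for outcome in config.outcomes:
        y_tr = tr_clin[outcome].to_numpy(float)
        obs_w = None
        if config.extreme_weight_factor is not None:
            obs_w = extreme_quintile_weights(y_tr, config.extreme_weight_factor)
        model = AdaptiveLasso(y_tr, tr_design.design.to_numpy(float),
                              feature_names=tr_design.feature_names,
                              obs_weights=obs_w)
        fit = model.fit_cv(folds=config.folds, seed=config.seed,
                           n_lambda=config.n_lambda)
        logger.info("%s[%s] selected %d features at lambda=%.4g",
                    tag, outcome, fit.n_selected, fit.lambda_min)
        metss = build_metss(fit)
        s_tr = apply_metss(metss, tr_design.design)
        s_va = apply_metss(metss, va_design.design)

        cov_tr = expand_covariates(tr_clin, config.covariates)
        cov_va = expand_covariates(va_clin, config.covariates)
        eval_tr = eval_models(y_tr, s_tr, cov_tr)
        y_va = va_clin[outcome].to_numpy(float)
        eval_va = eval_models(y_va, s_va, cov_va)
        slope_va, icpt_va = predicted_vs_observed(y_va, s_va)

        results["outcomes"][outcome] = {
            "fit": fit, "metss": metss,
            "scores_train": s_tr, "scores_valid": s_va,
            "eval_train": eval_tr, "eval_valid": eval_va,
            "pred_obs_slope_valid": slope_va,
            "pred_obs_intercept_valid": icpt_va,
        }

        if config.pathway_gmt:
            pathways = read_pathways(config.pathway_gmt,
                                     edges_dir=config.pathway_edges_dir)
            universe = [f for f in tr_design.feature_names
                        if not f.endswith("__present")]
            selected = [f for f in metss.features if not f.endswith("__present")]
            ora = run_ora(selected, pathways, universe)
            results["outcomes"][outcome]["ora"] = ora

    if out is not None:
        _write_artifacts(results, tr_design, va_design, compare, out, tag)
    return results


def _write_artifacts(results, tr_design, va_design, compare, out: Path, tag):
    pre = f"{tag}" if tag else ""
    tr_design.to_tsv(out / f"{pre}train_design.tsv")
    va_design.to_tsv(out / f"{pre}valid_design.tsv")
    tr_design.recipe.to_json(out / f"{pre}recipe.json")
    compare.to_csv(out / f"{pre}cohort_compare.tsv", sep="\t", index=False)
    with open(out / f"{pre}qc.json", "w") as fh:
        json.dump(results["qc"], fh)
    for outcome, r in results["outcomes"].items():
        r["fit"].to_json(out / f"{pre}{outcome}_adalasso_fit.json")
        r["fit"].cv_curve_tsv(out / f"{pre}{outcome}_cv_curve.tsv")
        r["metss"].to_json(out / f"{pre}{outcome}_metss.json")
        pd.DataFrame({"train": r["scores_train"]}).to_csv(
            out / f"{pre}{outcome}_scores_train.tsv", sep="\t")
        pd.DataFrame({"valid": r["scores_valid"]}).to_csv(
            out / f"{pre}{outcome}_scores_valid.tsv", sep="\t")
        evdf = pd.concat({"train": r["eval_train"].to_frame(),
                          "valid": r["eval_valid"].to_frame()}, names=["cohort"])
        evdf.to_csv(out / f"{pre}{outcome}_model_eval.tsv", sep="\t")
        with open(out / f"{pre}{outcome}_pred_vs_obs.json", "w") as fh:
            json.dump({"slope": r["pred_obs_slope_valid"],
                       "intercept": r["pred_obs_intercept_valid"]}, fh)
        if "ora" in r:
            r["ora"].to_csv(out / f"{pre}{outcome}_ora.tsv", sep="\t", index=False)


def swap_cohorts(train, valid, config: RunConfig, out: Path | None = None):
    """Rerun the full pipeline with the cohort roles exchanged."""
    return run_cohort_pair(valid, train, config, out=out, tag="swapped_")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run end to end; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train, valid, truth = _get_cohorts(config, out)
    results = run_cohort_pair(train, valid, config, out=out)
    if config.swap:
        swap_cohorts(train, valid, config, out=out)
    cfg_dict = asdict(config)
    manifest = {
        "config": cfg_dict,
        "artifacts": {p.name: _sha256(p) for p in sorted(out.iterdir())
                      if p.is_file() and p.name != "manifest.json"},
        "selected": {o: results["outcomes"][o]["fit"].n_selected
                     for o in config.outcomes},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
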