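"""End-to-end orchestration: simulate/load -> fit -> integrate -> evidence -> RFX -> stats.

Every stage writes its tidy table to the output directory, and a JSON manifest
records the configuration, seeds, package version and SHA-256 of every output
file, so a run is fully re-derivable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .bayes_integration import build_subject_models, models_table
from .behavioral_stats import (
    apply_subsample_cutoffs,
    pearson_correlation,
    regress_placebo_on_sigmas,
    summarize_cohort,
)
from .errors import InputError, ParameterError
from .gaussian_fit import GaussianParams, fit_all_subjects, params_from_row
from .model_evidence import compare_models, evidence_table, positive_evidence_ratio
from .rfx_bms import rfx_model_selection
from .synthetic_data import TRIAL_COLUMNS, CohortConfig, simulate_cohort

logger = logging.getLogger("placebayes")

REQUIRED_TRIAL_COLUMNS = set(TRIAL_COLUMNS)


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig | str | Path  # config to simulate, or path to a trial CSV
    output_dir: str | Path
    sigma_floor: float = 0.5
    sigma_obs_convention: Literal["n_minus_1", "n"] = "n_minus_1"
    evidence_model_input: Literal["posterior", "prior"] = "posterior"
    per_threshold: float = 3.0
    rfx_prior_alpha: float = 1.0
    rfx_seed: int = 0
    center_covariates: bool = False

    def __post_init__(self):
        if self.sigma_obs_convention not in ("n_minus_1", "n"):
            raise ParameterError(f"bad sigma_obs_convention {self.sigma_obs_convention!r}")
        if self.evidence_model_input not in ("posterior", "prior"):
            raise ParameterError(f"bad evidence_model_input {self.evidence_model_input!r}")
        if self.per_threshold <= 1:
            raise ParameterError("per_threshold must exceed 1")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read an intermediate pipeline CSV.

    Default-NA parsing is disabled so the literal model name "null" survives a
    round trip through disk.
    """
    try:
        return pd.read_csv(path, keep_default_na=False, na_values=[""])
    except pd.errors.ParserError as exc:
        raise InputError(f"cannot parse {path}: {exc}") from exc


def load_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-rating CSV (UTF-8, '.' decimal, header required)."""
    path = Path(path)
    trials = read_table(path)
    missing = REQUIRED_TRIAL_COLUMNS - set(trials.columns)
    if missing:
        raise InputError(f"{path} lacks required columns {sorted(missing)}")
    vas = pd.to_numeric(trials["vas"], errors="coerce")
    bad = trials.index[vas.isna() | (vas < 0) | (vas > 100)]
    if len(bad):
        # +2: one for the header, one for 1-based line numbering
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise InputError(f"{path}: invalid VAS values at line(s) {lines}")
    trials["vas"] = vas
    return trials


def compute_models(fits: pd.DataFrame) -> pd.DataFrame:
    """Integrate fitted priors/likelihoods into posterior predictions per subject."""
    models = []
    for subject_id, sub in fits.groupby("subject_id", sort=False):
        by_model = {row["model"]: row for _, row in sub.iterrows()}
        bayes_prior = params_from_row(by_model["bayes"], "prior")
        null_prior = params_from_row(by_model["null"], "prior")
        likelihood = params_from_row(by_model["bayes"], "like")
        models.extend(build_subject_models(subject_id, bayes_prior, null_prior, likelihood))
    return models_table(models)


def compute_evidence(
    trials: pd.DataFrame,
    models: pd.DataFrame,
    *,
    sigma_obs_convention: str = "n_minus_1",
    evidence_model_input: str = "posterior",
    sigma_floor: float = 0.5,
) -> pd.DataFrame:
    """Per-subject Bayes-factor comparison on the test-placebo ratings."""
    key = "post" if evidence_model_input == "posterior" else "prior"
    results = []
    for subject_id, sub in models.groupby("subject_id", sort=False):
        ratings = trials.loc[
            (trials["subject_id"] == subject_id)
            & (trials["phase"] == "test")
            & (trials["condition"] == "placebo"),
            "vas",
        ].to_numpy(dtype=float)
        row = {m: r for m, (_, r) in zip(sub["model"], sub.iterrows())}
        params = {
            m: GaussianParams(float(row[m][f"mu_{key}"]), float(row[m][f"sigma_{key}"]))
            for m in ("bayes", "null")
        }
        results.append(
            compare_models(
                ratings,
                params["bayes"],
                params["null"],
                subject_id=subject_id,
                sigma_obs_convention=sigma_obs_convention,
                sigma_floor=sigma_floor,
            )
        )
    return evidence_table(results)


def export_covariates(
    models: pd.DataFrame, evidence: pd.DataFrame, center: bool = False
) -> pd.DataFrame:
    """Per-subject covariate table: w_prior, mu_prior, log sigma_prior (natural
    log), and the posterior probability of the Bayesian model."""
    bayes = models.loc[models["model"] == "bayes", ["subject_id", "w_prior", "mu_prior", "sigma_prior"]]
    out = bayes.merge(evidence[["subject_id", "p_bayes"]], on="subject_id", how="outer", indicator=True)
    missing = out.loc[out["_merge"] != "both", "subject_id"].tolist()
    if missing:
        raise InputError(f"subjects missing from one input: {missing}")
    out = out.drop(columns="_merge")
    out["log_sigma_prior"] = np.log(out["sigma_prior"])
    out = out[["subject_id", "w_prior", "mu_prior", "log_sigma_prior", "p_bayes"]]
    if center:
        for col in out.columns[1:]:
            out[col] = out[col] - out[col].mean()
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s starting", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s finished in %.2fs", name, timings[name])

    stage("data")
    ground_truth = None
    if isinstance(config.cohort, CohortConfig):
        trials, ground_truth = simulate_cohort(config.cohort)
        cohort_desc = config.cohort.to_dict()
    else:
        trials = load_trials(config.cohort)
        cohort_desc = {"trials_csv": str(config.cohort)}
    done("data")

    stage("fit")
    fits = fit_all_subjects(trials, sigma_floor=config.sigma_floor)
    done("fit")
    stage("integrate")
    models = compute_models(fits)
    done("integrate")
    stage("evidence")
    evidence = compute_evidence(
        trials,
        models,
        sigma_obs_convention=config.sigma_obs_convention,
        evidence_model_input=config.evidence_model_input,
        sigma_floor=config.sigma_floor,
    )
    per = positive_evidence_ratio(evidence, threshold=config.per_threshold)
    done("evidence")

    stage("rfx")
    lme = evidence[["log_evidence_bayes", "log_evidence_null"]].to_numpy(dtype=float)
    rfx = rfx_model_selection(lme, prior_alpha=config.rfx_prior_alpha, seed=config.rfx_seed)
    done("rfx")

    stage("stats")
    summaries = apply_subsample_cutoffs(summarize_cohort(trials, models))
    regression = regress_placebo_on_sigmas(summaries, models)
    merged = summaries.merge(
        models.loc[models["model"] == "bayes", ["subject_id", "w_prior"]], on="subject_id"
    )
    r_pred, p_pred = pearson_correlation(
        merged["placebo_effect_predicted"], merged["placebo_effect_observed"]
    )
    r_w, p_w = pearson_correlation(merged["w_prior"], merged["placebo_effect_observed"])
    covariates = export_covariates(models, evidence, center=config.center_covariates)
    done("stats")

    # ---- outputs ------------------------------------------------------
    _write_csv(trials, out_dir / "trials.csv")
    files["trials"] = out_dir / "trials.csv"
    if ground_truth is not None:
        _write_csv(ground_truth, out_dir / "ground_truth.csv")
        files["ground_truth"] = out_dir / "ground_truth.csv"
    for name, df in (
        ("fits", fits),
        ("models", models),
        ("evidence", evidence),
        ("summaries", summaries),
    ):
        _write_csv(df, out_dir / f"{name}.csv")
        files[name] = out_dir / f"{name}.csv"
    _write_csv(trials[["subject_id", "group", "phase", "condition", "trial", "vas"]],
               out_dir / "tidy_long.csv")
    files["tidy_long"] = out_dir / "tidy_long.csv"
    covariates.to_csv(out_dir / "covariates.tsv", sep="\t", index=False, float_format="%.12g")
    files["covariates"] = out_dir / "covariates.tsv"
    (out_dir / "rfx.json").write_text(json.dumps(rfx.to_dict(), indent=2))
    files["rfx"] = out_dir / "rfx.json"
    (out_dir / "regression.json").write_text(json.dumps(regression.to_dict(), indent=2))
    files["regression"] = out_dir / "regression.json"

    results = {
        "n_subjects": int(evidence.shape[0]),
        "rfx_expected_prob": {"bayes": rfx.expected_prob[0], "null": rfx.expected_prob[1]},
        "rfx_exceedance_prob": {"bayes": rfx.exceedance_prob[0], "null": rfx.exceedance_prob[1]},
        "per": {
            "n_favoring_bayes": per.n_favoring_bayes,
            "n_favoring_null": per.n_favoring_null,
            "value": None if not per.defined else per.per,
        },
        "predicted_vs_observed_effect": {"r": r_pred, "p": p_pred},
        "w_prior_vs_observed_effect": {"r": r_w, "p": p_w},
        "regression": {
            "coefficients": regression.params,
            "r_squared": regression.r_squared,
            "f_statistic": regression.f_statistic,
        },
        "group_mean_observed_effect": summaries.groupby("group")["placebo_effect_observed"]
        .mean()
        .to_dict(),
    }
    report = _render_report(results)
    (out_dir / "report.txt").write_text(report)
    files["report"] = out_dir / "report.txt"

    manifest = {
        "package": "placebayes",
        "version": __version__,
        "config": {
            "cohort": cohort_desc,
            "sigma_floor": config.sigma_floor,
            "sigma_obs_convention": config.sigma_obs_convention,
            "evidence_model_input": config.evidence_model_input,
            "per_threshold": config.per_threshold,
            "rfx_prior_alpha": config.rfx_prior_alpha,
            "rfx_seed": config.rfx_seed,
            "center_covariates": config.center_covariates,
        },
        "results": results,
        "hashes": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    logger.info("pipeline complete: %d subjects, outputs in %s", results["n_subjects"], out_dir)
    return manifest


def _render_report(results: dict) -> str:
    per = results["per"]
    per_txt = (
        f"{per['value']:.2f}" if per["value"] is not None
        else f"undefined (counts {per['n_favoring_bayes']}/{per['n_favoring_null']})"
    )
    lines = [
        "placebayes run report",
        "=====================",
        f"subjects analysed: {results['n_subjects']}",
        "",
        "Random-effects model selection (Bayes vs Null):",
        f"  expected model probability (Bayes): {results['rfx_expected_prob']['bayes']:.3f}",
        f"  exceedance probability (Bayes):     {results['rfx_exceedance_prob']['bayes']:.4f}",
        f"  positive evidence ratio:            {per_txt} "
        f"({per['n_favoring_bayes']} vs {per['n_favoring_null']} decisive subjects)",
        "",
        "Behavior:",
        f"  predicted vs observed placebo effect: r = {results['predicted_vs_observed_effect']['r']:.3f}"
        f" (p = {results['predicted_vs_observed_effect']['p']:.2e})",
        f"  attraction weight vs observed effect: r = {results['w_prior_vs_observed_effect']['r']:.3f}"
        f" (p = {results['w_prior_vs_observed_effect']['p']:.2e})",
        "  placebo effect ~ {intercept:.3f} + {sigma_prior:.3f}*sigma_prior + "
        "{sigma_like:.3f}*sigma_like".format(**results["regression"]["coefficients"]),
        f"  regression R^2 = {results['regression']['r_squared']:.3f}",
        "",
        "Group mean observed placebo effects (VAS):",
    ]
    for group, eff in sorted(results["group_mean_observed_effect"].items()):
        lines.append(f"  {group}: {eff:.2f}")
    return "\n".join(lines) + "\n"
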