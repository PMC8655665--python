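"""End-to-end trial runner: simulate -> prognosis -> allocate -> outcomes ->
analyze -> economics, with a manifest tying outputs to the configuration
and seed.  All randomness flows from the single manifest seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allocation import adherence_stats, allocate_cohort
from .cohort import generate_cohort, simulate_pathway_and_outcomes
from .config import GAD7_BOUNDS, PHQ9_BOUNDS, TrialConfig, save_config
from .economics import ceac, cohort_costs
from .errors import ConfigError, StageError, StratCareError
from .io import write_patient_table
from .outcomes import build_outcome_panel
from .prognosis import (
    calibrate_threshold,
    classify_cohort,
    fit_prognosis,
    remission_training_labels,
    save_model,
    select_penalty,
)
from .stats import (
    adjusted_logistic_or,
    cluster_effect_check,
    em_impute_endpoints,
    mann_whitney_u,
    pearson_chi2,
)

log = logging.getLogger("stratcare")


def _spawn_seeds(seed: int, n: int):
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def trial_summary(completed: pd.DataFrame, decisions: pd.DataFrame, panel: pd.DataFrame,
                  thresholds) -> pd.DataFrame:
    """Arm-by-arm summary table mirroring the trial's outcomes table:
    pathway, sessions, dropout, adherence, and outcome rows with the
    between-arm test statistic for each."""
    df = completed.merge(panel.drop(columns=["dropout"], errors="ignore"),
                         on="patient_id", how="left")
    strat = df[df["arm"] == "stratified"]
    step = df[df["arm"] == "stepped"]
    rows = []

    def frac(sub, mask_col, denom_mask=None):
        sub2 = sub if denom_mask is None else sub[denom_mask(sub)]
        col = sub2[mask_col].dropna()
        return int(col.sum()), len(col)

    # Pathway: final LIT vs HIT
    a, n1 = (strat["allocated_intensity"] == "LIT").sum(), len(strat)
    c, n0 = (step["allocated_intensity"] == "LIT").sum(), len(step)
    chi2_path = pearson_chi2(a, n1 - a, c, n0 - c)
    rows.append(("pathway_LIT", a, n1, c, n0, "chi2", chi2_path))

    mw = mann_whitney_u(strat["sessions"], step["sessions"])
    rows.append(("sessions", float(strat["sessions"].mean()), len(strat),
                 float(step["sessions"].mean()), len(step), "mann_whitney_u", mw.u))

    a, n1 = frac(strat, "dropout")
    c, n0 = frac(step, "dropout")
    rows.append(("dropout", a, n1, c, n0, "chi2", pearson_chi2(a, n1 - a, c, n0 - c)))

    dec = decisions.merge(completed[["patient_id", "arm"]], on="patient_id")
    for arm in ("stratified", "stepped"):
        pct, kappa = adherence_stats(dec[dec["arm"] == arm])
        rows.append((f"adherence_{arm}", pct, len(dec[dec["arm"] == arm]),
                     np.nan, np.nan, "kappa", kappa))

    for outcome, covariate in (
        ("rcsi_phq9", "baseline_phq9"),
        ("rcsi_gad7", "baseline_gad7"),
        ("reliable_recovery", "baseline_phq9"),
    ):
        sub = df.dropna(subset=[outcome])
        if sub.empty or sub[outcome].nunique() < 2 or sub["arm"].nunique() < 2:
            continue
        res = adjusted_logistic_or(sub, outcome, "arm", covariate)
        a, n1 = frac(sub[sub["arm"] == "stratified"], outcome)
        c, n0 = frac(sub[sub["arm"] == "stepped"], outcome)
        rows.append((outcome, a, n1, c, n0, "adjusted_or",
                     f"{res.odds_ratio:.3f} ({res.ci_low:.3f}-{res.ci_high:.3f}) p={res.p:.3f}"))
        for level in ("standard", "complex"):
            subl = sub[sub["complexity_label"] == level]
            if subl.empty or subl[outcome].nunique() < 2 or subl["arm"].nunique() < 2:
                continue
            resl = adjusted_logistic_or(subl, outcome, "arm", covariate)
            a, n1 = frac(subl[subl["arm"] == "stratified"], outcome)
            c, n0 = frac(subl[subl["arm"] == "stepped"], outcome)
            rows.append((f"{outcome}_{level}", a, n1, c, n0, "adjusted_or",
                         f"{resl.odds_ratio:.3f} ({resl.ci_low:.3f}-{resl.ci_high:.3f}) p={resl.p:.3f}"))

    return pd.DataFrame(
        rows,
        columns=["row", "stratified_count", "stratified_n",
                 "stepped_count", "stepped_n", "statistic", "value"],
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_trial(config: TrialConfig, out_dir, seed: int | None = None) -> dict:
    """Execute the full pipeline, writing all outputs plus a manifest.

    Returns the manifest dict.  Any stage failure raises StageError naming
    the failing stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.validate()
    if config.cohort.n_patients == 0:
        raise ConfigError("empty cohort: n_patients is 0")
    seed = config.cohort.seed if seed is None else seed
    seeds = dict(zip(
        ["training", "cohort", "allocate", "outcomes", "bootstrap"],
        _spawn_seeds(seed, 5),
    ))
    stage = "simulate"
    try:
        log.info("simulate: generating training (n=%d) and trial cohorts (n=%d)",
                 config.n_training, config.cohort.n_patients)
        train_cfg = dataclasses.replace(config.cohort, n_patients=config.n_training)
        training = generate_cohort(train_cfg, seed=seeds["training"])
        training_dec = allocate_cohort(training, config.policy, seed=seeds["training"])
        training = simulate_pathway_and_outcomes(
            training, training_dec, train_cfg, config.policy, config.thresholds,
            seed=seeds["training"],
        )
        cohort = generate_cohort(config.cohort, seed=seeds["cohort"])

        stage = "fit_prognosis"
        labels = remission_training_labels(training, config.thresholds)
        penalty = (
            select_penalty(training, seed=seeds["training"], labels=labels)
            if config.cv_penalty
            else config.penalty_weight
        )
        log.info("fit_prognosis: penalty=%s on %d labelled patients", penalty, len(labels))
        model = fit_prognosis(training, penalty, seed=seeds["training"], labels=labels)
        calibrate_threshold(model, training, config.cohort.complex_prevalence)

        stage = "classify_prognosis"
        pred = classify_cohort(model, cohort)
        cohort["predicted_remission_prob"] = pred["predicted_remission_prob"]
        cohort["complexity_label"] = pred["complexity_label"]

        stage = "allocate"
        decisions = allocate_cohort(cohort, config.policy, seed=seeds["allocate"])

        stage = "simulate_outcomes"
        completed = simulate_pathway_and_outcomes(
            cohort, decisions, config.cohort, config.policy, config.thresholds,
            seed=seeds["outcomes"],
        )

        stage = "impute"
        bounds = {"post_phq9": PHQ9_BOUNDS, "post_gad7": GAD7_BOUNDS}
        em = em_impute_endpoints(completed, bounds=bounds)
        analyzed = em.table

        stage = "classify_outcomes"
        panel = build_outcome_panel(analyzed, config.thresholds)

        stage = "analyze"
        summary = trial_summary(analyzed, decisions, panel, config.thresholds)
        merged = analyzed.merge(panel.drop(columns=["dropout"], errors="ignore"),
                                on="patient_id")
        cluster = cluster_effect_check(merged.dropna(subset=["rcsi_phq9"]),
                                       "rcsi_phq9")

        stage = "economics"
        merged["cost"] = cohort_costs(merged, config.costs)
        econ = ceac(merged, config.costs, effect_col="reliable_improvement",
                    cost_col="cost", seed=seeds["bootstrap"])
    except StratCareError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    files = {
        "cohort": out_dir / "cohort.csv",
        "decisions": out_dir / "decisions.csv",
        "outcomes": out_dir / "outcomes.csv",
        "summary": out_dir / "summary.csv",
        "econ": out_dir / "econ.csv",
        "model": out_dir / "prognosis_model.txt",
        "config": out_dir / "config_used.yaml",
    }
    write_patient_table(completed, files["cohort"])
    decisions.to_csv(files["decisions"], index=False, lineterminator="\n")
    write_patient_table(merged, files["outcomes"])
    summary.to_csv(files["summary"], index=False, lineterminator="\n")
    econ.ceac_table().to_csv(files["econ"], index=False, lineterminator="\n")
    save_model(model, files["model"])
    save_config(config, files["config"])

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "stage_seeds": seeds,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "cluster_check": {"minus2_delta_ll": cluster.minus2_delta_ll,
                          "df": cluster.df, "p": cluster.p},
        "economics": {"incremental_cost": econ.incremental_cost,
                      "incremental_cost_ci": list(econ.incremental_cost_ci),
                      "incremental_effect": econ.incremental_effect,
                      "lambda_50": econ.lambda_50},
        "files": {name: {"path": str(path), "sha256": _digest(path)}
                  for name, path in files.items()},
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
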