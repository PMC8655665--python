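"""Treatment-selection policies and adherence metrics.

Both arms' intake decisions are modelled.  The stratified engine matches
standard cases with low-intensity treatment and fast-tracks two groups to
high intensity: patients with disorders treated only by psychotherapy and
patients labelled complex.  The stepped engine allocates most patients to
low intensity, referring fast-track disorders and severely impaired
patients directly to high intensity.  Shared decision-making is modelled
as an independent Bernoulli override of the recommendation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DIAGNOSES, PolicyConfig
from .errors import ConfigError, DegenerateMarginalsError
from .cohort import as_rng


@dataclass
class AllocationDecision:
    patient_id: int
    recommended: str
    actual: str
    fast_track: bool
    reason: str
    adherent: bool


def _check_diagnosis(diagnosis):
    if diagnosis not in DIAGNOSES:
        raise ConfigError(f"unknown diagnosis category {diagnosis!r}")


def stratified_recommendation(patient, prognosis_label, policy: PolicyConfig):
    """Deterministic model recommendation: (intensity, fast_track, reason)."""
    diagnosis = patient["diagnosis"]
    _check_diagnosis(diagnosis)
    if diagnosis in policy.fast_track_diagnoses:
        return "HIT", True, "fast_track_disorder"
    if prognosis_label == "complex":
        return "HIT", False, "complex_case"
    return "LIT", False, "standard_case"


def stratified_policy(
    patient, prognosis_label, override_prob: float = 0.10, seed=None,
    policy: PolicyConfig | None = None,
) -> AllocationDecision:
    """Stratified-arm decision: model recommendation plus clinician override."""
    policy = policy or PolicyConfig(override_prob=override_prob)
    rng = as_rng(seed)
    recommended, fast_track, reason = stratified_recommendation(
        patient, prognosis_label, policy
    )
    actual = recommended
    if rng.random() < policy.override_prob:
        actual = "LIT" if recommended == "HIT" else "HIT"
        reason = "clinician_override"
    return AllocationDecision(
        patient_id=int(patient["patient_id"]),
        recommended=recommended,
        actual=actual,
        fast_track=fast_track,
        reason=reason,
        adherent=recommended == actual,
    )


def stepped_policy(
    patient, policy: PolicyConfig | None = None, seed=None
) -> AllocationDecision:
    """Stepped-arm intake decision (step-up happens later in the pathway).

    ``recommended`` records what the stratified model would have advised,
    which is what the trial's adherence comparison is measured against; for
    that reason the patient mapping must carry a ``complexity_label``.
    """
    policy = policy or PolicyConfig()
    recommended, fast_track, _ = stratified_recommendation(
        patient, patient.get("complexity_label", "standard"), policy
    )
    diagnosis = patient["diagnosis"]
    if diagnosis in policy.fast_track_diagnoses:
        actual, reason = "HIT", "fast_track_disorder"
    elif policy.severe_rule_enabled and (
        patient["wsas"] >= policy.severe_wsas_cutoff
        or patient["baseline_phq9"] >= policy.severe_phq9_cutoff
    ):
        actual, reason = "HIT", "severe_impairment"
    else:
        actual, reason = "LIT", "standard_case"
    return AllocationDecision(
        patient_id=int(patient["patient_id"]),
        recommended=recommended,
        actual=actual,
        fast_track=fast_track,
        reason=reason,
        adherent=recommended == actual,
    )


def allocate_cohort(
    cohort: pd.DataFrame, policy: PolicyConfig | None = None, seed=None
) -> pd.DataFrame:
    """Intake decisions for a whole cohort, by each patient's arm.

    ``recommended`` is always the stratified-model recommendation (using the
    cohort's ``complexity_label``), so adherence can be compared across arms
    as in the trial.
    """
    policy = policy or PolicyConfig()
    policy.validate()
    rng = as_rng(seed)
    n = len(cohort)
    diagnosis = cohort["diagnosis"].to_numpy()
    for d in pd.unique(diagnosis):
        _check_diagnosis(d)
    complexity = cohort["complexity_label"].to_numpy()
    arm = cohort["arm"].to_numpy()

    fast = np.isin(diagnosis, list(policy.fast_track_diagnoses))
    recommended = np.where(fast | (complexity == "complex"), "HIT", "LIT")
    rec_reason = np.where(
        fast,
        "fast_track_disorder",
        np.where(complexity == "complex", "complex_case", "standard_case"),
    )

    stratified = arm == "stratified"
    override = stratified & (rng.random(n) < policy.override_prob)
    strat_actual = np.where(
        override, np.where(recommended == "HIT", "LIT", "HIT"), recommended
    )

    severe = policy.severe_rule_enabled & (
        (cohort["wsas"].to_numpy() >= policy.severe_wsas_cutoff)
        | (cohort["baseline_phq9"].to_numpy() >= policy.severe_phq9_cutoff)
    )
    stepped_actual = np.where(fast | severe, "HIT", "LIT")
    stepped_reason = np.where(
        fast,
        "fast_track_disorder",
        np.where(severe, "severe_impairment", "standard_case"),
    )

    actual = np.where(stratified, strat_actual, stepped_actual)
    reason = np.where(
        stratified, np.where(override, "clinician_override", rec_reason), stepped_reason
    )
    return pd.DataFrame(
        {
            "patient_id": cohort["patient_id"].to_numpy(),
            "recommended": recommended,
            "actual": actual,
            "fast_track": fast.astype(int),
            "reason": reason,
            "adherent": (recommended == actual).astype(int),
        }
    )


def cohen_kappa(recommended, actual) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), p_e from marginal products."""
    recommended = np.asarray(recommended)
    actual = np.asarray(actual)
    if recommended.shape != actual.shape or recommended.size < 2:
        raise ValueError("need >= 2 paired decisions")
    categories = np.union1d(recommended, actual)
    n = recommended.size
    p_o = float(np.mean(recommended == actual))
    p_e = 0.0
    for cat in categories:
        p_e += np.mean(recommended == cat) * np.mean(actual == cat)
    if p_e >= 1.0 - 1e-15:
        raise DegenerateMarginalsError(
            "expected agreement is 1 (degenerate marginals); kappa undefined"
        )
    return (p_o - p_e) / (1.0 - p_e)


def adherence_stats(decisions: pd.DataFrame) -> tuple:
    """(percent agreement, Cohen's kappa) for recommended vs actual intensity."""
    if len(decisions) < 2:
        raise ValueError("need >= 2 decisions")
    rec = decisions["recommended"].to_numpy()
    act = decisions["actual"].to_numpy()
    percent = float(np.mean(rec == act) * 100.0)
    kappa = cohen_kappa(rec, act)
    return percent, kappa
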