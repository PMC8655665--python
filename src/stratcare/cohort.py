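"""Synthetic two-arm cohort generator with clinician-cluster structure.

The generator emulates a cluster-randomized trial of stratified vs stepped
psychological care: clinicians are block-randomized 1:1, patients inherit
their assessing clinician's arm, baseline instrument scores are correlated
truncated-normal integer draws, a latent prognosis (logistic in a weighted
severity index) defines complex vs standard cases, and binary remission is
drawn per (arm, complexity) subgroup with posttreatment scores sampled
consistently with the remission indicator, so the outcome classifier
reproduces the latent labels exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (
    CohortConfig,
    GAD7_BOUNDS,
    OutcomeThresholds,
    PHQ9_BOUNDS,
    PolicyConfig,
    SAPAS_BOUNDS,
    WSAS_BOUNDS,
)
from .errors import ConfigError, InvalidDesignError

BASELINE_COLUMNS = [
    "patient_id",
    "clinician_id",
    "arm",
    "age",
    "sex",
    "ethnicity_group",
    "unemployed",
    "diagnosis",
    "baseline_phq9",
    "baseline_gad7",
    "wsas",
    "sapas",
    "latent_prognosis",
    "complexity_label",
]


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, Generator, or None into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def randomize_clinicians(
    n_clinicians: int,
    block_size: int = 4,
    seed=None,
    allow_partial_final_block: bool = True,
) -> dict:
    """Blocked 1:1 randomization of clinicians to trial arms.

    Within each complete block exactly half the clinicians go to each arm.
    A partial final block is balanced as evenly as possible (an odd leftover
    clinician is assigned at random).
    """
    if n_clinicians < 2:
        raise InvalidDesignError("need at least 2 clinicians to randomize")
    if block_size < 2 or block_size % 2:
        raise InvalidDesignError("block_size must be an even integer >= 2")
    if n_clinicians % block_size and not allow_partial_final_block:
        raise InvalidDesignError(
            f"{n_clinicians} clinicians do not fill blocks of {block_size}"
        )
    rng = as_rng(seed)
    assignment = {}
    cid = 1
    remaining = n_clinicians
    while remaining > 0:
        size = min(block_size, remaining)
        half = size // 2
        arms = ["stratified"] * half + ["stepped"] * half
        if size % 2:
            arms.append(rng.choice(["stratified", "stepped"]))
        arms = list(rng.permutation(arms))
        for arm in arms:
            assignment[cid] = arm
            cid += 1
        remaining -= size
    return assignment


def _truncated_integer_normal(rng, n, mean, sd, lo, hi, shared=None, corr=0.0):
    """Integer scores: normal draw, redrawn until the rounded value is in bounds.

    ``shared`` is an optional N(0,1) latent factor inducing pairwise
    correlation ``corr`` between instruments; only the idiosyncratic part is
    redrawn on rejection so the factor loading is preserved.
    """
    if sd == 0:
        value = int(np.clip(np.rint(mean), lo, hi))
        return np.full(n, value, dtype=int)
    out = np.empty(n)
    pending = np.ones(n, dtype=bool)
    a = np.sqrt(corr) if shared is not None else 0.0
    b = np.sqrt(1.0 - corr) if shared is not None else 1.0
    while pending.any():
        m = int(pending.sum())
        eps = rng.standard_normal(m)
        if shared is not None:
            v = mean + sd * (a * shared[pending] + b * eps)
        else:
            v = mean + sd * eps
        r = np.rint(v)
        ok = (r >= lo) & (r <= hi)
        idx = np.flatnonzero(pending)[ok]
        out[idx] = r[ok]
        pending[idx] = False
    return out.astype(int)


def generate_cohort(config: CohortConfig, seed=None) -> pd.DataFrame:
    """Draw a baseline cohort (no pathway or outcome fields yet).

    The latent prognosis is a logistic function of a severity index built
    from standardized PHQ-9, WSAS, SAPAS and unemployment; the lowest
    ``complex_prevalence`` quantile of the cohort is labelled complex, so
    the flagged share matches the configured prevalence exactly.
    """
    config.validate()
    rng = as_rng(config.seed if seed is None else seed)
    n = config.n_patients

    arms_by_clinician = randomize_clinicians(
        config.n_clinicians, config.block_size, seed=rng
    )
    clinician_id = rng.integers(1, config.n_clinicians + 1, size=n)
    arm = np.array([arms_by_clinician[c] for c in clinician_id])

    severity_factor = rng.standard_normal(n)
    rho = config.score_correlation
    phq9 = _truncated_integer_normal(
        rng, n, config.phq9_mean, config.phq9_sd, *PHQ9_BOUNDS, severity_factor, rho
    )
    gad7 = _truncated_integer_normal(
        rng, n, config.gad7_mean, config.gad7_sd, *GAD7_BOUNDS, severity_factor, rho
    )
    wsas = _truncated_integer_normal(
        rng, n, config.wsas_mean, config.wsas_sd, *WSAS_BOUNDS, severity_factor, rho
    )
    sapas = _truncated_integer_normal(
        rng, n, config.sapas_mean, config.sapas_sd, *SAPAS_BOUNDS
    )
    age = np.clip(
        np.rint(config.age_mean + config.age_sd * rng.standard_normal(n)), 16, 95
    ).astype(int)

    sex = np.where(rng.random(n) < config.prop_female, "female", "male")
    unemployed = (rng.random(n) < config.prop_unemployed).astype(int)
    ethnicity = np.where(rng.random(n) < config.prop_white, "White", "other")
    diagnoses = list(config.diagnosis_probs)
    diag_p = np.array([config.diagnosis_probs[d] for d in diagnoses])
    diagnosis = rng.choice(diagnoses, size=n, p=diag_p / diag_p.sum())

    def z(x, mean, sd):
        return (x - mean) / sd if sd > 0 else np.zeros(n)

    severity = (
        config.severity_weight_phq9 * z(phq9, config.phq9_mean, config.phq9_sd)
        + config.severity_weight_wsas * z(wsas, config.wsas_mean, config.wsas_sd)
        + config.severity_weight_sapas * z(sapas, config.sapas_mean, config.sapas_sd)
        + config.severity_weight_unemployed * unemployed
    )
    latent_prognosis = expit(-config.prognosis_slope * severity)

    complexity = np.full(n, "standard", dtype=object)
    k = int(round(config.complex_prevalence * n))
    if k > 0:
        worst = np.argsort(latent_prognosis, kind="stable")[:k]
        complexity[worst] = "complex"

    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "clinician_id": clinician_id,
            "arm": arm,
            "age": age,
            "sex": sex,
            "ethnicity_group": ethnicity,
            "unemployed": unemployed,
            "diagnosis": diagnosis,
            "baseline_phq9": phq9,
            "baseline_gad7": gad7,
            "wsas": wsas,
            "sapas": sapas,
            "latent_prognosis": latent_prognosis,
            "complexity_label": complexity,
        }
    )


def _conditional_post_scores(rng, baseline, remit, case, lo, hi, cutoff, change, loc_shift, sd):
    """Posttreatment integer scores consistent with the binary remission draw.

    Equivalent to rejection sampling from the baseline-conditioned truncated
    normal: the integer pmf is restricted to the set compatible with the
    remission indicator (remitters: post < cutoff AND baseline - post >= change;
    non-remitters: the complement) and sampled directly.
    """
    n = len(baseline)
    grid = np.arange(lo, hi + 1)
    loc = (baseline - loc_shift)[:, None]
    scale = sd if sd > 0 else 1e-9
    logw = -0.5 * ((grid[None, :] - loc) / scale) ** 2
    w = np.exp(logw - logw.max(axis=1, keepdims=True))

    meets = (grid[None, :] < cutoff) & ((baseline[:, None] - grid[None, :]) >= change)
    allowed = np.ones((n, grid.size), dtype=bool)
    is_case = case.astype(bool)
    rem = np.where(np.isnan(remit), 0, remit).astype(bool)
    allowed[is_case & rem] = meets[is_case & rem]
    allowed[is_case & ~rem] = ~meets[is_case & ~rem]

    w = np.where(allowed, w, 0.0)
    totals = w.sum(axis=1)
    dead = totals == 0
    if dead.any():  # numerical underflow: fall back to uniform on the allowed set
        w[dead] = allowed[dead].astype(float)
        totals = w.sum(axis=1)
    cum = np.cumsum(w, axis=1) / totals[:, None]
    u = rng.random(n)
    idx = (cum < u[:, None]).sum(axis=1)
    return grid[np.clip(idx, 0, grid.size - 1)]


def _session_counts(rng, n, mean, sd, cap):
    if n == 0:
        return np.zeros(0, dtype=int)
    return _truncated_integer_normal(rng, n, mean, sd, 1, cap)


def simulate_pathway_and_outcomes(
    cohort: pd.DataFrame,
    decisions: pd.DataFrame,
    config: CohortConfig,
    policy: PolicyConfig | None = None,
    thresholds: OutcomeThresholds | None = None,
    seed=None,
) -> pd.DataFrame:
    """Complete a baseline cohort with pathway and endpoint fields.

    Remission is Bernoulli per (arm, complexity-label) among baseline cases;
    sub-threshold patients are flagged (latent label missing) and handled by
    the analysis-stage exclusion.  Low-intensity non-remitters step up to
    high intensity with an arm-specific probability; dropout and endpoint
    missingness are drawn independently of arm.
    """
    policy = policy or PolicyConfig()
    thresholds = thresholds or OutcomeThresholds()
    rng = as_rng(seed)

    df = cohort.merge(
        decisions[["patient_id", "recommended", "actual", "fast_track", "reason", "adherent"]],
        on="patient_id",
        how="left",
        validate="one_to_one",
    )
    if df["actual"].isna().any():
        missing = df.loc[df["actual"].isna(), "patient_id"].tolist()[:5]
        raise ConfigError(f"patients without an allocation decision, e.g. {missing}")
    n = len(df)
    arm = df["arm"].to_numpy()
    complexity = df["complexity_label"].to_numpy()

    def subgroup_p(table):
        return np.array([table[a][c] for a, c in zip(arm, complexity)])

    p_phq = subgroup_p(config.subgroup_rcsi_probs)
    p_gad = subgroup_p(config.gad7_rcsi_probs)
    if config.cluster_sd > 0:
        intercepts = {
            c: config.cluster_sd * rng.standard_normal()
            for c in sorted(df["clinician_id"].unique())
        }
        u = np.array([intercepts[c] for c in df["clinician_id"]])
        p_phq = expit(np.log(p_phq / (1 - p_phq)) + u)
        p_gad = expit(np.log(p_gad / (1 - p_gad)) + u)

    phq_case = df["baseline_phq9"].to_numpy() >= thresholds.phq9_cutoff
    gad_case = df["baseline_gad7"].to_numpy() >= thresholds.gad7_cutoff

    latent_phq = np.full(n, np.nan)
    latent_phq[phq_case] = (rng.random(int(phq_case.sum())) < p_phq[phq_case]).astype(float)
    latent_gad = np.full(n, np.nan)
    latent_gad[gad_case] = (rng.random(int(gad_case.sum())) < p_gad[gad_case]).astype(float)

    post_phq9 = _conditional_post_scores(
        rng,
        df["baseline_phq9"].to_numpy().astype(float),
        latent_phq,
        phq_case,
        *PHQ9_BOUNDS,
        thresholds.phq9_cutoff,
        thresholds.phq9_reliable_change,
        config.post_improvement_mean,
        config.post_sd,
    )
    post_gad7 = _conditional_post_scores(
        rng,
        df["baseline_gad7"].to_numpy().astype(float),
        latent_gad,
        gad_case,
        *GAD7_BOUNDS,
        thresholds.gad7_cutoff,
        thresholds.gad7_reliable_change,
        config.post_improvement_mean,
        config.post_sd,
    )

    initial = df["actual"].to_numpy()
    stepup_p = np.where(
        arm == "stratified", policy.stepup_prob_stratified, policy.stepup_prob_stepped
    )
    eligible = (initial == "LIT") & phq_case & (latent_phq == 0)
    stepped_up = eligible & (rng.random(n) < stepup_p)
    final = np.where(stepped_up, "HIT", initial)

    sessions_lit = np.zeros(n, dtype=int)
    sessions_hit = np.zeros(n, dtype=int)
    lit_mask = (final == "LIT") | stepped_up
    hit_mask = final == "HIT"
    sessions_lit[lit_mask] = _session_counts(
        rng, int(lit_mask.sum()), config.session_mean_lit, config.session_sd_lit,
        config.session_max_lit,
    )
    sessions_hit[hit_mask] = _session_counts(
        rng, int(hit_mask.sum()), config.session_mean_hit, config.session_sd_hit,
        config.session_max_hit,
    )

    dropout = (rng.random(n) < config.dropout_prob).astype(int)
    missing = rng.random(n) < config.endpoint_missing_prob

    out = df.copy()
    out["initial_intensity"] = initial
    out["stepped_up"] = stepped_up.astype(int)
    out["allocated_intensity"] = final
    out["sessions_lit"] = sessions_lit
    out["sessions_hit"] = sessions_hit
    out["sessions"] = sessions_lit + sessions_hit
    out["dropout"] = dropout
    out["post_phq9"] = np.where(missing, np.nan, post_phq9.astype(float))
    out["post_gad7"] = np.where(missing, np.nan, post_gad7.astype(float))
    out["latent_rcsi_phq9"] = latent_phq
    out["latent_rcsi_gad7"] = latent_gad
    return out


def simulate_case_outcomes(
    arm: str,
    n_standard: int,
    n_complex: int,
    config: CohortConfig | None = None,
    thresholds: OutcomeThresholds | None = None,
    seed=None,
) -> pd.DataFrame:
    """Simulate endpoint scores for a fixed-size sample of baseline cases.

    Baseline PHQ-9 scores are drawn from the truncated-normal score model
    conditional on caseness; remission is Bernoulli per subgroup and the
    posttreatment score is drawn consistently with it.
    """
    config = config or CohortConfig()
    thresholds = thresholds or OutcomeThresholds()
    rng = as_rng(seed)
    n = n_standard + n_complex
    complexity = np.array(["standard"] * n_standard + ["complex"] * n_complex)
    baseline = _truncated_integer_normal(
        rng, n, config.phq9_mean, config.phq9_sd, thresholds.phq9_cutoff, PHQ9_BOUNDS[1]
    ).astype(float)
    p = np.array([config.subgroup_rcsi_probs[arm][c] for c in complexity])
    remit = (rng.random(n) < p).astype(float)
    post = _conditional_post_scores(
        rng,
        baseline,
        remit,
        np.ones(n, dtype=bool),
        *PHQ9_BOUNDS,
        thresholds.phq9_cutoff,
        thresholds.phq9_reliable_change,
        config.post_improvement_mean,
        config.post_sd,
    )
    return pd.DataFrame(
        {
            "arm": arm,
            "complexity_label": complexity,
            "baseline_phq9": baseline.astype(int),
            "post_phq9": post.astype(float),
            "latent_rcsi_phq9": remit,
        }
    )
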