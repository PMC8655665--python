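"""Configuration objects for the trial simulator and analysis pipeline.

Defaults reproduce the printed calibration of a cluster-randomized trial of
stratified vs stepped psychological care in IAPT services (n=951 patients,
30 assessing clinicians): baseline instrument distributions, the complexity
prevalence, subgroup remission probabilities, dropout and endpoint
missingness.  All values are plain attributes so a YAML file can override
any of them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError

# Instrument score bounds (inclusive).
PHQ9_BOUNDS = (0, 27)
GAD7_BOUNDS = (0, 21)
WSAS_BOUNDS = (0, 40)
SAPAS_BOUNDS = (0, 8)

ARMS = ("stratified", "stepped")
COMPLEXITY_LEVELS = ("standard", "complex")
DIAGNOSES = ("affective", "anxiety", "PTSD", "OCD")
INTENSITIES = ("LIT", "HIT")


def _default_diagnosis_probs() -> dict:
    # Exact count fractions so the mixture sums to 1 to machine precision.
    return {
        "affective": 483 / 916,
        "anxiety": 392 / 916,
        "PTSD": 27 / 916,
        "OCD": 14 / 916,
    }


def _default_rcsi_probs() -> dict:
    # Depression (PHQ-9) RCSI probability by (arm, complexity) among baseline cases.
    return {
        "stratified": {"standard": 0.583, "complex": 0.394},
        "stepped": {"standard": 0.483, "complex": 0.338},
    }


def _default_gad7_rcsi_probs() -> dict:
    # Anxiety (GAD-7) RCSI probability by (arm, complexity) among GAD-7 cases.
    return {
        "stratified": {"standard": 0.566, "complex": 0.325},
        "stepped": {"standard": 0.496, "complex": 0.323},
    }


@dataclass
class CohortConfig:
    """Generative model of a two-arm cohort with clinician clusters."""

    n_patients: int = 951
    n_clinicians: int = 30
    block_size: int = 4

    # Baseline instrument marginals: truncated normal, rounded to integers.
    phq9_mean: float = 15.47
    phq9_sd: float = 5.86
    gad7_mean: float = 14.21
    gad7_sd: float = 4.65
    wsas_mean: float = 20.33
    wsas_sd: float = 9.31
    sapas_mean: float = 3.97
    sapas_sd: float = 1.43
    age_mean: float = 38.27
    age_sd: float = 14.53

    prop_female: float = 0.651
    prop_unemployed: float = 0.197
    prop_white: float = 0.953
    diagnosis_probs: dict = field(default_factory=_default_diagnosis_probs)

    # Pairwise correlation among PHQ-9/GAD-7/WSAS via a shared severity factor.
    score_correlation: float = 0.5

    # Latent prognosis: logistic in a weighted severity index (z-scored inputs).
    complex_prevalence: float = 0.237
    severity_weight_phq9: float = 1.6
    severity_weight_wsas: float = 0.6
    severity_weight_sapas: float = 0.4
    severity_weight_unemployed: float = 0.4
    prognosis_slope: float = 1.0

    subgroup_rcsi_probs: dict = field(default_factory=_default_rcsi_probs)
    gad7_rcsi_probs: dict = field(default_factory=_default_gad7_rcsi_probs)

    # Optional clinician random intercept (SD on the remission log-odds scale).
    cluster_sd: float = 0.0

    dropout_prob: float = 0.30
    endpoint_missing_prob: float = 38 / 951

    # Session counts: truncated normal rounded, floor 1, instrument-specific cap.
    session_mean_lit: float = 5.0
    session_sd_lit: float = 2.5
    session_max_lit: int = 8
    session_mean_hit: float = 9.0
    session_sd_hit: float = 5.0
    session_max_hit: int = 20

    # Posttreatment score model: centred baseline-minus-improvement, integer draw.
    post_improvement_mean: float = 6.5
    post_sd: float = 5.0

    seed: int = 0

    def validate(self) -> None:
        probs = {
            "prop_female": self.prop_female,
            "prop_unemployed": self.prop_unemployed,
            "prop_white": self.prop_white,
            "complex_prevalence": self.complex_prevalence,
            "dropout_prob": self.dropout_prob,
            "endpoint_missing_prob": self.endpoint_missing_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        total = sum(self.diagnosis_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"diagnosis probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.diagnosis_probs.values()):
            raise ConfigError("negative diagnosis probability")
        for arm_table in (self.subgroup_rcsi_probs, self.gad7_rcsi_probs):
            for arm in ARMS:
                for level in COMPLEXITY_LEVELS:
                    p = arm_table[arm][level]
                    if not 0.0 <= p <= 1.0:
                        raise ConfigError(f"remission probability {p} outside [0, 1]")
        bounds = {
            "phq9": (self.phq9_mean, PHQ9_BOUNDS),
            "gad7": (self.gad7_mean, GAD7_BOUNDS),
            "wsas": (self.wsas_mean, WSAS_BOUNDS),
            "sapas": (self.sapas_mean, SAPAS_BOUNDS),
        }
        for name, (mean, (lo, hi)) in bounds.items():
            if not lo <= mean <= hi:
                raise ConfigError(f"{name} mean {mean} outside instrument bounds [{lo}, {hi}]")
        for name in ("phq9_sd", "gad7_sd", "wsas_sd", "sapas_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} negative")
        if self.n_patients < 0:
            raise ConfigError("n_patients negative")
        if not 0.0 <= self.score_correlation < 1.0:
            raise ConfigError("score_correlation must be in [0, 1)")


@dataclass
class PolicyConfig:
    """Treatment-selection rules for the two arms."""

    # Disorders routed straight to high-intensity psychotherapy in both arms.
    fast_track_diagnoses: tuple = ("PTSD", "OCD")
    # Probability that shared decision-making overrides the model recommendation.
    override_prob: float = 0.10
    # Probability that a low-intensity non-remitter steps up to high intensity.
    stepup_prob_stratified: float = 0.34
    stepup_prob_stepped: float = 0.18
    # Stepped-care severe-impairment fast-track rule (WSAS >= w OR PHQ-9 >= p).
    severe_wsas_cutoff: float = 32.0
    severe_phq9_cutoff: float = 23.0
    severe_rule_enabled: bool = True

    def validate(self) -> None:
        for diag in self.fast_track_diagnoses:
            if diag not in DIAGNOSES:
                raise ConfigError(f"unknown fast-track diagnosis {diag!r}")
        for name in ("override_prob", "stepup_prob_stratified", "stepup_prob_stepped"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")


@dataclass
class OutcomeThresholds:
    """Caseness cutoffs and reliable-change magnitudes for the two instruments."""

    phq9_cutoff: int = 10
    phq9_reliable_change: int = 6
    gad7_cutoff: int = 8
    gad7_reliable_change: int = 4


@dataclass
class CostConfig:
    """Unit costs (health-services perspective) and CEAC bootstrap settings."""

    unit_cost_lit_session: float = 24.0  # per 30-min guided self-help session
    unit_cost_hit_session: float = 48.0  # per 60-min psychotherapy session
    assessment_cost: float = 40.0
    currency_label: str = "GBP"
    wtp_grid: tuple = tuple(float(x) for x in range(0, 4001, 100))
    bootstrap_reps: int = 5000
    seed: int = 0

    def validate(self) -> None:
        for name in ("unit_cost_lit_session", "unit_cost_hit_session", "assessment_cost"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} negative")
        grid = tuple(self.wtp_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigError("wtp_grid must be strictly increasing")
        if self.bootstrap_reps < 1:
            raise ConfigError("bootstrap_reps must be positive")


@dataclass
class TrialConfig:
    """End-to-end pipeline configuration."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    policy: PolicyConfig = field(default_factory=PolicyConfig)
    thresholds: OutcomeThresholds = field(default_factory=OutcomeThresholds)
    costs: CostConfig = field(default_factory=CostConfig)
    # Prognosis training settings.
    n_training: int = 5000
    penalty_weight: float = 1.0
    cv_penalty: bool = False

    def validate(self) -> None:
        self.cohort.validate()
        self.policy.validate()
        self.costs.validate()
        if self.n_training < 10:
            raise ConfigError("n_training too small to fit a prognosis model")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _from_mapping(cls, mapping):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in mapping:
            continue
        value = mapping[f.name]
        if dataclasses.is_dataclass(f.default_factory() if f.default_factory is not dataclasses.MISSING else None):  # pragma: no cover
            value = _from_mapping(type(f.default_factory()), value)
        kwargs[f.name] = value
    unknown = set(mapping) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**kwargs)


def trial_config_from_dict(mapping: dict) -> TrialConfig:
    mapping = dict(mapping)
    sub = {
        "cohort": CohortConfig,
        "policy": PolicyConfig,
        "thresholds": OutcomeThresholds,
        "costs": CostConfig,
    }
    kwargs = {}
    for key, cls in sub.items():
        if key in mapping:
            obj = _from_mapping(cls, mapping.pop(key))
            if key == "policy":
                obj.fast_track_diagnoses = tuple(obj.fast_track_diagnoses)
            if key == "costs":
                obj.wtp_grid = tuple(obj.wtp_grid)
            kwargs[key] = obj
    for f in dataclasses.fields(TrialConfig):
        if f.name in mapping:
            kwargs[f.name] = mapping.pop(f.name)
    if mapping:
        raise ConfigError(f"unknown TrialConfig keys: {sorted(mapping)}")
    cfg = TrialConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path) -> TrialConfig:
    """Read a TrialConfig from a YAML file; missing keys keep their defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return trial_config_from_dict(mapping)


def save_config(config: TrialConfig, path) -> None:
    """Write the exact configuration used, as a YAML sidecar."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)
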