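"""Prognostic classifier: baseline features -> remission probability -> label.

A penalized (L1) logistic regression on the intake measures stands in for
the trial's treatment-selection algorithm.  Features follow the stated
inputs of that algorithm: depression (PHQ-9), anxiety (GAD-7), functional
impairment (WSAS), personality traits (SAPAS), employment status, and
ethnicity group.  A patient is labelled *complex* (poorer expected
prognosis) when the predicted remission probability falls strictly below
the complexity threshold; the boundary belongs to *standard*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import KFold

from .config import OutcomeThresholds
from .errors import FitError, MissingFeatureError
from .outcomes import build_outcome_panel

FEATURE_NAMES = (
    "baseline_phq9",
    "baseline_gad7",
    "wsas",
    "sapas",
    "unemployed",
    "ethnicity_group",
)


@dataclass
class PrognosisModel:
    feature_names: tuple = FEATURE_NAMES
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros(len(FEATURE_NAMES)))
    intercept: float = 0.0
    penalty_weight: float = 0.0
    complexity_threshold: float = 0.5

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ np.asarray(self.coefficients)


def _encode(df: pd.DataFrame, feature_names) -> np.ndarray:
    cols = []
    for name in feature_names:
        if name not in df.columns:
            raise MissingFeatureError(f"feature column {name!r} absent")
        col = df[name]
        if name == "ethnicity_group":
            col = (col == "other").astype(float)  # White = 0, other = 1
        col = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
        if np.isnan(col).any():
            raise MissingFeatureError(f"missing values in feature {name!r}")
        cols.append(col)
    return np.column_stack(cols)


def remission_training_labels(
    df: pd.DataFrame,
    thresholds: OutcomeThresholds | None = None,
    joint: bool = True,
) -> pd.Series:
    """Binary training labels from observed endpoints.

    With ``joint=True`` (default) the label is full remission of depression
    and anxiety symptoms (reliable recovery); otherwise depression RCSI
    alone.  Rows where the label is undefined (sub-threshold at baseline or
    missing endpoint) are dropped.
    """
    panel = build_outcome_panel(df, thresholds)
    col = panel["reliable_recovery"] if joint else panel["rcsi_phq9"]
    labels = pd.Series(col.to_numpy(), index=df.index, name="remission_label")
    return labels.dropna().astype(int)


def fit_prognosis(
    training_cohort: pd.DataFrame,
    penalty_weight: float = 1.0,
    seed: int = 0,
    labels: pd.Series | None = None,
    feature_names=FEATURE_NAMES,
) -> PrognosisModel:
    """Fit the L1-penalized logistic prognosis model.

    ``penalty_weight`` is the L1 strength on standardized features; 0 gives
    the unpenalized maximum-likelihood fit.  The fit is deterministic given
    the data and seed.
    """
    if labels is None:
        labels = remission_training_labels(training_cohort)
    df = training_cohort.loc[labels.index]
    y = labels.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise FitError("degenerate outcome column: only one class present")
    X = _encode(df, feature_names)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    if penalty_weight < 0:
        raise FitError("penalty_weight must be nonnegative")
    if penalty_weight == 0:
        clf = LogisticRegression(
            C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-12
        )
    else:
        clf = LogisticRegression(
            C=1.0 / penalty_weight,
            l1_ratio=1.0,
            solver="saga",
            max_iter=20000,
            tol=1e-8,
            random_state=seed,
        )
    clf.fit(Z, y)
    if not np.all(np.isfinite(clf.coef_)):
        raise FitError("non-finite coefficients: possible separation")
    beta_std = clf.coef_.ravel()
    if penalty_weight > 0 and not beta_std.any():
        # All coefficients shrunk to zero: the ML intercept is the logit of
        # the base rate (saga undershoots it at extreme penalties).
        intercept = float(np.log(y.mean() / (1.0 - y.mean())))
        return PrognosisModel(
            feature_names=tuple(feature_names),
            coefficients=np.zeros(len(feature_names)),
            intercept=intercept,
            penalty_weight=penalty_weight,
        )
    coefficients = beta_std / sd
    intercept = float(clf.intercept_[0] - np.sum(beta_std * mu / sd))
    return PrognosisModel(
        feature_names=tuple(feature_names),
        coefficients=coefficients,
        intercept=intercept,
        penalty_weight=penalty_weight,
    )


def select_penalty(
    training_cohort: pd.DataFrame,
    grid=(0.01, 0.1, 1.0, 10.0, 100.0),
    n_folds: int = 5,
    seed: int = 0,
    labels: pd.Series | None = None,
) -> float:
    """K-fold cross-validated log-loss over a penalty grid (seeded)."""
    if labels is None:
        labels = remission_training_labels(training_cohort)
    df = training_cohort.loc[labels.index].reset_index(drop=True)
    y = labels.to_numpy(dtype=int)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    best, best_loss = None, np.inf
    for penalty in grid:
        losses = []
        for train_idx, test_idx in kf.split(df):
            model = fit_prognosis(
                df.iloc[train_idx],
                penalty_weight=penalty,
                seed=seed,
                labels=pd.Series(y[train_idx], index=df.index[train_idx]),
            )
            p = predict_probability(model, df.iloc[test_idx])
            losses.append(log_loss(y[test_idx], p, labels=[0, 1]))
        mean_loss = float(np.mean(losses))
        if mean_loss < best_loss:
            best, best_loss = penalty, mean_loss
    return best


def predict_probability(model: PrognosisModel, df: pd.DataFrame) -> np.ndarray:
    """Predicted remission probabilities, invariant to row order."""
    X = _encode(df, model.feature_names)
    return expit(model.linear_predictor(X))


def calibrate_threshold(
    model: PrognosisModel, cohort: pd.DataFrame, complex_prevalence: float
) -> PrognosisModel:
    """Set the complexity threshold at the empirical quantile of training
    predictions matching the configured complex-case prevalence."""
    probs = predict_probability(model, cohort)
    model.complexity_threshold = float(np.quantile(probs, complex_prevalence))
    return model


def classify(model: PrognosisModel, patient) -> tuple:
    """(probability, label) for one patient (mapping or Series).

    Label is ``complex`` iff probability < threshold (strict); a probability
    exactly at the threshold is ``standard``.
    """
    row = pd.DataFrame([dict(patient)])
    p = float(predict_probability(model, row)[0])
    label = "complex" if p < model.complexity_threshold else "standard"
    return p, label


def classify_cohort(model: PrognosisModel, df: pd.DataFrame) -> pd.DataFrame:
    probs = predict_probability(model, df)
    labels = np.where(probs < model.complexity_threshold, "complex", "standard")
    return pd.DataFrame(
        {"predicted_remission_prob": probs, "complexity_label": labels}, index=df.index
    )


def save_model(model: PrognosisModel, path) -> None:
    """Serialize as a plain-text key-value file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"intercept\t{model.intercept!r}\n")
        fh.write(f"penalty_weight\t{model.penalty_weight!r}\n")
        fh.write(f"complexity_threshold\t{model.complexity_threshold!r}\n")
        for name, coef in zip(model.feature_names, model.coefficients):
            fh.write(f"coef:{name}\t{coef!r}\n")


def load_model(path) -> PrognosisModel:
    scalars, names, coefs = {}, [], []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            key, value = line.rstrip("\n").split("\t")
            if key.startswith("coef:"):
                names.append(key[5:])
                coefs.append(float(value))
            else:
                scalars[key] = float(value)
    return PrognosisModel(
        feature_names=tuple(names),
        coefficients=np.array(coefs),
        intercept=scalars["intercept"],
        penalty_weight=scalars["penalty_weight"],
        complexity_threshold=scalars["complexity_threshold"],
    )
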