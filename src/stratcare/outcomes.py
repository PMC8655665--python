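"""Endpoint classification: reliable and clinically significant improvement.

RCSI (Jacobson–Truax style) requires the posttreatment score to fall below
the clinical cutoff (strict inequality) AND the improvement to reach the
reliable-change magnitude (>=).  Reliable recovery additionally requires
subclinical scores on both instruments and no reliable deterioration on
either.  Classification is pure and deterministic.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import GAD7_BOUNDS, OutcomeThresholds, PHQ9_BOUNDS
from .errors import MissingEndpointError, NotACaseError


def _check(value, lo, hi, what):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingEndpointError(f"{what} score is missing")
    if not lo <= value <= hi:
        raise ValueError(f"{what} score {value} outside [{lo}, {hi}]")


def rcsi(baseline, post, cutoff, reliable_change, bounds):
    """Reliable and clinically significant improvement on one instrument."""
    lo, hi = bounds
    _check(baseline, lo, hi, "baseline")
    _check(post, lo, hi, "posttreatment")
    if baseline < cutoff:
        raise NotACaseError(
            f"baseline {baseline} below clinical cutoff {cutoff}: RCSI undefined"
        )
    return bool(post < cutoff and (baseline - post) >= reliable_change)


def rcsi_phq9(baseline, post, cutoff=10, reliable_change=6):
    """Depression RCSI: posttreatment PHQ-9 < 10 and improved by >= 6 points."""
    return rcsi(baseline, post, cutoff, reliable_change, PHQ9_BOUNDS)


def rcsi_gad7(baseline, post, cutoff=8, reliable_change=4):
    """Anxiety RCSI: posttreatment GAD-7 < 8 and improved by >= 4 points."""
    return rcsi(baseline, post, cutoff, reliable_change, GAD7_BOUNDS)


def reliable_improvement(baseline, post, reliable_change):
    return bool((baseline - post) >= reliable_change)


def reliable_deterioration(baseline, post, reliable_change):
    """Symmetric counterpart: worsening by at least the reliable-change magnitude."""
    return bool((post - baseline) >= reliable_change)


def reliable_recovery(
    baseline_phq9,
    post_phq9,
    baseline_gad7,
    post_gad7,
    thresholds: OutcomeThresholds | None = None,
):
    """Composite recovery for patients case-level on PHQ-9 and/or GAD-7.

    True iff (1) reliable improvement on every measure where the patient was
    a case, (2) both posttreatment scores subclinical, and (3) no reliable
    deterioration on either measure.
    """
    t = thresholds or OutcomeThresholds()
    _check(baseline_phq9, *PHQ9_BOUNDS, "baseline PHQ-9")
    _check(baseline_gad7, *GAD7_BOUNDS, "baseline GAD-7")
    _check(post_phq9, *PHQ9_BOUNDS, "posttreatment PHQ-9")
    _check(post_gad7, *GAD7_BOUNDS, "posttreatment GAD-7")
    case_phq = baseline_phq9 >= t.phq9_cutoff
    case_gad = baseline_gad7 >= t.gad7_cutoff
    if not (case_phq or case_gad):
        raise NotACaseError("patient subclinical on both measures at baseline")
    if case_phq and not reliable_improvement(baseline_phq9, post_phq9, t.phq9_reliable_change):
        return False
    if case_gad and not reliable_improvement(baseline_gad7, post_gad7, t.gad7_reliable_change):
        return False
    if post_phq9 >= t.phq9_cutoff or post_gad7 >= t.gad7_cutoff:
        return False
    if reliable_deterioration(baseline_phq9, post_phq9, t.phq9_reliable_change):
        return False
    if reliable_deterioration(baseline_gad7, post_gad7, t.gad7_reliable_change):
        return False
    return True


def build_outcome_panel(
    df: pd.DataFrame, thresholds: OutcomeThresholds | None = None
) -> pd.DataFrame:
    """Vectorized per-patient outcome panel.

    RCSI columns are NaN for patients who are not a case on that instrument
    or whose endpoint score is missing; reliable_recovery is NaN for patients
    subclinical on both measures at baseline or with any missing endpoint.
    """
    t = thresholds or OutcomeThresholds()
    b_phq = df["baseline_phq9"].to_numpy(dtype=float)
    b_gad = df["baseline_gad7"].to_numpy(dtype=float)
    p_phq = df["post_phq9"].to_numpy(dtype=float)
    p_gad = df["post_gad7"].to_numpy(dtype=float)
    obs_phq = ~np.isnan(p_phq)
    obs_gad = ~np.isnan(p_gad)
    case_phq = b_phq >= t.phq9_cutoff
    case_gad = b_gad >= t.gad7_cutoff

    def flagged(condition, defined):
        out = np.full(len(df), np.nan)
        out[defined] = condition[defined].astype(float)
        return out

    rcsi_p = (p_phq < t.phq9_cutoff) & ((b_phq - p_phq) >= t.phq9_reliable_change)
    rcsi_g = (p_gad < t.gad7_cutoff) & ((b_gad - p_gad) >= t.gad7_reliable_change)
    impr_p = (b_phq - p_phq) >= t.phq9_reliable_change
    det_p = (p_phq - b_phq) >= t.phq9_reliable_change
    impr_g = (b_gad - p_gad) >= t.gad7_reliable_change
    det_g = (p_gad - b_gad) >= t.gad7_reliable_change

    recovery = np.ones(len(df), dtype=bool)
    recovery &= np.where(case_phq, impr_p, True)
    recovery &= np.where(case_gad, impr_g, True)
    recovery &= (p_phq < t.phq9_cutoff) & (p_gad < t.gad7_cutoff)
    recovery &= ~det_p & ~det_g
    recovery_defined = (case_phq | case_gad) & obs_phq & obs_gad

    panel = pd.DataFrame(
        {
            "patient_id": df["patient_id"] if "patient_id" in df else np.arange(1, len(df) + 1),
            "caseness_phq9": case_phq.astype(int),
            "caseness_gad7": case_gad.astype(int),
            "rcsi_phq9": flagged(rcsi_p, case_phq & obs_phq),
            "rcsi_gad7": flagged(rcsi_g, case_gad & obs_gad),
            "reliable_improvement": flagged(impr_p, obs_phq),
            "reliable_deterioration": flagged(det_p | det_g, obs_phq & obs_gad),
            "reliable_recovery": flagged(recovery, recovery_defined),
        }
    )
    if "dropout" in df:
        panel["dropout"] = df["dropout"].to_numpy()
    return panel
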