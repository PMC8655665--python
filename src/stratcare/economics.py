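"""Treatment costs, incremental cost, and the cost-effectiveness
acceptability curve (CEAC).

Costs take a health-services perspective: one assessment plus session
costs at intensity-specific unit prices (split across low- and
high-intensity phases for stepped-up patients).  The CEAC is estimated by
nonparametric patient-level bootstrap within arm: at each willingness-to-
pay value λ it reports the fraction of replicates with positive
incremental net benefit λ·Δeffect − Δcost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CostConfig
from .errors import DataError
from .cohort import as_rng


@dataclass
class EconResult:
    mean_cost: dict
    incremental_cost: float
    incremental_cost_ci: tuple
    incremental_effect: float
    ceac: dict = field(default_factory=dict)
    lambda_50: float = float("nan")
    effect_name: str = "reliable_improvement"
    n_boot: int = 0

    def ceac_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": list(self.ceac), "prob_cost_effective": list(self.ceac.values())}
        )


def patient_cost(record, cost_config: CostConfig) -> float:
    """assessment_cost + sessions x per-intensity unit cost."""
    s_lit = record["sessions_lit"]
    s_hit = record["sessions_hit"]
    if s_lit < 0 or s_hit < 0:
        raise DataError("negative session count")
    return float(
        cost_config.assessment_cost
        + s_lit * cost_config.unit_cost_lit_session
        + s_hit * cost_config.unit_cost_hit_session
    )


def cohort_costs(df: pd.DataFrame, cost_config: CostConfig) -> pd.Series:
    s_lit = df["sessions_lit"].to_numpy(dtype=float)
    s_hit = df["sessions_hit"].to_numpy(dtype=float)
    if (s_lit < 0).any() or (s_hit < 0).any():
        raise DataError("negative session count")
    costs = (
        cost_config.assessment_cost
        + s_lit * cost_config.unit_cost_lit_session
        + s_hit * cost_config.unit_cost_hit_session
    )
    return pd.Series(costs, index=df.index, name="cost")


def ceac(
    table: pd.DataFrame,
    cost_config: CostConfig,
    effect_col: str = "reliable_improvement",
    cost_col: str | None = None,
    arm_col: str = "arm",
    intervention: str = "stratified",
    seed=None,
) -> EconResult:
    """Bootstrap CEAC and percentile CI for the incremental cost.

    ``effect_col`` must be a binary per-patient outcome (rows where it is
    missing are dropped); costs are computed from the session columns unless
    ``cost_col`` names a precomputed column.
    """
    cost_config.validate()
    df = table.dropna(subset=[effect_col]).copy()
    costs = (
        df[cost_col].to_numpy(dtype=float)
        if cost_col
        else cohort_costs(df, cost_config).to_numpy()
    )
    effects = df[effect_col].to_numpy(dtype=float)
    arm_mask = (df[arm_col] == intervention).to_numpy()
    if arm_mask.all() or not arm_mask.any():
        raise DataError("both arms must be present")
    c1, e1 = costs[arm_mask], effects[arm_mask]
    c0, e0 = costs[~arm_mask], effects[~arm_mask]

    rng = as_rng(cost_config.seed if seed is None else seed)
    reps = cost_config.bootstrap_reps
    n1, n0 = c1.size, c0.size
    idx1 = rng.integers(0, n1, size=(reps, n1))
    idx0 = rng.integers(0, n0, size=(reps, n0))
    d_cost = c1[idx1].mean(axis=1) - c0[idx0].mean(axis=1)
    d_eff = e1[idx1].mean(axis=1) - e0[idx0].mean(axis=1)

    grid = np.asarray(cost_config.wtp_grid, dtype=float)
    nb = grid[None, :] * d_eff[:, None] - d_cost[:, None]
    probs = (nb > 0).mean(axis=0)

    lam50 = float("nan")
    crossing = np.nonzero(probs >= 0.5)[0]
    if crossing.size and crossing[0] > 0:
        j = crossing[0]
        x0, x1 = grid[j - 1], grid[j]
        y0, y1 = probs[j - 1], probs[j]
        lam50 = float(x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0)) if y1 > y0 else float(x1)
    elif crossing.size:
        lam50 = float(grid[0])

    ci = tuple(np.percentile(d_cost, [2.5, 97.5]).tolist())
    return EconResult(
        mean_cost={
            intervention: float(c1.mean()),
            "comparator": float(c0.mean()),
        },
        incremental_cost=float(c1.mean() - c0.mean()),
        incremental_cost_ci=ci,
        incremental_effect=float(e1.mean() - e0.mean()),
        ceac={float(l): float(p) for l, p in zip(grid, probs)},
        lambda_50=lam50,
        effect_name=effect_col,
        n_boot=reps,
    )
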