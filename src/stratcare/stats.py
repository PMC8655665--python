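"""Statistical machinery for the between-arm comparisons.

Implements the five analysis steps applied to the patient-level table:
EM imputation of missing endpoint scores under a multivariate-normal model,
baseline-adjusted logistic regression (odds ratio with Wald CI), a
random-intercept logistic model for the clinician-cluster check (-2 delta
log-likelihood vs the plain fit), and the Pearson chi-square and
Mann-Whitney U tests for the categorical and count comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit, logsumexp

from .errors import ConvergenceError, DataError, FitError, ZeroMarginError


# ---------------------------------------------------------------------------
# Contingency tables and ranks
# ---------------------------------------------------------------------------

def pearson_chi2(a, b, c, d) -> float:
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]], no continuity
    correction: n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    for x in (a, b, c, d):
        if x < 0:
            raise DataError("negative cell count")
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ZeroMarginError("chi-square undefined: zero margin")
    return float(n * (a * d - b * c) ** 2 / denom)


@dataclass
class MannWhitneyResult:
    u: float
    se: float
    z: float
    p: float


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Mann-Whitney U with normal approximation and tie-corrected SE.

    Convention: U counts pairs where an x observation exceeds a y
    observation (ties count 1/2), so x = {1, 2} vs y = {3, 4} gives U = 0.
    No continuity correction is applied to z.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # pairs favoring x
    mean_u = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    se = float(np.sqrt(var_u))
    if se == 0:
        return MannWhitneyResult(u=float(u), se=0.0, z=0.0, p=1.0)
    z = (u - mean_u) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MannWhitneyResult(u=float(u), se=se, z=float(z), p=float(p))


# ---------------------------------------------------------------------------
# Adjusted logistic regression
# ---------------------------------------------------------------------------

@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int


def adjusted_logistic_or(
    table: pd.DataFrame,
    outcome: str,
    group_var: str = "arm",
    baseline_covariate: str = "baseline_phq9",
    reference: str = "stepped",
) -> OddsRatioResult:
    """Outcome ~ group + baseline covariate; OR = exp(group coefficient),
    Wald 95% CI.  Rows with a missing outcome are dropped."""
    df = table.dropna(subset=[outcome])
    y = df[outcome].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DataError(f"outcome {outcome!r} is not binary")
    groups = df[group_var].unique()
    if len(groups) < 2:
        raise DataError("both groups must be present")
    g = (df[group_var] != reference).to_numpy(dtype=float)
    X = sm.add_constant(
        np.column_stack([g, df[baseline_covariate].to_numpy(dtype=float)])
    )
    try:
        fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(fit.bse)):
        raise FitError("non-finite standard errors: possible separation")
    beta, se = fit.params[1], fit.bse[1]
    z = stats.norm.ppf(0.975)
    return OddsRatioResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p=float(fit.pvalues[1]),
        n=len(df),
        events=int(y.sum()),
    )


# ---------------------------------------------------------------------------
# Cluster-effect check: random-intercept logistic vs plain logistic
# ---------------------------------------------------------------------------

@dataclass
class ClusterEffectResult:
    minus2_delta_ll: float
    df: int
    p: float
    sigma: float
    ll_mixed: float
    ll_plain: float


def _mixed_loglik(params, X, y, cluster_index, n_clusters, gh_x, gh_w):
    beta = params[:-1]
    sigma = np.exp(params[-1])
    eta = X @ beta
    # nodes: u = sqrt(2) * sigma * t, weights w / sqrt(pi)
    u = np.sqrt(2.0) * sigma * gh_x
    lin = eta[:, None] + u[None, :]
    logp = -np.logaddexp(0.0, -lin)
    log1mp = -np.logaddexp(0.0, lin)
    contrib = np.where(y[:, None] == 1, logp, log1mp)
    per_cluster = np.zeros((n_clusters, gh_x.size))
    np.add.at(per_cluster, cluster_index, contrib)
    return float(logsumexp(per_cluster + np.log(gh_w / np.sqrt(np.pi)), axis=1).sum())


def cluster_effect_check(
    table: pd.DataFrame,
    outcome: str,
    cluster_var: str = "clinician_id",
    covariates: tuple = ("baseline_phq9",),
    gh_points: int = 20,
) -> ClusterEffectResult:
    """Likelihood-ratio comparison of a clinician random-intercept logistic
    model against the plain logistic model (-2 delta LL, df = 1).

    The mixed likelihood is maximized by adaptive search over the intercept
    SD with Gauss-Hermite quadrature; the statistic is floored at 0 because
    the models are nested at sigma = 0.
    """
    df = table.dropna(subset=[outcome])
    clusters = df[cluster_var].unique()
    if len(clusters) < 2:
        raise DataError("cluster check undefined with a single cluster")
    y = df[outcome].to_numpy(dtype=float)
    X = sm.add_constant(
        np.column_stack([df[c].to_numpy(dtype=float) for c in covariates])
        if covariates
        else np.zeros((len(df), 0))
    )
    plain = sm.Logit(y, X).fit(disp=False, maxiter=200)
    ll_plain = float(plain.llf)

    codes, _ = pd.factorize(df[cluster_var])
    n_clusters = codes.max() + 1
    gh_x, gh_w = np.polynomial.hermite.hermgauss(gh_points)

    def neg_ll(params):
        return -_mixed_loglik(params, X, y, codes, n_clusters, gh_x, gh_w)

    best_ll = ll_plain
    best_params = None
    for sigma0 in (0.1, 0.5, 1.0):
        start = np.concatenate([plain.params, [np.log(sigma0)]])
        res = optimize.minimize(neg_ll, start, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 4000})
        if -res.fun > best_ll:
            best_ll = -res.fun
            best_params = res.x
    sigma_hat = float(np.exp(best_params[-1])) if best_params is not None else 0.0
    stat = max(0.0, 2.0 * (best_ll - ll_plain))
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return ClusterEffectResult(
        minus2_delta_ll=stat, df=1, p=p, sigma=sigma_hat,
        ll_mixed=best_ll, ll_plain=ll_plain,
    )


# ---------------------------------------------------------------------------
# EM imputation of endpoint scores
# ---------------------------------------------------------------------------

@dataclass
class EMResult:
    table: pd.DataFrame
    mean: np.ndarray = None
    cov: np.ndarray = None
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0


def em_impute_endpoints(
    table: pd.DataFrame,
    endpoint_cols: tuple = ("post_phq9", "post_gad7"),
    predictor_cols: tuple = ("baseline_phq9", "baseline_gad7", "wsas", "sapas"),
    tol: float = 1e-6,
    max_iter: int = 500,
    bounds: dict | None = None,
    round_values: bool = True,
) -> EMResult:
    """EM under a joint multivariate-normal model of (predictors, endpoints).

    Missingness must be confined to the endpoint columns.  Convergence is
    declared when the observed-data log-likelihood changes by less than
    ``tol``; missing cells are then replaced by their conditional means
    (clipped to instrument bounds and rounded when requested).  The result
    is deterministic given the inputs.
    """
    cols = list(predictor_cols) + list(endpoint_cols)
    Y = table[cols].to_numpy(dtype=float)
    n, p = Y.shape
    miss = np.isnan(Y)
    if miss[:, : len(predictor_cols)].any():
        raise DataError("predictor columns must be complete")
    if not miss.any():
        return EMResult(table=table.copy(), n_iter=0)

    mu = np.nanmean(Y, axis=0)
    filled = np.where(miss, mu, Y)
    cov = np.cov(filled, rowvar=False, bias=True)
    cov += 1e-8 * np.eye(p)

    patterns = {}
    for i in range(n):
        patterns.setdefault(tuple(miss[i]), []).append(i)

    trace = []
    prev_ll = -np.inf
    for iteration in range(1, max_iter + 1):
        Ey = Y.copy()
        Eyy_corr = np.zeros((p, p))
        ll = 0.0
        for pattern, idx in patterns.items():
            idx = np.asarray(idx)
            m = np.array(pattern)
            o = ~m
            yo = Y[np.ix_(idx, np.flatnonzero(o))]
            mu_o, mu_m = mu[o], mu[m]
            S_oo = cov[np.ix_(o, o)]
            ll += stats.multivariate_normal.logpdf(
                yo, mean=mu_o, cov=S_oo, allow_singular=True
            ).sum()
            if not m.any():
                continue
            S_mo = cov[np.ix_(m, o)]
            S_mm = cov[np.ix_(m, m)]
            solve = np.linalg.solve(S_oo, S_mo.T).T
            cond_mean = mu_m + (yo - mu_o) @ solve.T
            cond_cov = S_mm - solve @ S_mo.T
            Ey[np.ix_(idx, np.flatnonzero(m))] = cond_mean
            Eyy_corr[np.ix_(m, m)] += len(idx) * cond_cov
        mu = Ey.mean(axis=0)
        centered = Ey - mu
        cov = (centered.T @ centered + Eyy_corr) / n
        cov += 1e-10 * np.eye(p)
        trace.append(ll)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    else:
        raise ConvergenceError(
            f"EM did not converge in {max_iter} iterations", trace=trace
        )

    # Final imputation: conditional means under the converged parameters.
    imputed = Y.copy()
    for pattern, idx in patterns.items():
        m = np.array(pattern)
        if not m.any():
            continue
        idx = np.asarray(idx)
        o = ~m
        yo = Y[np.ix_(idx, np.flatnonzero(o))]
        solve = np.linalg.solve(cov[np.ix_(o, o)], cov[np.ix_(m, o)].T).T
        imputed[np.ix_(idx, np.flatnonzero(m))] = mu[m] + (yo - mu[o]) @ solve.T

    out = table.copy()
    for j, col in enumerate(cols):
        values = imputed[:, j]
        if col in endpoint_cols and bounds and col in bounds:
            lo, hi = bounds[col]
            values = np.clip(values, lo, hi)
            if round_values:
                values = np.rint(values)
        elif col in endpoint_cols and round_values and bounds is not None:
            values = np.rint(values)
        out[col] = values
    return EMResult(table=out, mean=mu, cov=cov, loglik_trace=trace, n_iter=iteration)
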