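"""Weibull accelerated failure time (AFT) regression with right censoring.

Model
-----
``log T = X beta + sigma * W`` with ``W`` standard Gumbel (minimum),
which for Weibull errors is simultaneously a proportional-hazards
model: the hazard ratio for a unit increase in covariate ``x_j`` is
``HR_j = exp(-beta_j / sigma)``.

The log-likelihood for right-censored data, with
``z_i = (log t_i - x_i' beta) / sigma`` and event indicator ``d_i``, is

``l = sum_i [ d_i (z_i - log sigma) - exp(z_i) ]``

and is maximized over ``theta = (beta, log sigma)`` by Newton's method
with analytic gradient and Hessian (step-halving line search, quasi-
Newton fallback).  The reported covariance is the inverse observed
information on the ``(beta, log sigma)`` scale; hazard-ratio confidence
intervals use the delta method on ``-beta_j / sigma``.

Continuous covariates are standardized internally for numerical
conditioning and the estimates mapped back, so results are invariant to
affine rescaling of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SurvivalDesign",
    "AFTFit",
    "HazardRatio",
    "RankDeficientDesignError",
    "ConvergenceError",
    "fit_weibull_aft",
    "aft_to_hr",
    "lrt",
    "wald_p",
    "stratified_treatment_hr",
    "StratifiedTreatmentResult",
    "build_design",
]

INTERCEPT = "Intercept"


class RankDeficientDesignError(ValueError):
    """The design matrix has linearly dependent columns."""


class ConvergenceError(RuntimeError):
    """The likelihood maximization did not converge."""


@dataclass
class SurvivalDesign:
    """Right-censored survival data with a named covariate matrix.

    ``X`` should include an intercept column (see :func:`build_design`).
    """

    time: np.ndarray
    event: np.ndarray
    X: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.time.size:
            raise ValueError("X must be (n, p) aligned with time")
        if len(self.names) != self.X.shape[1]:
            raise ValueError("names must match X columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate column names in design")
        if np.any(self.time <= 0):
            raise ValueError("all survival times must be > 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0/1")
        if self.event.sum() < 1:
            raise ValueError("design has no events")
        if not (np.isfinite(self.X).all() and np.isfinite(self.time).all()):
            raise ValueError("design contains non-finite values")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


def build_design(
    df: pd.DataFrame,
    time_col: str,
    event_col: str,
    covariates: list[str],
    add_intercept: bool = True,
) -> SurvivalDesign:
    """Build a design from a patient table.

    String/categorical covariates are dummy-coded against their first
    (sorted) level; the special column name ``treatment`` may be used if
    the table has an ``arm`` column with 'intensive'/'standard' values.
    """
    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols[INTERCEPT] = np.ones(len(df))
    for c in covariates:
        if c == "treatment" and c not in df.columns and "arm" in df.columns:
            cols["treatment"] = (df["arm"] == "intensive").to_numpy(dtype=float)
            continue
        s = df[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.dropna()))
            for lev in levels[1:]:
                cols[f"{c}[{lev}]"] = (s == lev).to_numpy(dtype=float)
        else:
            cols[c] = s.to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    return SurvivalDesign(
        time=df[time_col].to_numpy(dtype=float),
        event=df[event_col].to_numpy(dtype=int),
        X=X,
        names=tuple(cols.keys()),
    )


@dataclass
class AFTFit:
    """A maximized Weibull AFT model."""

    beta: pd.Series  # AFT-scale coefficients (log-time units)
    sigma: float
    loglik: float
    cov: np.ndarray  # covariance of (beta, log sigma)
    n: int
    n_events: int
    converged: bool
    n_iter: int = 0
    grad_norm: float = np.nan

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.beta.index)

    @property
    def n_params(self) -> int:
        return len(self.beta) + 1  # + sigma

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n) - 2 * self.loglik


@dataclass(frozen=True)
class HazardRatio:
    term: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float


def _loglik_only(theta: np.ndarray, X: np.ndarray, y: np.ndarray, d: np.ndarray) -> float:
    # Log-likelihood on the log-time scale, without the -sum(d*log t)
    # Jacobian constant (added once by the caller).
    beta, logs = theta[:-1], theta[-1]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        z = (y - X @ beta) / np.exp(logs)
        w = np.exp(np.minimum(z, 700.0))
        return float(np.sum(d * (z - logs)) - w.sum())


def _loglik_grad_hess(theta: np.ndarray, X: np.ndarray, y: np.ndarray, d: np.ndarray):
    beta, logs = theta[:-1], theta[-1]
    s = np.exp(logs)
    z = (y - X @ beta) / s
    z = np.clip(z, -700.0, 700.0)
    with np.errstate(over="ignore", invalid="ignore"):
        w = np.exp(z)
        ll = float(np.sum(d * (z - logs)) - w.sum())
        r = w - d
        gb = (X.T @ r) / s
        gs = float(np.sum(z * r) - d.sum())
        grad = np.append(gb, gs)
        p = X.shape[1]
        H = np.empty((p + 1, p + 1))
        Xw = X * w[:, None]
        H[:p, :p] = -(X.T @ Xw) / s**2
        hbs = (X.T @ (d - w - w * z)) / s
        H[:p, p] = H[p, :p] = hbs
        H[p, p] = float(np.sum(-z * r - z**2 * w))
    return ll, grad, H


def _newton(theta0, X, y, d, tol, max_iter):
    theta = theta0.copy()
    ll, g, H = _loglik_grad_hess(theta, X, y, d)
    eye = np.eye(theta.size)
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(g)) < tol:
            break
        # Damped Newton ascent: escalate ridge until an uphill step is found.
        lam = 0.0
        cand = None
        for _ in range(10):
            try:
                step = np.linalg.solve(-H + lam * eye, g)
            except np.linalg.LinAlgError:
                lam = max(1.0, 10.0 * lam)
                continue
            if not np.all(np.isfinite(step)):
                lam = max(1.0, 10.0 * lam)
                continue
            scale = 1.0
            for _ in range(30):
                trial = theta + scale * step
                ll_new = _loglik_only(trial, X, y, d)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    cand = trial
                    break
                scale *= 0.5
            if cand is not None:
                break
            lam = max(1.0, 10.0 * lam)
        if cand is None:
            break
        theta = cand
        ll, g, H = _loglik_grad_hess(theta, X, y, d)
    return theta, ll, g, H, it


def fit_weibull_aft(
    design: SurvivalDesign,
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 60,
) -> AFTFit:
    """Maximum-likelihood Weibull AFT fit.

    Parameters
    ----------
    design
        Survival design; must have full column rank.
    start
        Optional warm start ``(beta, log sigma)`` on the *raw* scale.
    tol
        Convergence threshold on the max-abs gradient component
        (internal standardized scale).

    Raises
    ------
    RankDeficientDesignError
        If the design columns are linearly dependent (names reported).
    """
    X, y, d = design.X, np.log(design.time), design.event.astype(float)
    n, p = X.shape

    # Rank diagnosis on column-scaled X.
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        zero = [design.names[i] for i in np.flatnonzero(norms == 0)]
        raise RankDeficientDesignError(f"all-zero design column(s): {zero}")
    Q, R = np.linalg.qr(X / norms)
    small = np.abs(np.diag(R)) < 1e-8
    if small.any():
        bad = [design.names[i] for i in np.flatnonzero(small)]
        raise RankDeficientDesignError(f"collinear design column(s): {bad}")

    # Internal standardization of non-constant columns.
    center = X.mean(axis=0)
    spread = X.std(axis=0)
    const = spread < 1e-12
    center[const] = 0.0
    spread[const] = 1.0
    Xs = (X - center) / spread

    if start is None:
        theta0 = np.zeros(p + 1)
        if INTERCEPT in design.names:
            theta0[design.names.index(INTERCEPT)] = float(np.log(np.median(design.time)))
        else:
            theta0[0] = float(np.log(np.median(design.time)))
    else:
        theta0 = np.asarray(start, dtype=float).copy()
        # map raw-scale start to standardized scale
        b = theta0[:p] * spread
        shift = float(np.sum(theta0[:p] * center))
        if INTERCEPT in design.names:
            b[design.names.index(INTERCEPT)] += shift
        theta0 = np.append(b, theta0[p])

    theta, ll, g, H, it = _newton(theta0, Xs, y, d, tol, max_iter)
    converged = bool(np.max(np.abs(g)) < max(tol, 1e-6))
    if not converged:
        res = optimize.minimize(
            lambda th: -_loglik_grad_hess(th, Xs, y, d)[0],
            theta,
            jac=lambda th: -_loglik_grad_hess(th, Xs, y, d)[1],
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
        )
        # polish the quasi-Newton solution with damped Newton steps
        theta, ll, g, H, _ = _newton(res.x, Xs, y, d, tol, max_iter)
        converged = bool(np.max(np.abs(g)) < 1e-4)

    # Covariance: inverse observed information on the standardized scale,
    # then mapped back through the affine reparameterization.
    info = -H
    try:
        cov_s = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_s = np.linalg.pinv(info)
    cov_s = (cov_s + cov_s.T) / 2.0

    # beta_raw_j = beta_s_j / spread_j (slopes); intercept absorbs centers.
    J = np.zeros((p + 1, p + 1))
    for j in range(p):
        J[j, j] = 1.0 / spread[j]
    if INTERCEPT in design.names:
        i0 = design.names.index(INTERCEPT)
        for j in range(p):
            if j != i0:
                J[i0, j] += -center[j] / spread[j]
    J[p, p] = 1.0
    beta_s = theta[:p]
    beta_raw = beta_s / spread
    if INTERCEPT in design.names:
        i0 = design.names.index(INTERCEPT)
        beta_raw[i0] = beta_s[i0] / spread[i0] - float(
            np.sum(np.delete(beta_s / spread * center, i0))
        )
    cov = J @ cov_s @ J.T
    cov = (cov + cov.T) / 2.0

    # add the log-time Jacobian constant so loglik is the density of T
    ll_time = ll - float(np.sum(d * y))

    return AFTFit(
        beta=pd.Series(beta_raw, index=list(design.names)),
        sigma=float(np.exp(theta[p])),
        loglik=ll_time,
        cov=cov,
        n=n,
        n_events=design.n_events,
        converged=converged,
        n_iter=it,
        grad_norm=float(np.max(np.abs(g))),
    )


def _require_converged(fit: AFTFit) -> None:
    if not fit.converged:
        raise ConvergenceError("refusing to use a non-converged AFT fit")


def aft_to_hr(fit: AFTFit, term: str, scale: float = 1.0) -> HazardRatio:
    """Hazard ratio for ``term`` via the Weibull identity ``exp(-beta/sigma)``.

    ``scale`` multiplies the coefficient first (HR per ``scale`` units).
    The 95% CI is a delta-method interval on the log-HR; the p-value is
    the two-sided Wald test of log-HR = 0.
    """
    _require_converged(fit)
    if term not in fit.beta.index:
        raise KeyError(f"unknown term {term!r}; have {list(fit.beta.index)}")
    j = list(fit.beta.index).index(term)
    p = len(fit.beta)
    b = fit.beta.iloc[j] * scale
    sigma = fit.sigma
    v = -b / sigma
    # gradient of v wrt (beta_j, log sigma)
    grad = np.zeros(p + 1)
    grad[j] = -scale / sigma
    grad[p] = b / sigma
    var = float(grad @ fit.cov @ grad)
    se = np.sqrt(max(var, 0.0))
    zq = stats.norm.ppf(0.975)
    pval = 2.0 * stats.norm.sf(abs(v) / se) if se > 0 else np.nan
    return HazardRatio(
        term=term,
        hr=float(np.exp(v)),
        ci_low=float(np.exp(v - zq * se)),
        ci_high=float(np.exp(v + zq * se)),
        p_value=float(pval),
    )


def wald_p(fit: AFTFit, term: str) -> float:
    """Two-sided Wald p-value for a single coefficient being zero."""
    _require_converged(fit)
    j = list(fit.beta.index).index(term)
    se = float(np.sqrt(max(fit.cov[j, j], 0.0)))
    if se == 0:
        return np.nan
    return float(2.0 * stats.norm.sf(abs(fit.beta.iloc[j]) / se))


def lrt(full: AFTFit, reduced: AFTFit, df: int) -> float:
    """Likelihood-ratio test p-value for nested Weibull AFT fits."""
    if df <= 0:
        raise ValueError("df must be positive")
    if not set(reduced.names) <= set(full.names):
        raise ValueError("models are not nested (reduced terms not in full model)")
    if full.loglik < reduced.loglik - 1e-8:
        raise ValueError(
            f"full-model log-likelihood ({full.loglik:.6f}) is below the "
            f"reduced model's ({reduced.loglik:.6f}); fits are suspect"
        )
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return float(stats.chi2.sf(stat, df))


@dataclass
class StratifiedTreatmentResult:
    """Per-variability-group treatment effects plus interaction tests."""

    per_group: dict[str, HazardRatio]
    n_by_group: dict[str, int]
    events_by_group: dict[str, int]
    interaction_p: float
    trend_p: float
    outcome: str


GROUP_ORDER = ("low", "medium", "high")


def stratified_treatment_hr(
    patients: pd.DataFrame,
    groups: np.ndarray | pd.Series,
    outcome: str,
    covariates: list[str],
) -> StratifiedTreatmentResult:
    """Treatment hazard ratios stratified by variability group.

    Fits one adjusted Weibull AFT per group for the treatment HR; the
    interaction p comes from a 2-df LRT of pooled models with/without
    treatment-by-group terms, and the trend p is a Wald test on a
    treatment-by-ordinal-group (0/1/2) coefficient.
    """
    groups = np.asarray(groups)
    if set(np.unique(groups)) != set(GROUP_ORDER):
        raise ValueError(f"expected exactly the groups {GROUP_ORDER}, got {set(groups)}")
    time_col, event_col = f"time_{outcome}", f"event_{outcome}"
    treat = (patients["arm"] == "intensive").to_numpy()
    per_group: dict[str, HazardRatio] = {}
    n_by, ev_by = {}, {}
    for g in GROUP_ORDER:
        mask = groups == g
        for armval, armname in ((True, "intensive"), (False, "standard")):
            if not np.any(mask & (treat == armval)):
                raise ValueError(f"empty cell: group={g!r}, arm={armname!r}")
        sub = patients.loc[mask]
        design = build_design(sub, time_col, event_col, ["treatment"] + covariates)
        fit = fit_weibull_aft(design)
        per_group[g] = aft_to_hr(fit, "treatment")
        n_by[g] = int(mask.sum())
        ev_by[g] = int(sub[event_col].sum())

    # Pooled models for interaction and trend.
    df = patients.copy()
    df["_treat"] = treat.astype(float)
    for g in ("medium", "high"):
        df[f"_grp_{g}"] = (groups == g).astype(float)
        df[f"_tx_{g}"] = df["_treat"] * df[f"_grp_{g}"]
    base_terms = ["_treat", "_grp_medium", "_grp_high"] + covariates
    full = fit_weibull_aft(build_design(df, time_col, event_col, base_terms + ["_tx_medium", "_tx_high"]))
    reduced = fit_weibull_aft(build_design(df, time_col, event_col, base_terms))
    interaction_p = lrt(full, reduced, df=2)

    ordinal = np.select([groups == g for g in GROUP_ORDER], [0.0, 1.0, 2.0])
    df["_tx_ord"] = df["_treat"] * ordinal
    trend_fit = fit_weibull_aft(
        build_design(df, time_col, event_col, base_terms + ["_tx_ord"])
    )
    trend_p = wald_p(trend_fit, "_tx_ord")

    return StratifiedTreatmentResult(
        per_group=per_group,
        n_by_group=n_by,
        events_by_group=ev_by,
        interaction_p=interaction_p,
        trend_p=trend_p,
        outcome=outcome,
    )
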