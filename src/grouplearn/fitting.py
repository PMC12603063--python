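"""Per-participant maximum-likelihood parameter estimation.

All models are fitted by least squares under a Gaussian observation model:
minimizing the sum of squared residuals between predicted and observed
ratings is the maximum-likelihood estimate, and profiling out the noise
scale gives sigma_hat^2 = SSE/n and

    ln L = -n/2 * (ln(2 pi sigma_hat^2) + 1).

Optimization uses bounded quasi-Newton (L-BFGS-B) with multiple random
restarts drawn uniformly within the parameter bounds to escape local
minima.  Closeness models are conditionally linear: for fixed gamma the
weights solve an ordinary least-squares problem, so gamma is profiled on a
grid, refined by 1-D bounded search, and the joint solution polished with a
final quasi-Newton step.

The free-parameter count k used in AIC = -2 ln L + 2k counts structural
parameters only; sigma is profiled identically for every model and cancels
in comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import closeness_models, learning_models
from ._kernels import discounted_sums, rw_forward
from .learning_models import LatentTrajectory, LearningParams
from .closeness_models import ClosenessParams, observed_closeness_change
from .synthetic_data import SessionData
from .task_design import INGROUP

__all__ = [
    "FitResult",
    "fit_learning",
    "fit_closeness",
    "goodness_of_fit",
    "learning_bounds",
    "closeness_bounds",
    "fits_to_frame",
]

#: fitting bounds: learning rates in [0,1], response scaling in (0,3]
_BETA_MIN = 1e-3
_GAMMA_GRID = np.linspace(0.0, 1.0, 201)


@dataclass
class FitResult:
    participant: str
    model: str
    params: dict[str, float]
    sse: float
    loglik: float
    k: int
    aic: float
    r2: float
    mse: float
    n_obs: int
    n_restarts_used: int = 0
    converged: bool = True
    group: str | None = None
    trajectory: LatentTrajectory | None = field(default=None, repr=False)

    def to_learning_params(self, v0_in: float, v0_out: float) -> LearningParams:
        p = self.params
        if self.model == "M1":
            a = [p["alpha"]] * 4
        elif self.model == "M2":
            a = [p["alpha_in"], p["alpha_in"], p["alpha_out"], p["alpha_out"]]
        else:
            a = [p["alpha_in_pos"], p["alpha_in_neg"], p["alpha_out_pos"], p["alpha_out_neg"]]
        return LearningParams(*a, p["beta"], v0_in, v0_out)


def learning_bounds(model_variant: str) -> list[tuple[float, float]]:
    n_alpha = {"M1": 1, "M2": 2, "M3": 4}[model_variant]
    return [(0.0, 1.0)] * n_alpha + [(_BETA_MIN, 3.0)]


def closeness_bounds(model_variant: str) -> list[tuple[float, float]]:
    n_w = 1 if model_variant == "C1" else 2
    return [(0.0, 10.0)] + [(-10.0, 10.0)] * n_w + [(0.0, 1.0)]


def _gaussian_loglik(sse: float, n: int) -> float:
    sigma2 = max(sse / n, 1e-12)
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def _expand_learning(x: np.ndarray, model_variant: str) -> tuple[float, float, float, float, float]:
    if model_variant == "M1":
        return x[0], x[0], x[0], x[0], x[1]
    if model_variant == "M2":
        return x[0], x[0], x[1], x[1], x[2]
    return x[0], x[1], x[2], x[3], x[4]


def _param_names(model_variant: str) -> list[str]:
    return {
        "M1": ["alpha", "beta"],
        "M2": ["alpha_in", "alpha_out", "beta"],
        "M3": ["alpha_in_pos", "alpha_in_neg", "alpha_out_pos", "alpha_out_neg", "beta"],
        "C1": ["w0", "w", "gamma"],
        "C2": ["w0", "w_pos", "w_neg", "gamma"],
    }[model_variant]


def _multistart(objective, bounds, n_restarts, rng):
    """Best-of-n bounded quasi-Newton minimization with uniform random
    starts; returns (x, fun, any_converged)."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = None
    converged = False
    for _ in range(max(1, n_restarts)):
        x0 = rng.uniform(lo, hi)
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return best.x, float(best.fun), converged


def fit_learning(
    session: SessionData,
    model_variant: str = "M3",
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit a learning-model variant to one participant's expectancy ratings.

    Initial values are read off the data (each group's first rating); those
    two trials serve as priors and are excluded from the residuals.  The
    same seed always reproduces the same restart stream and result.
    """
    sched = session.schedule
    obs = np.asarray(session.expectancy, dtype=float)
    is_in = np.ascontiguousarray(sched.is_ingroup)
    outcomes = np.ascontiguousarray(sched.outcome_sequence, dtype=np.float64)

    first_in = int(np.argmax(is_in))
    first_out = int(np.argmax(~is_in))
    v0_in = float(np.clip(obs[first_in], 0.0, 1.0))
    v0_out = float(np.clip(obs[first_out], 0.0, 1.0))
    mask = np.ones(len(obs), dtype=bool)
    mask[[first_in, first_out]] = False
    y = obs[mask]
    n = int(mask.sum())

    if np.std(obs) < 1e-12:
        warnings.warn(
            f"constant expectancy series for {session.participant}; "
            "learning rate is unidentifiable",
            stacklevel=2,
        )

    def objective(x: np.ndarray) -> float:
        aip, ain, aop, aon, beta = _expand_learning(x, model_variant)
        values, _ = rw_forward(is_in, outcomes, v0_in, v0_out, aip, ain, aop, aon)
        resid = beta * values[mask] - y
        return float(resid @ resid)

    rng = np.random.default_rng(seed)
    bounds = learning_bounds(model_variant)
    x, sse, converged = _multistart(objective, bounds, n_restarts, rng)
    if not converged:
        warnings.warn(f"no restart converged for {session.participant}/{model_variant}", stacklevel=2)

    aip, ain, aop, aon, beta = _expand_learning(x, model_variant)
    values, deltas = rw_forward(is_in, outcomes, v0_in, v0_out, aip, ain, aop, aon)
    params = LearningParams(aip, ain, aop, aon, beta, v0_in, v0_out)
    traj = LatentTrajectory(
        values=values,
        prediction_errors=deltas,
        predicted_ratings=beta * values,
        group_sequence=np.asarray(sched.group_sequence),
        outcome_sequence=np.asarray(sched.outcome_sequence),
        params=params,
    )
    gof = goodness_of_fit(y, beta * values[mask])
    k = learning_models.N_PARAMS[model_variant]
    loglik = _gaussian_loglik(sse, n)
    return FitResult(
        participant=session.participant,
        model=model_variant,
        params=dict(zip(_param_names(model_variant), x)),
        sse=sse,
        loglik=loglik,
        k=k,
        aic=-2.0 * loglik + 2.0 * k,
        r2=gof["r2"],
        mse=gof["mse"],
        n_obs=n,
        n_restarts_used=n_restarts,
        converged=converged,
        trajectory=traj,
    )


def _closeness_design(pe: np.ndarray, gamma: float, model_variant: str, n_obs: int) -> np.ndarray:
    s_all, s_pos, s_neg = discounted_sums(pe, float(gamma))
    if model_variant == "C1":
        return np.column_stack([np.ones(n_obs), s_all[:n_obs]])
    return np.column_stack([np.ones(n_obs), s_pos[:n_obs], s_neg[:n_obs]])


def _bounded_ols(X: np.ndarray, y: np.ndarray, bounds: list[tuple[float, float]]):
    """OLS, falling back to a bounded linear solve when the unconstrained
    solution violates the parameter box."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if np.any(coef < lo - 1e-12) or np.any(coef > hi + 1e-12):
        res = optimize.lsq_linear(X, y, bounds=(lo, hi))
        coef = res.x
    resid = X @ coef - y
    return coef, float(resid @ resid)


def fit_closeness(
    session: SessionData,
    trajectory: LatentTrajectory,
    model_variant: str = "C2",
    group: str = INGROUP,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit a closeness-model variant to one group's closeness-change series.

    Prediction errors come from ``trajectory`` (in fitted pipelines, the
    participant's winning learning model).  The problem is linear in the
    weights given gamma, so gamma is profiled on a 201-point grid, refined
    by bounded 1-D search, then the joint solution is polished with
    L-BFGS-B; extra random restarts of the joint problem guard against the
    profile path missing the optimum.
    """
    if len(trajectory.values) != session.schedule.n_trials:
        raise ValueError("trajectory length does not match the session's schedule")
    ratings = session.closeness(group)
    y = observed_closeness_change(ratings)
    n = len(y)
    pe = np.ascontiguousarray(trajectory.pe_series(group), dtype=np.float64)

    bounds = closeness_bounds(model_variant)
    lin_bounds = bounds[:-1]

    def profile_sse(gamma: float) -> float:
        X = _closeness_design(pe, gamma, model_variant, n)
        _, sse = _bounded_ols(X, y, lin_bounds)
        return sse

    grid_sse = np.array([profile_sse(g) for g in _GAMMA_GRID])
    g0 = _GAMMA_GRID[int(np.argmin(grid_sse))]
    lo1, hi1 = max(0.0, g0 - 0.01), min(1.0, g0 + 0.01)
    res1 = optimize.minimize_scalar(profile_sse, bounds=(lo1, hi1), method="bounded")
    gamma_star = float(res1.x) if res1.fun < grid_sse.min() else float(g0)

    X = _closeness_design(pe, gamma_star, model_variant, n)
    coef, _ = _bounded_ols(X, y, lin_bounds)
    x_start = np.append(coef, gamma_star)

    def objective(x: np.ndarray) -> float:
        Xg = _closeness_design(pe, x[-1], model_variant, n)
        resid = Xg @ x[:-1] - y
        return float(resid @ resid)

    polish = optimize.minimize(objective, x_start, method="L-BFGS-B", bounds=bounds)
    best_x, best_sse = (polish.x, float(polish.fun)) if polish.fun <= objective(x_start) else (
        x_start,
        objective(x_start),
    )
    converged = bool(polish.success)

    rng = np.random.default_rng(seed)
    if n_restarts > 1:
        x_r, sse_r, conv_r = _multistart(objective, bounds, n_restarts - 1, rng)
        if sse_r < best_sse:
            best_x, best_sse = x_r, sse_r
        converged = converged or conv_r

    names = _param_names(model_variant)
    pred = _closeness_design(pe, best_x[-1], model_variant, n) @ best_x[:-1]
    gof = goodness_of_fit(y, pred)
    k = closeness_models.N_PARAMS[model_variant]
    loglik = _gaussian_loglik(best_sse, n)
    return FitResult(
        participant=session.participant,
        model=model_variant,
        params=dict(zip(names, best_x)),
        sse=best_sse,
        loglik=loglik,
        k=k,
        aic=-2.0 * loglik + 2.0 * k,
        r2=gof["r2"],
        mse=gof["mse"],
        n_obs=n,
        n_restarts_used=n_restarts,
        converged=converged,
        group=group,
    )


def goodness_of_fit(
    observed: np.ndarray,
    predicted: np.ndarray,
    method: str = "pearson",
) -> dict[str, float]:
    """Variance explained and mean squared error of a fitted series.

    ``method="pearson"`` (default) reports the squared Pearson correlation
    of observed and predicted; ``method="sse"`` reports 1 - SSE/SST.  A
    zero-variance series makes the correlation undefined (NaN).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("need equal-length 1-D series with >= 2 points")
    resid = obs - pred
    mse = float(resid @ resid) / len(obs)
    if method == "pearson":
        if np.std(obs) < 1e-14 or np.std(pred) < 1e-14:
            return {"r2": float("nan"), "mse": mse}
        r, _ = stats.pearsonr(obs, pred)
        return {"r2": float(r**2), "mse": mse}
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        return {"r2": float("nan"), "mse": mse}
    return {"r2": 1.0 - float(resid @ resid) / sst, "mse": mse}


def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    """Flatten fit results into the package-standard CSV layout."""
    rows = []
    for f in fits:
        row = {
            "participant": f.participant,
            "model": f.model,
            "group": f.group,
            **f.params,
            "sse": f.sse,
            "loglik": f.loglik,
            "k": f.k,
            "aic": f.aic,
            "r2": f.r2,
            "mse": f.mse,
            "n_obs": f.n_obs,
            "converged": f.converged,
        }
        rows.append(row)
    return pd.DataFrame(rows)
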