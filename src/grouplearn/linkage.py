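"""Linking fitted model parameters to impression change.

The question these analyses answer: which learning-related parameters
(learning rates alpha, closeness weights W) explain the post- vs
pre-learning change in intergroup impressions, defined as

    (ingroup - outgroup)_after - (ingroup - outgroup)_before,

where negative values indicate a reduction of the initial ingroup bias?

Four tools: forward/backward stepwise multiple regression over the
candidate parameters; moderation analysis (interaction of a focal
predictor with a moderator such as frame or ingroup identification, with
simple slopes); influence diagnostics (DFFITS, Cook's distance, leverage,
DFBETAS) with a refit excluding flagged cases; and the descriptive
correlation between initial ingroup bias and ingroup identification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "LinkageResult",
    "stepwise_regression",
    "moderation",
    "influence_filter",
    "bias_identification_correlation",
]


@dataclass
class LinkageResult:
    analysis: str
    selected_predictors: list[str]
    coefficients: pd.DataFrame  # term, coef, se, t, p
    model_fit: object = field(repr=False, default=None)
    interaction: dict | None = None
    simple_slopes: pd.DataFrame | None = None
    robustness: pd.DataFrame | None = None
    flagged: list | None = None
    notes: str = ""


def _coef_table(fit) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": fit.model.exog_names,
            "coef": np.asarray(fit.params),
            "se": np.asarray(fit.bse),
            "t": np.asarray(fit.tvalues),
            "p": np.asarray(fit.pvalues),
        }
    )


def _ols(y: pd.Series, X: pd.DataFrame):
    return sm.OLS(np.asarray(y, dtype=float), sm.add_constant(X.astype(float))).fit()


def stepwise_regression(
    candidates: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    condition_threshold: float = 1e8,
) -> LinkageResult:
    """Forward/backward stepwise OLS over candidate predictors.

    Forward steps add the candidate with the smallest p-value below
    ``entry_p`` (ties broken by smaller p, then predictor name); backward
    steps drop any retained predictor whose p-value exceeds ``removal_p``;
    the two alternate to a fixed point.  Collinear candidates (condition
    number of the candidate matrix above ``condition_threshold``) raise a
    warning and the later duplicate is dropped from the candidate set.
    """
    y = pd.Series(np.asarray(outcome, dtype=float)).reset_index(drop=True)
    X_all = candidates.reset_index(drop=True).astype(float)
    n, p = X_all.shape
    if n <= p + 2:
        raise ValueError(f"need n > {p + 2} observations for {p} candidates, got {n}")

    cols = list(X_all.columns)
    if len(cols) > 1:
        std = X_all.std()
        keep = [c for c in cols if std[c] > 1e-12]
        if len(keep) < len(cols):
            warnings.warn("dropping zero-variance candidates", stacklevel=2)
        cond = np.linalg.cond(X_all[keep] - X_all[keep].mean()) if keep else 0.0
        while cond > condition_threshold and len(keep) > 1:
            warnings.warn("collinear candidates; dropping later duplicate", stacklevel=2)
            keep = keep[:-1]
            cond = np.linalg.cond(X_all[keep] - X_all[keep].mean())
        cols = keep

    selected: list[str] = []
    changed = True
    while changed:
        changed = False
        # forward: best candidate below entry threshold
        best = None
        for c in sorted(set(cols) - set(selected)):
            fit = _ols(y, X_all[selected + [c]])
            pv = fit.pvalues[c]
            if pv < entry_p and (best is None or pv < best[1] - 1e-15):
                best = (c, pv)
        if best is not None:
            selected.append(best[0])
            changed = True
        # backward: drop anything above removal threshold
        while selected:
            fit = _ols(y, X_all[selected])
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] > removal_p:
                selected.remove(worst)
                changed = True
            else:
                break

    fit = _ols(y, X_all[selected]) if selected else sm.OLS(y, np.ones((n, 1))).fit()
    return LinkageResult(
        analysis="stepwise",
        selected_predictors=selected,
        coefficients=_coef_table(fit),
        model_fit=fit,
        notes=f"entry_p={entry_p}, removal_p={removal_p}",
    )


def moderation(
    x: np.ndarray | pd.Series,
    moderator: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    x_name: str = "x",
    moderator_name: str = "moderator",
) -> LinkageResult:
    """OLS moderation: outcome on centered x, moderator, and their product.

    A binary moderator (exactly two distinct values) is coded 0/1 and
    simple slopes are reported at each level; a continuous moderator is
    mean-centered with simple slopes at mean +/- 1 SD.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(moderator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, moderator and outcome must be aligned")
    if len(y) <= 10:
        raise ValueError("need n > 10 observations")
    if np.std(m) < 1e-12:
        raise ValueError("moderator has zero variance")

    levels = np.unique(m)
    binary = len(levels) == 2
    xc = x - x.mean()
    if binary:
        mc = (m == levels[1]).astype(float)
        probe_points = {f"level_{levels[0]:g}": 0.0, f"level_{levels[1]:g}": 1.0}
    else:
        mc = m - m.mean()
        sd = m.std(ddof=1)
        probe_points = {"mean_minus_1sd": -sd, "mean": 0.0, "mean_plus_1sd": sd}

    X = pd.DataFrame({x_name: xc, moderator_name: mc, f"{x_name}:{moderator_name}": xc * mc})
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], dtype=float)
    fit = _ols(pd.Series(y), X)

    inter = f"{x_name}:{moderator_name}"
    interaction = {
        "term": inter,
        "coef": float(fit.params[inter]),
        "t": float(fit.tvalues[inter]),
        "p": float(fit.pvalues[inter]),
    }

    # simple slope of x at moderator value m*: b_x + m* b_inter, with
    # variance from the coefficient covariance
    cov = fit.cov_params()
    slopes = []
    for label, mv in probe_points.items():
        slope = fit.params[x_name] + mv * fit.params[inter]
        var = (
            cov.loc[x_name, x_name]
            + 2 * mv * cov.loc[x_name, inter]
            + mv**2 * cov.loc[inter, inter]
        )
        se = float(np.sqrt(var))
        t = float(slope / se)
        df = fit.df_resid
        pv = float(2 * stats.t.sf(abs(t), df))
        slopes.append({"at": label, "slope": float(slope), "se": se, "t": t, "p": pv})

    return LinkageResult(
        analysis="moderation",
        selected_predictors=list(X.columns),
        coefficients=_coef_table(fit),
        model_fit=fit,
        interaction=interaction,
        simple_slopes=pd.DataFrame(slopes),
    )


def influence_filter(model_fit) -> LinkageResult:
    """Flag influential observations of a fitted OLS and refit without them.

    An observation is flagged when any standard cutoff trips:
    |DFFITS| > 2 sqrt(k/n), Cook's D > 4/n, leverage > 2k/n, or any
    |DFBETA| > 1.  The refit is reported whether or not conclusions change.
    """
    infl = OLSInfluence(model_fit)
    n = int(model_fit.nobs)
    k = int(model_fit.df_model) + 1  # including intercept
    dffits = np.abs(infl.dffits[0]) > 2 * np.sqrt(k / n)
    cooks = infl.cooks_distance[0] > 4 / n
    hat = infl.hat_matrix_diag > 2 * k / n
    dfbeta = np.any(np.abs(infl.dfbetas) > 1, axis=1)
    flags = dffits | cooks | hat | dfbeta
    flagged = list(np.nonzero(flags)[0])

    exog = np.asarray(model_fit.model.exog)
    endog = np.asarray(model_fit.model.endog)
    keep = ~flags
    if flagged:
        refit = sm.OLS(endog[keep], exog[keep]).fit()
    else:
        refit = model_fit
    names = model_fit.model.exog_names
    robustness = pd.DataFrame(
        {
            "term": names,
            "coef": np.asarray(refit.params),
            "se": np.asarray(refit.bse),
            "t": np.asarray(refit.tvalues),
            "p": np.asarray(refit.pvalues),
        }
    )
    return LinkageResult(
        analysis="influence",
        selected_predictors=list(names),
        coefficients=_coef_table(model_fit),
        model_fit=refit,
        robustness=robustness,
        flagged=flagged,
        notes=f"{len(flagged)} of {n} observations flagged",
    )


def bias_identification_correlation(participants: pd.DataFrame) -> dict:
    """Pearson (and Spearman robustness) correlation between initial
    ingroup bias (pre ingroup - outgroup impression) and ingroup
    identification.

    Expects columns ``impression_pre_in``, ``impression_pre_out`` and
    ``identification``.
    """
    if len(participants) < 4:
        raise ValueError("need at least 4 participants")
    bias = (
        participants["impression_pre_in"].to_numpy(dtype=float)
        - participants["impression_pre_out"].to_numpy(dtype=float)
    )
    ident = participants["identification"].to_numpy(dtype=float)
    if np.std(ident) < 1e-12 or np.std(bias) < 1e-12:
        return {"r": float("nan"), "p": float("nan"), "rho": float("nan"),
                "rho_p": float("nan"), "n": len(bias), "degenerate": True}
    r, p = stats.pearsonr(ident, bias)
    rho, rho_p = stats.spearmanr(ident, bias)
    return {"r": float(r), "p": float(p), "rho": float(rho), "rho_p": float(rho_p),
            "n": len(bias), "degenerate": False}
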