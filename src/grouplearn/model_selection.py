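"""Group-level model comparison.

Per-participant AIC values are converted to approximate log model evidence
(-AIC/2) and fed to random-effects Bayesian model selection: model
identity is treated as a random effect across participants, with a
Dirichlet prior (alpha0 = 1 per model) over the population frequencies of
the candidate models.  The variational scheme iterates

    u_nk  ∝  exp( lme_nk + psi(alpha_k) - psi(sum_j alpha_j) )
    alpha_k = alpha0 + sum_n u_nk

to convergence.  The *exceedance probability* (XP) of model k is the
posterior probability that its population frequency exceeds every other
model's, estimated by Monte-Carlo sampling from the posterior Dirichlet.
An XP above 0.95 is conventionally read as significant evidence that the
model is the most prevalent in the population.  A fixed-effects summary
(summed AIC) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp

from .fitting import FitResult

__all__ = ["ComparisonResult", "compare_models", "exceedance_probability"]


@dataclass
class ComparisonResult:
    aic_matrix: pd.DataFrame  # participants x models
    evidence_matrix: pd.DataFrame  # -AIC/2
    dirichlet_alpha: pd.Series
    expected_frequencies: pd.Series
    exceedance_probability: pd.Series
    summed_aic: pd.Series
    winner: str
    winner_resolved: bool
    n_draws: int

    @property
    def models(self) -> list[str]:
        return list(self.aic_matrix.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.models,
                "exceedance_probability": self.exceedance_probability.values,
                "expected_frequency": self.expected_frequencies.values,
                "dirichlet_alpha": self.dirichlet_alpha.values,
                "summed_aic": self.summed_aic.values,
            }
        )

    def summary(self) -> str:
        lines = [f"Random-effects model comparison over {len(self.aic_matrix)} participants"]
        for m in self.models:
            lines.append(
                f"  {m}: XP = {self.exceedance_probability[m]:.4f}, "
                f"E[freq] = {self.expected_frequencies[m]:.3f}, "
                f"summed AIC = {self.summed_aic[m]:.1f}"
            )
        tag = "" if self.winner_resolved else " (unresolved tie)"
        lines.append(f"  winner: {self.winner}{tag}")
        return "\n".join(lines)


def _vb_dirichlet(log_evidence: np.ndarray, alpha0: float = 1.0, tol: float = 1e-8, max_iter: int = 500):
    n, m = log_evidence.shape
    alpha = np.full(m, alpha0)
    for _ in range(max_iter):
        log_u = log_evidence + (digamma(alpha) - digamma(alpha.sum()))
        u = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha


def exceedance_probability(alpha: np.ndarray, n_draws: int = 1_000_000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo XP under a Dirichlet(alpha) posterior: the probability
    that each component is the largest."""
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_draws)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=len(alpha)) / n_draws


def compare_models(
    fits: list[FitResult] | pd.DataFrame,
    alpha0: float = 1.0,
    n_draws: int = 1_000_000,
    seed: int = 0,
    tie_margin: float = 0.01,
) -> ComparisonResult:
    """Random-effects Bayesian model selection from per-participant AICs.

    ``fits`` is either a flat list of FitResult (every participant must
    have one fit per model) or a participants x models AIC DataFrame.
    Only within-participant evidence differences matter: adding a constant
    to a participant's row leaves the result unchanged.
    """
    if isinstance(fits, pd.DataFrame):
        aic = fits.copy()
    else:
        df = pd.DataFrame(
            [{"participant": f.participant, "model": f.model, "aic": f.aic} for f in fits]
        )
        aic = df.pivot(index="participant", columns="model", values="aic")
    if aic.isna().any().any():
        missing = [
            f"{p}/{m}" for p, row in aic.iterrows() for m in aic.columns if pd.isna(row[m])
        ]
        raise ValueError(f"missing fits for: {', '.join(missing)}")

    evidence = -aic / 2.0
    # row-center for numerical stability (invariant to per-row constants)
    log_ev = evidence.values - evidence.values.mean(axis=1, keepdims=True)
    alpha = _vb_dirichlet(log_ev, alpha0=alpha0)
    xp = exceedance_probability(alpha, n_draws=n_draws, seed=seed)
    freq = alpha / alpha.sum()

    models = list(aic.columns)
    xp_s = pd.Series(xp, index=models)
    order = xp_s.sort_values(ascending=False)
    winner = str(order.index[0])
    resolved = bool(len(models) == 1 or order.iloc[0] - order.iloc[1] >= tie_margin)

    return ComparisonResult(
        aic_matrix=aic,
        evidence_matrix=evidence,
        dirichlet_alpha=pd.Series(alpha, index=models),
        expected_frequencies=pd.Series(freq, index=models),
        exceedance_probability=xp_s,
        summed_aic=aic.sum(axis=0),
        winner=winner,
        winner_resolved=resolved,
        n_draws=n_draws,
    )
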