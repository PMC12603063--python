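"""Prediction-error-driven closeness dynamics (Closeness Models 1-2).

The trial-wise *change* in rated closeness toward group i is modeled as a
linear function of the exponentially discounted sum of past prediction
errors generated by that group:

    C1:  dCloseness_i(t) = W0 + W   * sum_{j<=t} gamma^(t-j) delta_i(j)
    C2:  dCloseness_i(t) = W0 + Wpos * S_pos(i,t) + Wneg * S_neg(i,t)

where S_pos/S_neg accumulate only the positive/negative parts of the
prediction errors.  On trials where group i is not the partner, its series
receives an additional prediction error of zero — the existing sums keep
decaying by gamma (the discount clock runs in absolute trial time), but the
other group's outcome never leaks in.

gamma in [0, 1] sets the memory horizon: gamma = 1 weighs all past errors
equally, gamma = 0 leaves only the current trial's error.  Weights W are
bounded in [-10, 10] (10 is the ceiling of the closeness scale) and the
intercept W0 in [0, 10].

Observed changes are rating(t+1) - rating(t) on the 0-10 closeness scale:
closeness is rated at the start of each trial, so the change predicted by
trial t's discounted sums is only observable on the next trial, and the
final trial's prediction has no observable counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import discounted_sums
from .learning_models import LatentTrajectory

MODEL_VARIANTS = ("C1", "C2")

#: free structural parameters per variant (per group series)
N_PARAMS = {"C1": 3, "C2": 4}

__all__ = [
    "ClosenessParams",
    "ClosenessTrajectory",
    "discounted_pe_sum",
    "predict_closeness_change",
    "observed_closeness_change",
    "MODEL_VARIANTS",
    "N_PARAMS",
]


@dataclass
class ClosenessParams:
    """Weights of one group's closeness-update model.

    C1 uses a single weight on the signed discounted sum; express it by
    tying ``w_pos == w_neg``.
    """

    w0: float
    w_pos: float
    w_neg: float
    gamma: float

    def validate(self) -> None:
        if not 0 <= self.w0 <= 10:
            raise ValueError("W0 must lie in [0, 10]")
        for w in (self.w_pos, self.w_neg):
            if not -10 <= w <= 10:
                raise ValueError("weights must lie in [-10, 10]")
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must lie in [0, 1]")

    @classmethod
    def from_vector(cls, x: np.ndarray, model_variant: str) -> "ClosenessParams":
        if model_variant == "C1":
            w0, w, gamma = x
            return cls(w0, w, w, gamma)
        if model_variant == "C2":
            w0, w_pos, w_neg, gamma = x
            return cls(w0, w_pos, w_neg, gamma)
        raise ValueError(f"unknown model variant {model_variant!r}")


@dataclass
class ClosenessTrajectory:
    """Per-trial predicted closeness changes for one group."""

    group: str
    predicted_delta: np.ndarray
    s_pos: np.ndarray
    s_neg: np.ndarray
    s_all: np.ndarray
    params: ClosenessParams | None = None

    def to_frame(self, participant: str = "sim", observed: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "participant": participant,
                "trial": np.arange(1, len(self.predicted_delta) + 1),
                "group": self.group,
                "predicted_delta": self.predicted_delta,
            }
        )
        if observed is not None:
            obs = np.asarray(observed, dtype=float)
            padded = np.full(len(df), np.nan)
            padded[: len(obs)] = obs
            df["observed_delta"] = padded
        return df


def discounted_pe_sum(
    pe_series: np.ndarray,
    gamma: float,
    valence: str = "all",
    t: int | None = None,
) -> float | np.ndarray:
    """Discounted sum of prediction errors of one valence up to trial ``t``.

    ``pe_series`` is aligned to the schedule, with zeros on the group's
    inactive trials (those zeros still advance the discount clock).
    ``valence`` selects the positive part (max(delta, 0)), the negative
    part (min(delta, 0)) or the signed errors.  ``t`` is a 0-based trial
    index; omit it to get the whole running series.
    """
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must lie in [0, 1]")
    pe = np.ascontiguousarray(pe_series, dtype=np.float64)
    s_all, s_pos, s_neg = discounted_sums(pe, float(gamma))
    series = {"all": s_all, "positive": s_pos, "negative": s_neg}[valence]
    if t is None:
        return series
    return float(series[t])


def predict_closeness_change(
    trajectory: LatentTrajectory,
    params: ClosenessParams,
    model_variant: str = "C2",
    group: str = "ingroup",
) -> ClosenessTrajectory:
    """Predicted per-trial closeness change for one group under C1 or C2.

    C1 requires tied weights (``w_pos == w_neg``); the prediction errors
    are taken from ``trajectory`` (fitted pipelines pass the trajectory of
    the winning learning model).
    """
    if model_variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {model_variant!r}")
    params.validate()
    if model_variant == "C1" and params.w_pos != params.w_neg:
        raise ValueError("C1 requires a single weight (tie w_pos and w_neg)")

    pe = np.ascontiguousarray(trajectory.pe_series(group), dtype=np.float64)
    s_all, s_pos, s_neg = discounted_sums(pe, float(params.gamma))
    if model_variant == "C1":
        pred = params.w0 + params.w_pos * s_all
    else:
        pred = params.w0 + params.w_pos * s_pos + params.w_neg * s_neg
    return ClosenessTrajectory(
        group=group,
        predicted_delta=pred,
        s_pos=s_pos,
        s_neg=s_neg,
        s_all=s_all,
        params=params,
    )


def observed_closeness_change(ratings: np.ndarray) -> np.ndarray:
    """rating(t+1) - rating(t); one element shorter than the rating series.

    Element t is the change realized after trial t's outcome, i.e. the
    observable counterpart of the model's prediction at trial t; the final
    trial's prediction is dropped from residuals for lack of a successor.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 1 or len(r) < 2:
        raise ValueError("need a 1-D rating series of length >= 2")
    return np.diff(r)
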