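"""Rescorla-Wagner learning of outcome expectancies (Learning Models 1-3).

Each partner group i (ingroup/outgroup) carries a value V_i(t), the
expected probability of a positive outcome.  On a trial with partner i the
prediction error is

    delta_i(t) = R(t) - V_i(t),        R(t) in {0, 1}

and the value is updated with a learning rate alpha in [0, 1]:

    V_i(t+1) = V_i(t) + alpha * delta_i(t).

The model's predicted expectancy rating on trial t is beta * V_i(t),
computed *before* the update, with a single response-scaling parameter
beta > 0.  The three variants differ only in how many distinct learning
rates they allow:

* M1 — one alpha shared by both groups and both error valences;
* M2 — one alpha per group (ingroup vs outgroup);
* M3 — one alpha per group x valence cell (positive vs negative delta),
  four in total.

Initial values V_i(0) are not free parameters: they are set to the
participant's first observed (normalized) expectancy rating for each group,
so each group's first trial serves as the prior rather than as data and is
excluded from fitted residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import rw_forward
from .task_design import TrialSchedule

MODEL_VARIANTS = ("M1", "M2", "M3")

#: free structural parameters per variant (alphas + beta)
N_PARAMS = {"M1": 2, "M2": 3, "M3": 5}

__all__ = [
    "LearningParams",
    "LatentTrajectory",
    "simulate_learning",
    "predict_expectancy",
    "MODEL_VARIANTS",
    "N_PARAMS",
]


@dataclass
class LearningParams:
    """Learning rates (one per group x valence cell), response scaling, and
    per-group initial values on the normalized [0, 1] expectancy scale.

    Tie cells to express the nested variants: M1 ties all four alphas,
    M2 ties the two valence cells within each group.
    """

    alpha_in_pos: float
    alpha_in_neg: float
    alpha_out_pos: float
    alpha_out_neg: float
    beta: float = 1.0
    v0_ingroup: float = 0.5
    v0_outgroup: float = 0.5

    @classmethod
    def from_vector(cls, x: np.ndarray, model_variant: str, v0_in: float, v0_out: float) -> "LearningParams":
        if model_variant == "M1":
            a, beta = x
            return cls(a, a, a, a, beta, v0_in, v0_out)
        if model_variant == "M2":
            a_in, a_out, beta = x
            return cls(a_in, a_in, a_out, a_out, beta, v0_in, v0_out)
        if model_variant == "M3":
            aip, ain, aop, aon, beta = x
            return cls(aip, ain, aop, aon, beta, v0_in, v0_out)
        raise ValueError(f"unknown model variant {model_variant!r}")

    @property
    def alphas(self) -> np.ndarray:
        return np.array([self.alpha_in_pos, self.alpha_in_neg, self.alpha_out_pos, self.alpha_out_neg])

    def validate(self) -> None:
        if np.any(self.alphas < 0) or np.any(self.alphas > 1):
            raise ValueError("learning rates must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        for v0 in (self.v0_ingroup, self.v0_outgroup):
            if not 0 <= v0 <= 1:
                raise ValueError("initial values must lie in [0, 1]")


@dataclass
class LatentTrajectory:
    """Forward-simulated latent state aligned to a schedule.

    ``values`` and ``prediction_errors`` refer to the *active* (partner)
    group on each trial; a group's value only changes on its own trials.
    """

    values: np.ndarray
    prediction_errors: np.ndarray
    predicted_ratings: np.ndarray
    group_sequence: np.ndarray = field(repr=False)
    outcome_sequence: np.ndarray = field(repr=False)
    params: LearningParams | None = None

    @property
    def is_ingroup(self) -> np.ndarray:
        return self.group_sequence == "ingroup"

    def pe_series(self, group: str) -> np.ndarray:
        """Prediction errors attributed to ``group``: delta on its own
        trials, zero elsewhere (the other group's outcomes carry no signal
        for this group)."""
        active = self.is_ingroup if group == "ingroup" else ~self.is_ingroup
        return np.where(active, self.prediction_errors, 0.0)

    def to_frame(self, participant: str = "sim") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": participant,
                "trial": np.arange(1, len(self.values) + 1),
                "group": self.group_sequence,
                "V": self.values,
                "delta": self.prediction_errors,
                "predicted_rating": self.predicted_ratings,
            }
        )


def simulate_learning(
    schedule: TrialSchedule,
    params: LearningParams,
    model_variant: str = "M3",
) -> LatentTrajectory:
    """Deterministic forward recursion of the RW model over a schedule.

    The variant only restricts which alpha cells may differ; passing
    untied cells with ``M1``/``M2`` raises, so a variant label always
    means what it claims.
    """
    if model_variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {model_variant!r}")
    params.validate()
    a = params.alphas
    if model_variant == "M1" and not np.all(a == a[0]):
        raise ValueError("M1 requires a single shared learning rate")
    if model_variant == "M2" and not (a[0] == a[1] and a[2] == a[3]):
        raise ValueError("M2 requires valence-tied learning rates within group")

    values, deltas = rw_forward(
        schedule.is_ingroup,
        schedule.outcome_sequence.astype(np.float64),
        params.v0_ingroup,
        params.v0_outgroup,
        params.alpha_in_pos,
        params.alpha_in_neg,
        params.alpha_out_pos,
        params.alpha_out_neg,
    )
    return LatentTrajectory(
        values=values,
        prediction_errors=deltas,
        predicted_ratings=params.beta * values,
        group_sequence=np.asarray(schedule.group_sequence),
        outcome_sequence=np.asarray(schedule.outcome_sequence),
        params=params,
    )


def predict_expectancy(trajectory: LatentTrajectory) -> np.ndarray:
    """Model-predicted expectancy ratings beta * V(t) on the normalized
    [0, 1] scale.  No clipping: the fit penalizes out-of-range predictions
    through the residuals."""
    return trajectory.predicted_ratings.copy()
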