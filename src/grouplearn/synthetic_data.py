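"""Synthetic study populations and sessions.

Generates complete datasets with the structure the downstream analyses
assume: agents with RW learning parameters and per-group closeness-update
parameters, trial-level expectancy and closeness ratings over a task
schedule, and per-participant ingroup-identification scores plus pre/post
impression ratings.

Two culture-like profiles are provided, parameterized from the study-scale
descriptives of a Western and an East Asian sample (identification
4.57 +/- 1.15 vs 5.75 +/- 0.91 on a 1-7 scale; ingroup impressions above
outgroup impressions on a 1-9 scale in both, more so in the East Asian
profile).  Initial ingroup bias (pre ingroup - outgroup impression) is
drawn correlated with identification (population r ~= 0.26).

The link from learning to impression change is *not* part of the fitted
model space; impressions are measured quantities.  So that linkage
analyses have recoverable structure, sessions adopt a transparent synthetic
convention: post-impressions equal pre-impressions plus a coupling times
the net change in closeness toward that group over the session, plus noise.
The coupling is active only in the loss frame and attenuates linearly with
ingroup identification — the sign pattern the moderation analysis probes.

Rating conventions: each group's *first* expectancy rating reports the
agent's initial value V(0) directly (it is the prior the fitting procedure
reads off, not data); later ratings are beta * V + Gaussian noise.
Closeness ratings integrate the agent's predicted per-trial changes plus
noise.  Clipping to scale bounds happens after noise; clipped trials are
retained, as in real rating data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .closeness_models import ClosenessParams, predict_closeness_change
from .learning_models import LearningParams, simulate_learning
from .task_design import INGROUP, OUTGROUP, TrialSchedule, make_schedule

__all__ = [
    "AgentProfile",
    "SessionData",
    "CULTURE_PROFILES",
    "sample_population",
    "generate_session",
    "generate_study",
    "trials_table",
    "participants_table",
]

#: Population-level descriptive targets per culture profile.
CULTURE_PROFILES = {
    "western": {
        "identification_mean": 4.57,
        "identification_sd": 1.15,
        "impression_in_mean": 5.99,
        "impression_out_mean": 5.68,
        "bias_identification_r": 0.26,
    },
    "east_asian": {
        "identification_mean": 5.75,
        "identification_sd": 0.91,
        "impression_in_mean": 6.69,
        "impression_out_mean": 5.04,
        "bias_identification_r": 0.25,
    },
}

# Generative coupling from learning to impression change (loss frame
# only), attenuated with identification; a synthetic convention, not an
# estimated quantity.  Impressions respond to w_neg times the mean
# discounted negative-PE sum at a fixed reference horizon (gamma = 0.5),
# so the weight on negative prediction errors — not the more frequent
# positive ones — carries the planted association.
_COUPLING_LOSS = 2.0
_COUPLING_GAIN = 0.0
_COUPLING_REF_GAMMA = 0.5
_IMPRESSION_NOISE_SD = 0.3


@dataclass
class AgentProfile:
    participant: str
    frame: str  # "gain" or "loss"
    learning: LearningParams
    closeness_in: ClosenessParams
    closeness_out: ClosenessParams
    identification: float
    impression_pre_in: float
    impression_pre_out: float
    noise_sd_expectancy: float = 0.15
    noise_sd_closeness: float = 1.0


@dataclass
class SessionData:
    """One participant's ratings aligned to a schedule."""

    participant: str
    frame: str
    schedule: TrialSchedule
    expectancy: np.ndarray
    closeness_in: np.ndarray
    closeness_out: np.ndarray
    impression_pre_in: float
    impression_pre_out: float
    impression_post_in: float
    impression_post_out: float
    identification: float
    profile: AgentProfile | None = field(default=None, repr=False)

    def closeness(self, group: str) -> np.ndarray:
        return self.closeness_in if group == INGROUP else self.closeness_out

    @property
    def intergroup_impression_change(self) -> float:
        """(ingroup - outgroup) after minus (ingroup - outgroup) before;
        negative values mean the initial ingroup bias shrank."""
        return (self.impression_post_in - self.impression_post_out) - (
            self.impression_pre_in - self.impression_pre_out
        )


def _draw_closeness_params(rng: np.random.Generator) -> ClosenessParams:
    return ClosenessParams(
        w0=rng.uniform(0.0, 1.0),
        w_pos=rng.uniform(-5.0, 5.0),
        w_neg=rng.uniform(-5.0, 5.0),
        gamma=rng.uniform(0.0, 1.0),
    )


def sample_population(
    n_agents: int,
    frame_split: float = 0.5,
    culture_profile: str = "western",
    seed: int = 0,
    custom: dict | None = None,
) -> list[AgentProfile]:
    """Draw agent profiles for one culture.

    ``frame_split`` is the proportion of agents assigned the gain frame.
    Learning/closeness parameters are drawn within the fitting bounds;
    identification and pre-impressions follow the culture profile's
    descriptives, with the initial ingroup bias correlated with
    identification.
    """
    if n_agents < 2:
        raise ValueError("need at least 2 agents")
    if culture_profile == "custom":
        if custom is None:
            raise ValueError("culture_profile='custom' requires a profile dict")
        prof = custom
    else:
        prof = CULTURE_PROFILES[culture_profile]

    rng = np.random.default_rng(seed)
    n_gain = int(round(frame_split * n_agents))
    frames = np.array(["gain"] * n_gain + ["loss"] * (n_agents - n_gain))
    rng.shuffle(frames)

    mu_id, sd_id = prof["identification_mean"], prof["identification_sd"]
    mu_bias = prof["impression_in_mean"] - prof["impression_out_mean"]
    r = prof["bias_identification_r"]
    sd_bias = 1.6  # spread of initial bias on the 1-9 impression scale
    base_mean = (prof["impression_in_mean"] + prof["impression_out_mean"]) / 2

    agents = []
    for i in range(n_agents):
        z_id = rng.standard_normal()
        identification = float(np.clip(mu_id + sd_id * z_id, 1.0, 7.0))
        bias = mu_bias + sd_bias * (r * z_id + np.sqrt(1 - r**2) * rng.standard_normal())
        base = base_mean + 0.8 * rng.standard_normal()
        imp_in = float(np.clip(base + bias / 2, 1.0, 9.0))
        imp_out = float(np.clip(base - bias / 2, 1.0, 9.0))

        learning = LearningParams(
            alpha_in_pos=rng.uniform(0.0, 1.0),
            alpha_in_neg=rng.uniform(0.0, 1.0),
            alpha_out_pos=rng.uniform(0.0, 1.0),
            alpha_out_neg=rng.uniform(0.0, 1.0),
            beta=rng.uniform(0.5, 1.5),
            v0_ingroup=rng.uniform(0.2, 0.9),
            v0_outgroup=rng.uniform(0.2, 0.9),
        )
        agents.append(
            AgentProfile(
                participant=f"{culture_profile[:2]}{i + 1:03d}",
                frame=str(frames[i]),
                learning=learning,
                closeness_in=_draw_closeness_params(rng),
                closeness_out=_draw_closeness_params(rng),
                identification=identification,
                impression_pre_in=imp_in,
                impression_pre_out=imp_out,
            )
        )
    return agents


def generate_session(
    profile: AgentProfile,
    schedule: TrialSchedule,
    seed: int = 0,
) -> SessionData:
    """Simulate one participant's ratings over a schedule."""
    rng = np.random.default_rng(seed)
    traj = simulate_learning(schedule, profile.learning, "M3")

    # expectancy: first rating per group reports V(0); later beta*V + noise
    n = schedule.n_trials
    expectancy = profile.learning.beta * traj.values + rng.normal(
        0.0, profile.noise_sd_expectancy, n
    )
    is_in = schedule.is_ingroup
    first_in = int(np.argmax(is_in))
    first_out = int(np.argmax(~is_in))
    expectancy[first_in] = profile.learning.v0_ingroup
    expectancy[first_out] = profile.learning.v0_outgroup
    expectancy = np.clip(expectancy, 0.0, 1.0)

    closeness = {}
    neg_drive = {}
    for group, cparams, start in (
        (INGROUP, profile.closeness_in, profile.impression_pre_in),
        (OUTGROUP, profile.closeness_out, profile.impression_pre_out),
    ):
        ct = predict_closeness_change(traj, cparams, "C2", group)
        pred = ct.predicted_delta
        ratings = np.empty(n)
        # starting closeness anchored to the pre-impression (1-9 -> 0-10)
        ratings[0] = np.clip(start * 10.0 / 9.0 + rng.normal(0.0, 0.5), 0.0, 10.0)
        for t in range(n - 1):
            step = pred[t] + rng.normal(0.0, profile.noise_sd_closeness)
            ratings[t + 1] = np.clip(ratings[t] + step, 0.0, 10.0)
        closeness[group] = ratings
        # negative-PE drive at the reference horizon: proportional to the
        # agent's weight on negative PEs from this group
        from .closeness_models import discounted_pe_sum

        s_neg_ref = discounted_pe_sum(traj.pe_series(group), _COUPLING_REF_GAMMA, "negative")
        neg_drive[group] = float(cparams.w_neg * s_neg_ref[: n - 1].mean())

    coupling_frame = _COUPLING_LOSS if profile.frame == "loss" else _COUPLING_GAIN
    attenuation = float(np.clip((7.0 - profile.identification) / 3.0, 0.0, 1.5))
    coupling = coupling_frame * attenuation
    post = {}
    for group, pre in ((INGROUP, profile.impression_pre_in), (OUTGROUP, profile.impression_pre_out)):
        post[group] = float(
            np.clip(
                pre + coupling * neg_drive[group] + rng.normal(0.0, _IMPRESSION_NOISE_SD),
                1.0,
                9.0,
            )
        )

    return SessionData(
        participant=profile.participant,
        frame=profile.frame,
        schedule=schedule,
        expectancy=expectancy,
        closeness_in=closeness[INGROUP],
        closeness_out=closeness[OUTGROUP],
        impression_pre_in=profile.impression_pre_in,
        impression_pre_out=profile.impression_pre_out,
        impression_post_in=post[INGROUP],
        impression_post_out=post[OUTGROUP],
        identification=profile.identification,
        profile=profile,
    )


def generate_study(
    n_agents: int = 112,
    frame_split: float = 0.52,
    culture_profile: str = "western",
    seed: int = 0,
    n_blocks: int = 4,
    block_length: int = 24,
) -> list[SessionData]:
    """Sample a population and simulate every agent's session.

    Every agent in a frame sees the same outcome schedule (the feedback
    sequence was computer-generated and identical across participants);
    gain and loss schedules share the seed so only framing metadata
    differs.
    """
    ss = np.random.SeedSequence(seed)
    pop_seed, sched_seed, *agent_seeds = [
        int(s) for s in ss.generate_state(2 + n_agents, dtype=np.uint32) % (2**31)
    ]
    agents = sample_population(n_agents, frame_split, culture_profile, pop_seed)
    from .task_design import frame_by_label

    schedules = {
        label: make_schedule(n_blocks, block_length, 0.75, sched_seed, frame_by_label(label))
        for label in ("gain", "loss")
    }
    return [
        generate_session(agent, schedules[agent.frame], s)
        for agent, s in zip(agents, agent_seeds)
    ]


def trials_table(sessions: list[SessionData]) -> pd.DataFrame:
    """Package-standard long-format trials table (1-based ``trial``)."""
    rows = []
    for s in sessions:
        df = s.schedule.to_frame(s.participant, s.frame)
        df["expectancy"] = s.expectancy
        df["closeness_in"] = s.closeness_in
        df["closeness_out"] = s.closeness_out
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def participants_table(sessions: list[SessionData]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": [s.participant for s in sessions],
            "frame": [s.frame for s in sessions],
            "identification": [s.identification for s in sessions],
            "impression_pre_in": [s.impression_pre_in for s in sessions],
            "impression_pre_out": [s.impression_pre_out for s in sessions],
            "impression_post_in": [s.impression_post_in for s in sessions],
            "impression_post_out": [s.impression_post_out for s in sessions],
            "intergroup_impression_change": [
                s.intergroup_impression_change for s in sessions
            ],
        }
    )
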