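"""Trial schedules for the intergroup learning task.

A session consists of ``n_blocks`` blocks of ``block_length`` trials
(default 4 x 24 = 96).  On each trial a partner from the participant's
ingroup or outgroup delivers a binary outcome: positive (R = 1) or negative
(R = 0).  Outcomes are experimenter-controlled: positive events occur at a
fixed rate (default 75%) and are equalized across the two partner groups, so
that objective experience with ingroup and outgroup members is identical.

Two presentation frames exist with identical net payoffs: in the *gain*
frame the partner gives 5 or 0 monetary units (MU) on top of a 0 MU
endowment; in the *loss* frame the partner takes 5 or 10 MU from a 10 MU
endowment.  Either way a positive trial ends at 5 MU and a negative trial
at 0 MU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

INGROUP = "ingroup"
OUTGROUP = "outgroup"

__all__ = [
    "FrameSpec",
    "TrialSchedule",
    "GAIN_FRAME",
    "LOSS_FRAME",
    "frame_by_label",
    "make_schedule",
    "payoff",
    "schedule_from_config",
    "INGROUP",
    "OUTGROUP",
]


@dataclass(frozen=True)
class FrameSpec:
    """Payoff framing of the task.

    Parameters
    ----------
    frame_label:
        Either ``"gain"`` or ``"loss"``.
    endowment:
        MU the participant holds before the partner acts.
    positive_transfer:
        MU given (gain) or taken (loss) on a positive trial.
    negative_transfer:
        MU given (gain) or taken (loss) on a negative trial.
    """

    frame_label: str
    endowment: int
    positive_transfer: int
    negative_transfer: int

    def __post_init__(self) -> None:
        if self.frame_label not in ("gain", "loss"):
            raise ValueError(f"unknown frame label {self.frame_label!r}")


#: Partner gives 5 MU (positive) or 0 MU (negative) on a 0 MU endowment.
GAIN_FRAME = FrameSpec("gain", endowment=0, positive_transfer=5, negative_transfer=0)
#: Partner takes 5 MU (positive) or all 10 MU (negative) from a 10 MU endowment.
LOSS_FRAME = FrameSpec("loss", endowment=10, positive_transfer=5, negative_transfer=10)


def frame_by_label(label: str) -> FrameSpec:
    return {"gain": GAIN_FRAME, "loss": LOSS_FRAME}[label]


def payoff(frame: FrameSpec, outcome: int) -> int:
    """Final MU after the partner's decision.

    Gain frame: the partner gives ``positive_transfer`` (outcome 1) or
    ``negative_transfer`` (outcome 0).  Loss frame: the partner takes that
    amount from the endowment.  The two frames end at the same payoff for
    each outcome (5 MU positive, 0 MU negative at the default specs).
    """
    if outcome not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {outcome!r}")
    transfer = frame.positive_transfer if outcome == 1 else frame.negative_transfer
    if frame.frame_label == "gain":
        return frame.endowment + transfer
    return frame.endowment - transfer


@dataclass
class TrialSchedule:
    """Experimenter-controlled sequence of partner groups and outcomes."""

    n_trials: int
    n_blocks: int
    group_sequence: np.ndarray  # str array of INGROUP/OUTGROUP
    outcome_sequence: np.ndarray  # int array of 0/1
    frame: FrameSpec = field(default=GAIN_FRAME)
    positive_rate: float = 0.75
    seed: int | None = None

    def __post_init__(self) -> None:
        self.group_sequence = np.asarray(self.group_sequence)
        self.outcome_sequence = np.asarray(self.outcome_sequence, dtype=int)
        if len(self.group_sequence) != self.n_trials:
            raise ValueError("group_sequence length does not match n_trials")
        if len(self.outcome_sequence) != self.n_trials:
            raise ValueError("outcome_sequence length does not match n_trials")

    @property
    def block_length(self) -> int:
        return self.n_trials // self.n_blocks

    @property
    def is_ingroup(self) -> np.ndarray:
        return self.group_sequence == INGROUP

    def to_frame(self, participant: str = "sim", frame_label: str | None = None) -> pd.DataFrame:
        """Long-format table, one row per trial (1-based ``trial`` column)."""
        return pd.DataFrame(
            {
                "participant": participant,
                "frame": frame_label or self.frame.frame_label,
                "block": np.repeat(np.arange(1, self.n_blocks + 1), self.block_length),
                "trial": np.arange(1, self.n_trials + 1),
                "group": self.group_sequence,
                "outcome": self.outcome_sequence,
            }
        )


def _balanced_binary(n: int, n_ones: int, rng: np.random.Generator) -> np.ndarray:
    seq = np.zeros(n, dtype=int)
    seq[:n_ones] = 1
    rng.shuffle(seq)
    return seq


def make_schedule(
    n_blocks: int = 4,
    block_length: int = 24,
    positive_rate: float = 0.75,
    seed: int = 0,
    frame: FrameSpec = GAIN_FRAME,
) -> TrialSchedule:
    """Generate a pseudo-random schedule with exact counts.

    Group identity is balanced within each block (half ingroup, half
    outgroup, permuted); outcomes hit ``positive_rate`` exactly within each
    group over the whole session, in permuted order.  The same seed always
    yields the same schedule.

    Raises
    ------
    ValueError
        If the block length is odd (no equal group split) or
        ``positive_rate`` times the per-group trial count is not an integer.
    """
    if not 0 < positive_rate <= 1:
        raise ValueError("positive_rate must be in (0, 1]")
    if block_length % 2 != 0:
        raise ValueError("block_length must be even for an equal group split")
    n_trials = n_blocks * block_length
    per_group = n_trials // 2
    n_pos_f = positive_rate * per_group
    if abs(n_pos_f - round(n_pos_f)) > 1e-9:
        raise ValueError(
            f"positive_rate {positive_rate} x {per_group} trials per group "
            "is not an integer; choose a compatible rate"
        )
    n_pos = round(n_pos_f)

    rng = np.random.default_rng(seed)
    half = block_length // 2
    blocks = [_balanced_binary(block_length, half, rng) for _ in range(n_blocks)]
    is_in = np.concatenate(blocks).astype(bool)

    outcomes = np.empty(n_trials, dtype=int)
    outcomes[is_in] = _balanced_binary(per_group, n_pos, rng)
    outcomes[~is_in] = _balanced_binary(per_group, n_pos, rng)

    groups = np.where(is_in, INGROUP, OUTGROUP)
    return TrialSchedule(
        n_trials=n_trials,
        n_blocks=n_blocks,
        group_sequence=groups,
        outcome_sequence=outcomes,
        frame=frame,
        positive_rate=positive_rate,
        seed=seed,
    )


def schedule_from_config(path: str) -> TrialSchedule:
    """Build a schedule from a YAML/JSON config with keys
    n_blocks, block_length, positive_rate, seed, and optional frame."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    frame = frame_by_label(cfg.get("frame", "gain"))
    return make_schedule(
        n_blocks=int(cfg.get("n_blocks", 4)),
        block_length=int(cfg.get("block_length", 24)),
        positive_rate=float(cfg.get("positive_rate", 0.75)),
        seed=int(cfg.get("seed", 0)),
        frame=frame,
    )
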