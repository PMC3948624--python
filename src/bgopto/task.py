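"""Two-choice block-reversal bandit task and the five-step trial loop.

One of two task actions ("left"/"right") is rewarded at a time: the rewarded
side pays ``p_reward`` (default 0.75) and the other side never pays.  The
rewarded side alternates at the end of every block (default 20 trials of the
analysed, *recorded* state).  Each trial runs the fixed loop: activate one
state unit, select an action by softmax over the net D1-D2 activations,
read the reward prediction for the chosen pairing, draw the outcome, and apply
the RPE-gated plasticity update — with stimulation injected at exactly the
points the stimulation module defines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import model as md
from . import stimulation as st

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "SessionResult",
    "next_state",
    "reward_for",
    "run_trial",
    "run_session",
    "records_to_frame",
    "write_records_csv",
    "read_records_csv",
]

CSV_COLUMNS = [
    "trial", "block", "pos", "state", "stim", "action",
    "pred", "rpe", "reward", "side", "dw_d1", "aL", "aR",
]


@dataclass(frozen=True)
class TaskConfig:
    """Structure and contingencies of the block-reversal session.

    The network has ``n_states`` cortical states and ``n_actions`` action
    units, of which only ``left_action`` and ``right_action`` are selectable.
    All states share the block's contingency, but analyses use only trials of
    ``recorded_state``.  ``block_counting`` decides whether ``block_length``
    counts recorded-state trials (default, matching a single-context task) or
    all trials.
    """

    n_states: int = 5
    n_actions: int = 4
    left_action: int = 0
    right_action: int = 1
    recorded_state: int = 0
    block_length: int = 20
    p_reward: float = 0.75
    n_blocks: int = 200
    block_counting: str = "recorded"  # or "total"
    first_rewarded_side: str = "left"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.left_action == self.right_action:
            raise ValueError("left_action and right_action must differ")
        if not (0 <= self.left_action < self.n_actions and 0 <= self.right_action < self.n_actions):
            raise ValueError("task actions must be valid action indices")
        if not (0 < self.p_reward <= 1):
            raise ValueError("p_reward must be in (0, 1]")
        if not (0 <= self.recorded_state < self.n_states):
            raise ValueError("recorded_state out of range")
        if self.block_counting not in ("recorded", "total"):
            raise ValueError("block_counting must be 'recorded' or 'total'")
        if self.first_rewarded_side not in ("left", "right"):
            raise ValueError("first_rewarded_side must be 'left' or 'right'")

    @property
    def eligible_actions(self) -> tuple[int, int]:
        return (self.left_action, self.right_action)


@dataclass
class TrialRecord:
    """Everything observed on one trial (bookkeeping fields set by the session)."""

    trial_idx: int
    block_idx: int
    position_in_block: int
    state_idx: int
    a_pre_stim: np.ndarray          # net activations before any injection
    stimulated: bool
    selected_action: int
    predicted_reward: float         # unbiased Critic prediction
    rpe: float                      # the RPE actually used (biased if RP stimulated)
    reward: float
    rewarded_side: int
    dw_d1_selected: float           # D1 weight change of (state -> selected action)


@dataclass
class SessionResult:
    """Record stream of one session plus the final model state."""

    records: list[TrialRecord]
    model: md.ModelState
    config: TaskConfig

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records, self.config)


def next_state(tc: TaskConfig, rng: np.random.Generator) -> int:
    """Uniformly draw the active cortical state for this trial."""
    if tc.n_states == 1:
        return 0
    return int(rng.integers(tc.n_states))


def reward_for(
    tc: TaskConfig,
    rewarded_side: int,
    selected_action: int,
    rng: np.random.Generator,
    reward_magnitude: float = 1.0,
) -> float:
    """Outcome draw: the rewarded side pays with p_reward, the other never."""
    if selected_action != rewarded_side:
        return 0.0
    return reward_magnitude if rng.random() < tc.p_reward else 0.0


def run_trial(
    ms: md.ModelState,
    tc: TaskConfig,
    stim: st.StimulationSpec,
    lp: md.LearningParams,
    pp: md.PolicyParams,
    rng: np.random.Generator,
    rewarded_side: int,
    state_idx: int | None = None,
) -> TrialRecord:
    """Execute one trial in place; bookkeeping indices are filled by the caller.

    Steps: (1) activate one state unit; (2) compute net action activations,
    inject action-pathway stimulation if flagged, softmax-select among the
    eligible actions; (3) read the reward prediction for the chosen pairing
    and apply any RP bias; (4) draw the outcome; (5) compute the RPE and
    update all three pathways.  ``a_pre_stim`` is recorded before injection so
    stimulated and unstimulated trials can be compared at equal action values.
    """
    if state_idx is None:
        state_idx = next_state(tc, rng)

    a_pre = md.action_activation(ms, state_idx)
    flag = st.draw_stim_flag(stim, rng)
    a_sel = st.apply_to_action_values(a_pre, stim, flag, tc.left_action, tc.right_action)

    p = md.softmax_policy(a_sel, pp)
    action = pp.eligible_actions[md.select_action(p, rng)]

    pred = md.predict_reward(ms, state_idx, action)
    pred_biased = st.apply_to_rp(pred, stim, flag, action, tc.left_action, tc.right_action)

    reward = reward_for(tc, rewarded_side, action, rng, lp.reward_magnitude)
    delta = md.compute_rpe(pred_biased, reward)

    w_before = ms.w_d1[state_idx, action]
    md.update_actor(ms, lp, state_idx, action, delta, eligible=pp.eligible_actions)
    md.update_rp(ms, lp, state_idx, action, delta)

    return TrialRecord(
        trial_idx=-1,
        block_idx=-1,
        position_in_block=-1,
        state_idx=state_idx,
        a_pre_stim=a_pre,
        stimulated=flag,
        selected_action=action,
        predicted_reward=pred,
        rpe=delta,
        reward=reward,
        rewarded_side=rewarded_side,
        dw_d1_selected=float(ms.w_d1[state_idx, action] - w_before),
    )


def run_session(
    tc: TaskConfig,
    stim: st.StimulationSpec | None = None,
    lp: md.LearningParams | None = None,
    pp: md.PolicyParams | None = None,
    rng: np.random.Generator | None = None,
    ms: md.ModelState | None = None,
) -> SessionResult:
    """Run ``tc.n_blocks`` blocks, alternating the rewarded side at each boundary.

    Returns every trial's record (all states); analyses filter to the recorded
    state.  Deterministic given the RNG (or ``tc.seed``).
    """
    stim = st.StimulationSpec.none() if stim is None else stim
    lp = md.LearningParams() if lp is None else lp
    pp = PolicyParams_default(tc) if pp is None else pp
    if rng is None:
        rng = np.random.default_rng(tc.seed)
    if ms is None:
        ms = md.ModelState.initial(tc.n_states, tc.n_actions)

    sides = (tc.left_action, tc.right_action)
    side = sides[0] if tc.first_rewarded_side == "left" else sides[1]

    records: list[TrialRecord] = []
    block = 0
    pos = 0
    total = 0
    while block < tc.n_blocks:
        state = next_state(tc, rng)
        counts = (state == tc.recorded_state) if tc.block_counting == "recorded" else True
        if counts:
            pos += 1
        rec = run_trial(ms, tc, stim, lp, pp, rng, side, state_idx=state)
        rec.trial_idx = total
        rec.block_idx = block
        rec.position_in_block = pos
        records.append(rec)
        total += 1
        if counts and pos == tc.block_length:
            block += 1
            pos = 0
            side = sides[1] if side == sides[0] else sides[0]
    return SessionResult(records=records, model=ms, config=tc)


def PolicyParams_default(tc: TaskConfig) -> md.PolicyParams:
    """Softmax policy restricted to the task's two actions, default gain."""
    return md.PolicyParams(eligible_actions=tc.eligible_actions)


def records_to_frame(records: list[TrialRecord], tc: TaskConfig) -> pd.DataFrame:
    """Tabulate a record stream with the fixed column set (one row per trial)."""
    return pd.DataFrame(
        {
            "trial": [r.trial_idx for r in records],
            "block": [r.block_idx for r in records],
            "pos": [r.position_in_block for r in records],
            "state": [r.state_idx for r in records],
            "stim": [r.stimulated for r in records],
            "action": [r.selected_action for r in records],
            "pred": [r.predicted_reward for r in records],
            "rpe": [r.rpe for r in records],
            "reward": [r.reward for r in records],
            "side": [r.rewarded_side for r in records],
            "dw_d1": [r.dw_d1_selected for r in records],
            "aL": [r.a_pre_stim[tc.left_action] for r in records],
            "aR": [r.a_pre_stim[tc.right_action] for r in records],
        }
    )


def write_records_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, columns=CSV_COLUMNS)


def read_records_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
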