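"""Core actor-critic network: D1/D2 action pathways and the reward-prediction critic.

The network is an abstract basal-ganglia model.  Cortical *states* project to
*action* units through two plastic pathways: the direct (D1) pathway, whose
activity promotes an action, and the indirect (D2) pathway, whose activity is
subtracted and suppresses it.  A third pathway — the reward-prediction (RP)
system, the Critic — learns the expected reward of every state-action pairing.
The reward-prediction error (RPE, ``delta``) gates all plasticity as the third
factor of a three-factor rule.

Weights are Bayesian-confidence-propagation (BCPNN) log-probability ratios.
Each pathway maintains exponentially smoothed probability estimates of
pre-synaptic, post-synaptic and joint activity, and the weights and biases are
*derived* from those traces after every update::

    w_ij   = log( p_joint_ij / (p_pre_i * p_post_j) )
    beta_j = log( p_post_j )

so a weight estimates how much more likely action ``j`` is when state ``i`` is
active than its base rate, and the bias encodes the base rate itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PathwayTraces",
    "ModelState",
    "PolicyParams",
    "LearningParams",
    "pathway_input",
    "action_activation",
    "softmax_policy",
    "select_action",
    "predict_reward",
    "compute_rpe",
    "update_actor",
    "update_rp",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class PathwayTraces:
    """Probability-estimate traces of one pathway (all entries in ``[eps, 1]``)."""

    p_pre: np.ndarray   # (n_states,)   P(state i active)
    p_post: np.ndarray  # (n_actions,)  P(action j active)
    p_joint: np.ndarray  # (n_states, n_actions)  P(state i and action j co-active)

    def copy(self) -> "PathwayTraces":
        return PathwayTraces(self.p_pre.copy(), self.p_post.copy(), self.p_joint.copy())

    @classmethod
    def uniform(cls, n_states: int, n_actions: int) -> "PathwayTraces":
        """Independent uniform traces: all derived weights start at exactly 0."""
        p_pre = np.full(n_states, 1.0 / n_states)
        p_post = np.full(n_actions, 1.0 / n_actions)
        return cls(p_pre, p_post, np.outer(p_pre, p_post))


def _derive_weights(tr: PathwayTraces) -> tuple[np.ndarray, np.ndarray]:
    w = np.log(tr.p_joint / np.outer(tr.p_pre, tr.p_post))
    beta = np.log(tr.p_post)
    return w, beta


@dataclass
class ModelState:
    """All weights, biases, traces and reward predictions of the three pathways.

    ``w_d1``/``w_d2`` and ``beta_d1``/``beta_d2`` are derived from the traces and
    recomputed after every update; they never drift independently.  ``rp_pred``
    holds the Critic's expected reward for every state-action pairing (>= 0).
    """

    n_states: int
    n_actions: int
    traces_d1: PathwayTraces
    traces_d2: PathwayTraces
    w_d1: np.ndarray
    w_d2: np.ndarray
    beta_d1: np.ndarray
    beta_d2: np.ndarray
    rp_pred: np.ndarray

    @classmethod
    def initial(cls, n_states: int, n_actions: int) -> "ModelState":
        t1 = PathwayTraces.uniform(n_states, n_actions)
        t2 = PathwayTraces.uniform(n_states, n_actions)
        w1, b1 = _derive_weights(t1)
        w2, b2 = _derive_weights(t2)
        return cls(
            n_states=n_states,
            n_actions=n_actions,
            traces_d1=t1,
            traces_d2=t2,
            w_d1=w1,
            w_d2=w2,
            beta_d1=b1,
            beta_d2=b2,
            rp_pred=np.zeros((n_states, n_actions)),
        )

    def copy(self) -> "ModelState":
        t1, t2 = self.traces_d1.copy(), self.traces_d2.copy()
        return ModelState(
            self.n_states,
            self.n_actions,
            t1,
            t2,
            self.w_d1.copy(),
            self.w_d2.copy(),
            self.beta_d1.copy(),
            self.beta_d2.copy(),
            self.rp_pred.copy(),
        )

    # -- checkpointing ----------------------------------------------------

    def to_dict(self, rng: np.random.Generator | None = None) -> dict:
        d = {
            "n_states": self.n_states,
            "n_actions": self.n_actions,
            "w_d1": self.w_d1.tolist(),
            "w_d2": self.w_d2.tolist(),
            "beta_d1": self.beta_d1.tolist(),
            "beta_d2": self.beta_d2.tolist(),
            "rp_pred": self.rp_pred.tolist(),
            "traces": {
                "d1": {
                    "p_pre": self.traces_d1.p_pre.tolist(),
                    "p_post": self.traces_d1.p_post.tolist(),
                    "p_joint": self.traces_d1.p_joint.tolist(),
                },
                "d2": {
                    "p_pre": self.traces_d2.p_pre.tolist(),
                    "p_post": self.traces_d2.p_post.tolist(),
                    "p_joint": self.traces_d2.p_joint.tolist(),
                },
            },
            "rng_state": rng.bit_generator.state if rng is not None else None,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelState":
        def tr(sub: dict) -> PathwayTraces:
            return PathwayTraces(
                np.asarray(sub["p_pre"], dtype=float),
                np.asarray(sub["p_post"], dtype=float),
                np.asarray(sub["p_joint"], dtype=float),
            )

        return cls(
            n_states=int(d["n_states"]),
            n_actions=int(d["n_actions"]),
            traces_d1=tr(d["traces"]["d1"]),
            traces_d2=tr(d["traces"]["d2"]),
            w_d1=np.asarray(d["w_d1"], dtype=float),
            w_d2=np.asarray(d["w_d2"], dtype=float),
            beta_d1=np.asarray(d["beta_d1"], dtype=float),
            beta_d2=np.asarray(d["beta_d2"], dtype=float),
            rp_pred=np.asarray(d["rp_pred"], dtype=float),
        )


@dataclass
class PolicyParams:
    """Softmax selection parameters.

    ``gain`` is the softmax gain (inverse temperature); higher values make the
    transition from indifference to deterministic selection sharper.
    ``eligible_actions`` restricts selection to the task's actions — other
    action units exist and learn but are never selected.
    """

    gain: float = 2.0
    eligible_actions: tuple[int, ...] = (0, 1)

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("softmax gain must be > 0")
        if len(self.eligible_actions) == 0:
            raise ValueError("eligible_actions must be non-empty")


@dataclass
class LearningParams:
    """Plasticity parameters.

    ``alpha_actor`` is the trace smoothing rate of the D1/D2 pathways per unit
    of |RPE|; ``alpha_rp`` the (slower) rate of the reward-prediction pathway.
    ``epsilon`` floors the probability traces away from 0 so log-ratio weights
    stay finite.  ``reward_magnitude`` is the value of one delivered reward.
    """

    alpha_actor: float = 0.05
    alpha_rp: float = 0.01
    epsilon: float = 1e-4
    reward_magnitude: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha_rp < self.alpha_actor < 1):
            raise ValueError("require 0 < alpha_rp < alpha_actor < 1 (RP is the slow pathway)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _check_state(ms: ModelState, state_idx: int) -> None:
    if not (0 <= state_idx < ms.n_states):
        raise IndexError(f"state index {state_idx} out of range [0, {ms.n_states})")


def _check_action(ms: ModelState, action_idx: int) -> None:
    if not (0 <= action_idx < ms.n_actions):
        raise IndexError(f"action index {action_idx} out of range [0, {ms.n_actions})")


def pathway_input(ms: ModelState, pathway: str, state_idx: int) -> np.ndarray:
    """Activity each action unit receives from one pathway for a one-hot state.

    With the cortical input one-hot on ``state_idx``, the support an action unit
    ``j`` receives from pathway X is ``beta_j + w[state_idx, j]``.
    """
    _check_state(ms, state_idx)
    if pathway == "D1":
        return ms.beta_d1 + ms.w_d1[state_idx]
    if pathway == "D2":
        return ms.beta_d2 + ms.w_d2[state_idx]
    raise ValueError(f"unknown pathway {pathway!r} (expected 'D1' or 'D2')")


def action_activation(ms: ModelState, state_idx: int) -> np.ndarray:
    """Net action-layer activity: direct-pathway drive minus indirect-pathway drive."""
    return pathway_input(ms, "D1", state_idx) - pathway_input(ms, "D2", state_idx)


def softmax_policy(a: np.ndarray, pp: PolicyParams) -> np.ndarray:
    """Selection probabilities over ``pp.eligible_actions`` (stabilised softmax).

    Returns a vector aligned with ``pp.eligible_actions``; invariant to adding
    any constant to all activations.
    """
    a = np.asarray(a, dtype=float)
    elig = np.asarray(pp.eligible_actions, dtype=int)
    x = pp.gain * a[elig]
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


def select_action(p: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an index with the given probabilities (index into ``p``)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must be a probability vector summing to 1")
    # inverse-CDF draw: one uniform per trial keeps the stream cheap and reproducible
    return int(np.searchsorted(np.cumsum(p), rng.random(), side="right").clip(0, p.size - 1))


def predict_reward(ms: ModelState, state_idx: int, action_idx: int) -> float:
    """The Critic's expected reward for a state-action pairing (>= 0).

    Only one RP unit is active per trial — the one for the current state and
    the just-selected action — so the prediction is read after selection and
    before the outcome arrives.
    """
    _check_state(ms, state_idx)
    _check_action(ms, action_idx)
    return float(ms.rp_pred[state_idx, action_idx])


def compute_rpe(predicted: float, actual: float) -> float:
    """Reward-prediction error: actual reward minus predicted reward."""
    return float(actual) - float(predicted)


def update_actor(
    ms: ModelState,
    lp: LearningParams,
    state_idx: int,
    selected_action: int,
    delta: float,
    eligible: tuple[int, ...] | None = None,
) -> ModelState:
    """Three-factor update of the D1 and D2 pathway traces, gated by the RPE.

    ``|delta|`` scales the effective smoothing rate (``alpha_actor * |delta|``);
    the RPE's sign routes which post-units count as active:

    * ``delta > 0`` — D1 strengthens the co-active (state, selected) pairing;
      D2 treats the *non-selected* eligible actions as active (suppressing the
      alternatives).
    * ``delta < 0`` — the converse: D1 credits the non-selected alternatives,
      D2 the selected action.

    Traces are exponentially smoothed toward the pre/post activity pattern,
    floored at ``lp.epsilon``, and weights/biases are re-derived.  ``delta == 0``
    leaves the state untouched.  Mutates and returns ``ms``.
    """
    _check_state(ms, state_idx)
    _check_action(ms, selected_action)
    if not np.isfinite(delta):
        raise ValueError("RPE must be finite")
    if delta == 0.0:
        return ms

    a_eff = lp.alpha_actor * abs(delta)
    elig = np.asarray(
        range(ms.n_actions) if eligible is None else eligible, dtype=int
    )

    o = np.zeros(ms.n_states)
    o[state_idx] = 1.0
    y_d1 = np.zeros(ms.n_actions)
    y_d2 = np.zeros(ms.n_actions)
    if delta > 0:
        y_d1[selected_action] = 1.0
        y_d2[elig] = 1.0
        y_d2[selected_action] = 0.0
    else:
        y_d1[elig] = 1.0
        y_d1[selected_action] = 0.0
        y_d2[selected_action] = 1.0

    for tr, y in ((ms.traces_d1, y_d1), (ms.traces_d2, y_d2)):
        tr.p_pre[:] = np.clip((1 - a_eff) * tr.p_pre + a_eff * o, lp.epsilon, 1.0)
        tr.p_post[:] = np.clip((1 - a_eff) * tr.p_post + a_eff * y, lp.epsilon, 1.0)
        tr.p_joint[:] = np.clip(
            (1 - a_eff) * tr.p_joint + a_eff * np.outer(o, y), lp.epsilon, 1.0
        )

    ms.w_d1, ms.beta_d1 = _derive_weights(ms.traces_d1)
    ms.w_d2, ms.beta_d2 = _derive_weights(ms.traces_d2)
    return ms


def update_rp(
    ms: ModelState,
    lp: LearningParams,
    state_idx: int,
    selected_action: int,
    delta: float,
) -> ModelState:
    """Delta-rule update of the reward prediction for the visited pairing only.

    Uses the slow rate ``alpha_rp``; the prediction is clamped at 0 from below.
    Mutates and returns ``ms``.
    """
    _check_state(ms, state_idx)
    _check_action(ms, selected_action)
    new = ms.rp_pred[state_idx, selected_action] + lp.alpha_rp * delta
    ms.rp_pred[state_idx, selected_action] = max(0.0, new)
    return ms


def save_checkpoint(
    ms: ModelState, path: str | Path, rng: np.random.Generator | None = None
) -> None:
    """Serialise a ModelState (and optionally the session RNG state) to JSON."""
    Path(path).write_text(json.dumps(ms.to_dict(rng=rng)))


def load_checkpoint(path: str | Path) -> tuple[ModelState, dict | None]:
    """Load a checkpoint; returns the state and the stored RNG state (or None)."""
    d = json.loads(Path(path).read_text())
    return ModelState.from_dict(d), d.get("rng_state")
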