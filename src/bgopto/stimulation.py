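"""Phasic stimulation of D1/D2 action units and of the reward prediction.

Emulates optogenetic activation of channelrhodopsin-expressing medium spiny
neurons: on a stimulated trial, extra activation is injected into the unit
coding one action in one pathway just before action selection, and/or into the
reward prediction between selection and the RPE computation.  The injection is
transient — stored weights and predictions are never modified directly, so a
stimulated trial can only differ from its unstimulated counterfactual through
the learning update it triggers.

Site naming follows the hemisphere convention of the unilateral-stimulation
experiment it models: the letter is the stimulated hemisphere and the targeted
action is *contralateral*.  ``D1L`` therefore excites the D1 unit of action
"right", ``D2R`` the D2 unit of action "left", and so on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SITES",
    "RP_MODES",
    "StimulationSpec",
    "target_action",
    "draw_stim_flag",
    "apply_to_action_values",
    "apply_to_rp",
]

SITES = ("NONE", "D1L", "D1R", "D2L", "D2R", "RP_ONLY")
RP_MODES = ("none", "action_dependent", "action_independent")

# site -> (pathway, contralateral side of the targeted action)
_SITE_MAP = {
    "D1L": ("D1", "right"),
    "D1R": ("D1", "left"),
    "D2L": ("D2", "right"),
    "D2R": ("D2", "left"),
}


@dataclass(frozen=True)
class StimulationSpec:
    """Where, how strongly, how often and in which mode activation is injected.

    ``rp_mode`` controls whether the reward prediction is co-biased:
    ``action_dependent`` biases it only when the selected action is the one the
    stimulation targets; ``action_independent`` biases it on every flagged
    trial.  For ``site="RP_ONLY"`` the action pathways are untouched and
    ``rp_target_action`` names the action whose prediction is inflated in the
    action-dependent mode.
    """

    site: str = "NONE"
    intensity: float = 0.0
    probability: float = 0.0
    rp_mode: str = "none"
    rp_target_action: int | None = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.rp_mode not in RP_MODES:
            raise ValueError(f"unknown rp_mode {self.rp_mode!r}; expected one of {RP_MODES}")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must be in [0, 1]")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.site == "RP_ONLY":
            if self.rp_mode == "none":
                raise ValueError("RP_ONLY stimulation requires an rp_mode")
            if self.rp_mode == "action_dependent" and self.rp_target_action is None:
                raise ValueError("action_dependent RP_ONLY needs rp_target_action")

    @classmethod
    def none(cls) -> "StimulationSpec":
        return cls()


def target_action(spec: StimulationSpec, left_action: int, right_action: int) -> int | None:
    """Global index of the action a site targets (contralateral map), or None."""
    if spec.site == "RP_ONLY":
        return spec.rp_target_action
    if spec.site == "NONE":
        return None
    _, side = _SITE_MAP[spec.site]
    return right_action if side == "right" else left_action


def draw_stim_flag(spec: StimulationSpec, rng: np.random.Generator) -> bool:
    """Whether this trial is stimulated (Bernoulli with spec.probability)."""
    if spec.site == "NONE" or spec.probability == 0.0:
        return False
    return bool(rng.random() < spec.probability)


def apply_to_action_values(
    a: np.ndarray,
    spec: StimulationSpec,
    flag: bool,
    left_action: int,
    right_action: int,
) -> np.ndarray:
    """Inject activation into the net action values just before selection.

    D1 sites raise the targeted action's net activation by ``intensity``;
    D2 sites lower it (their drive is inhibitory).  Returns a new vector; the
    input — and the stored weights — are untouched.  No-op when the flag is
    down or the site does not touch the action pathways.
    """
    a = np.asarray(a, dtype=float)
    if not flag or spec.site in ("NONE", "RP_ONLY"):
        return a.copy()
    pathway, _ = _SITE_MAP[spec.site]
    tgt = target_action(spec, left_action, right_action)
    out = a.copy()
    out[tgt] += spec.intensity if pathway == "D1" else -spec.intensity
    return out


def apply_to_rp(
    predicted: float,
    spec: StimulationSpec,
    flag: bool,
    selected_action: int,
    left_action: int,
    right_action: int,
) -> float:
    """Bias the reward prediction between selection and the RPE computation.

    D1-linked stimulation inflates the prediction by ``intensity`` (the RP
    units are inhibited more); D2-linked stimulation deflates it, floored at
    zero.  The bias applies only when the flag is up and the ``rp_mode``
    condition on the selected action holds.
    """
    if not flag or spec.site == "NONE" or spec.rp_mode == "none":
        return float(predicted)
    if spec.rp_mode == "action_dependent":
        if selected_action != target_action(spec, left_action, right_action):
            return float(predicted)
    if spec.site == "RP_ONLY" or spec.site.startswith("D1"):
        return float(predicted) + spec.intensity
    return max(0.0, float(predicted) - spec.intensity)
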