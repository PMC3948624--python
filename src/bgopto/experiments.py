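"""Reproducible presets for the four in-model stimulation experiments.

Each preset bundles a task configuration and a set of stimulation conditions:

* ``fig1_intensity_sweep`` — validation runs on the two-action network:
  contralateral D1 stimulation at 6% of trials for each intensity in
  {0.15, 0.5, 2.0}; analysed as value-binned selection curves with sigmoid fits.
* ``fig2_history`` — the full network, D1L or D2L at intensity 0.5, 6% of
  trials, with and without the action-dependent co-bias of the reward
  prediction; analysed per two-back reward-history case with cross-run t-tests
  of stimulated vs unstimulated trials.
* ``fig3_rp_only`` — reward-prediction-only bias (+0.5) on the two-action
  network at 6% and 94% of trials, action-dependent (target "right") and
  action-independent, against matched no-stimulation runs.
* ``fig4_weight_change`` — RPE biased (+0.5) on 15% of trials over 5000 blocks;
  analysed as early/late-block D1 weight-change cells with a factorial ANOVA.

``run_experiment`` executes a preset end to end and writes CSV/JSON outputs
plus a manifest sufficient to reproduce the bundle.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import analysis as an
from .model import LearningParams, PolicyParams
from .stimulation import StimulationSpec
from .task import TaskConfig, run_session, write_records_csv

__all__ = [
    "Condition",
    "ExperimentPreset",
    "PRESET_NAMES",
    "get_preset",
    "validate_config",
    "spawn_seeds",
    "run_preset_sessions",
    "analyze_preset",
    "run_experiment",
]

PRESET_NAMES = (
    "fig1_intensity_sweep",
    "fig2_history",
    "fig3_rp_only",
    "fig4_weight_change",
)

STIM_INTENSITY = 0.5       # the intensity shared by the history/RP/weight experiments
SWEEP_INTENSITIES = (0.15, 0.5, 2.0)
STIM_PROBABILITY = 0.06
RP_HIGH_PROBABILITY = 0.94
RPE_BIAS_PROBABILITY = 0.15
N_RUNS = 20                # simulations per condition for the cross-run t-tests


@dataclass(frozen=True)
class Condition:
    """One stimulation condition of a preset."""

    label: str
    stim: StimulationSpec
    n_runs: int = 1


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    task: TaskConfig
    conditions: tuple[Condition, ...]
    learning: LearningParams = field(default_factory=LearningParams)
    gain: float = 2.0

    @property
    def policy(self) -> PolicyParams:
        return PolicyParams(gain=self.gain, eligible_actions=self.task.eligible_actions)


def _two_action_task(n_blocks: int = 200) -> TaskConfig:
    """The validation network: one state, two actions, every trial recorded."""
    return TaskConfig(
        n_states=1, n_actions=2, left_action=0, right_action=1,
        recorded_state=0, n_blocks=n_blocks,
    )


def _full_task(n_blocks: int) -> TaskConfig:
    return TaskConfig(n_blocks=n_blocks)


def get_preset(name: str) -> ExperimentPreset:
    """Build a preset by name with the experiment's published parameters."""
    if name == "fig1_intensity_sweep":
        conds = tuple(
            Condition(f"D1R_I{i:g}", StimulationSpec("D1R", i, STIM_PROBABILITY))
            for i in SWEEP_INTENSITIES
        )
        return ExperimentPreset(name, _two_action_task(), conds)
    if name == "fig2_history":
        conds = tuple(
            Condition(
                f"{site}_{'rp' if mode != 'none' else 'norp'}",
                StimulationSpec(site, STIM_INTENSITY, STIM_PROBABILITY, rp_mode=mode),
                n_runs=N_RUNS,
            )
            for site in ("D1L", "D2L")
            for mode in ("none", "action_dependent")
        )
        return ExperimentPreset(name, _full_task(200), conds)
    if name == "fig3_rp_only":
        tc = _two_action_task()
        rp = lambda prob, mode: StimulationSpec(  # noqa: E731
            "RP_ONLY", STIM_INTENSITY, prob, rp_mode=mode,
            rp_target_action=tc.right_action if mode == "action_dependent" else None,
        )
        conds = (
            Condition("none", StimulationSpec.none(), n_runs=N_RUNS),
            Condition("rp06_dep", rp(STIM_PROBABILITY, "action_dependent"), n_runs=N_RUNS),
            Condition("rp94_dep", rp(RP_HIGH_PROBABILITY, "action_dependent"), n_runs=N_RUNS),
            Condition("rp94_indep", rp(RP_HIGH_PROBABILITY, "action_independent"), n_runs=N_RUNS),
        )
        return ExperimentPreset(name, tc, conds)
    if name == "fig4_weight_change":
        cond = Condition(
            "rpe_bias15",
            StimulationSpec(
                "RP_ONLY", STIM_INTENSITY, RPE_BIAS_PROBABILITY,
                rp_mode="action_independent",
            ),
        )
        return ExperimentPreset(name, _full_task(5000), (cond,))
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")


def validate_config(raw: dict) -> ExperimentPreset:
    """Build a preset from a plain config mapping, aggregating all errors.

    An empty config yields the default preset (the intensity sweep).  Supported
    keys: ``preset`` plus overrides ``n_blocks``, ``n_runs``, ``gain``,
    ``alpha_actor``, ``alpha_rp``, ``epsilon``, ``intensity``, ``probability``.
    """
    errors: list[str] = []
    raw = dict(raw or {})
    name = raw.pop("preset", "fig1_intensity_sweep")
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    preset = get_preset(name)

    known = {"n_blocks", "n_runs", "gain", "alpha_actor", "alpha_rp", "epsilon",
             "intensity", "probability"}
    for k in raw:
        if k not in known:
            errors.append(f"unknown config key {k!r}")

    task, learning, gain = preset.task, preset.learning, preset.gain
    try:
        if "n_blocks" in raw:
            task = replace(task, n_blocks=int(raw["n_blocks"]))
    except (TypeError, ValueError) as e:
        errors.append(f"n_blocks: {e}")
    try:
        if {"alpha_actor", "alpha_rp", "epsilon"} & raw.keys():
            learning = replace(
                learning,
                alpha_actor=float(raw.get("alpha_actor", learning.alpha_actor)),
                alpha_rp=float(raw.get("alpha_rp", learning.alpha_rp)),
                epsilon=float(raw.get("epsilon", learning.epsilon)),
            )
    except (TypeError, ValueError) as e:
        errors.append(f"learning params: {e}")
    try:
        gain = float(raw.get("gain", gain))
        if gain <= 0:
            errors.append("gain must be > 0")
    except (TypeError, ValueError) as e:
        errors.append(f"gain: {e}")

    conds = list(preset.conditions)
    try:
        if "intensity" in raw or "probability" in raw:
            conds = [
                Condition(
                    c.label,
                    replace(
                        c.stim,
                        intensity=float(raw.get("intensity", c.stim.intensity)),
                        probability=float(raw.get("probability", c.stim.probability)),
                    ) if c.stim.site != "NONE" else c.stim,
                    c.n_runs,
                )
                for c in conds
            ]
        if "n_runs" in raw:
            n = int(raw["n_runs"])
            if n < 1:
                errors.append("n_runs must be >= 1")
            else:
                conds = [Condition(c.label, c.stim, n) for c in conds]
    except (TypeError, ValueError) as e:
        errors.append(str(e))

    if errors:
        raise ValueError("invalid experiment config:\n  - " + "\n  - ".join(errors))
    return ExperimentPreset(name, task, tuple(conds), learning, gain)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Fan out n per-run seeds from one master seed (kept below 2**31)."""
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n) % (2**31)]


def _scaled(preset: ExperimentPreset, scale: float) -> ExperimentPreset:
    if scale == 1.0:
        return preset
    n_blocks = max(2, int(round(preset.task.n_blocks * scale)))
    return replace(preset, task=replace(preset.task, n_blocks=n_blocks))


def run_preset_sessions(
    preset: ExperimentPreset, seed: int, scale: float = 1.0
) -> tuple[dict[str, list[pd.DataFrame]], list[int]]:
    """Run every condition of a (possibly scaled) preset.

    Returns ``{condition label: [one record frame per run]}`` and the flat list
    of per-run seeds spawned from ``seed`` (in execution order).
    """
    preset = _scaled(preset, scale)
    total = sum(c.n_runs for c in preset.conditions)
    seeds = spawn_seeds(seed, total)
    it = iter(seeds)
    frames: dict[str, list[pd.DataFrame]] = {}
    for cond in preset.conditions:
        frames[cond.label] = [
            run_session(
                preset.task, cond.stim, preset.learning, preset.policy,
                rng=np.random.default_rng(next(it)),
            ).to_frame()
            for _ in range(cond.n_runs)
        ]
    return frames, seeds


def _case_key(row) -> str:
    return an.HistoryCase(row.side, row.outcome_2back, row.outcome_1back).label


def _per_run_case_ratios(
    frames: list[pd.DataFrame], tc: TaskConfig, split_by_flag: bool
) -> dict[tuple[str, str], dict[str, list[float]]]:
    """case label -> group -> list of per-run left ratios."""
    out: dict = {}
    for df in frames:
        h = an.classify_history(
            df, tc.recorded_state, tc.left_action, tc.right_action,
            split_by_flag=split_by_flag,
        )
        for row in h.itertuples():
            out.setdefault(_case_key(row), {}).setdefault(row.group, []).append(row.left_ratio)
    return out


def analyze_preset(
    preset: ExperimentPreset, frames: dict[str, list[pd.DataFrame]]
) -> dict:
    """Run the preset's published analysis on its session record frames.

    Returns a JSON-serialisable summary; DataFrame tables are included under
    ``tables`` (label -> DataFrame) for CSV export.
    """
    tc = preset.task
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"preset": preset.name}

    if preset.name == "fig1_intensity_sweep":
        fits = {}
        for label, runs in frames.items():
            df = pd.concat(runs, ignore_index=True)
            bins = an.bin_selection_by_value(df, tc.recorded_state, tc.left_action)
            for grp, b in bins.items():
                tables[f"{label}_{grp}_bins"] = b.to_frame()
                fits[f"{label}_{grp}"] = {
                    "midpoint": b.midpoint,
                    "slope": b.slope,
                    "slope_se": b.slope_se,
                    "p_slope_positive": b.p_slope,
                }
        summary["sigmoid_fits"] = fits

    elif preset.name == "fig2_history":
        rows = []
        for label, runs in frames.items():
            cases = _per_run_case_ratios(runs, tc, split_by_flag=True)
            for case, groups in sorted(cases.items()):
                t, p, note = an.compare_runs(
                    groups.get("stim", []), groups.get("unstim", [])
                )
                rows.append(
                    {
                        "condition": label,
                        "case": case,
                        "mean_stim": np.mean(groups.get("stim", [np.nan])),
                        "mean_unstim": np.mean(groups.get("unstim", [np.nan])),
                        "t": t,
                        "p": p,
                        "stars": an.significance_stars(p),
                        "note": note,
                    }
                )
        tables["history_ttests"] = pd.DataFrame(rows)
        summary["history_ttests"] = tables["history_ttests"].drop(columns="note").to_dict("records")

    elif preset.name == "fig3_rp_only":
        base_runs = frames["none"]
        base_cases = _per_run_case_ratios(base_runs, tc, split_by_flag=False)
        base_side = {
            side: [
                an.history_side_ratio(df, tc.recorded_state, tc.left_action,
                                      tc.right_action, side)[0]
                for df in base_runs
            ]
            for side in ("left", "right")
        }
        rows, pooled = [], {}
        for label, runs in frames.items():
            if label == "none":
                continue
            cases = _per_run_case_ratios(runs, tc, split_by_flag=False)
            for case, groups in sorted(cases.items()):
                t, p, note = an.compare_runs(
                    groups.get("all", []), base_cases.get(case, {}).get("all", [])
                )
                rows.append(
                    {
                        "condition": label,
                        "case": case,
                        "mean_stim": np.mean(groups.get("all", [np.nan])),
                        "mean_none": np.mean(base_cases.get(case, {}).get("all", [np.nan])),
                        "t": t,
                        "p": p,
                        "stars": an.significance_stars(p),
                        "note": note,
                    }
                )
            for side in ("left", "right"):
                ratios = [
                    an.history_side_ratio(df, tc.recorded_state, tc.left_action,
                                          tc.right_action, side)[0]
                    for df in runs
                ]
                t, p, _ = an.compare_runs(ratios, base_side[side])
                pooled[f"{label}_{side}"] = {
                    "mean_stim": float(np.mean(ratios)),
                    "mean_none": float(np.mean(base_side[side])),
                    "t": t,
                    "p": p,
                }
        tables["history_ttests"] = pd.DataFrame(rows)
        summary["history_ttests"] = tables["history_ttests"].drop(columns="note").to_dict("records")
        summary["pooled_side_ttests"] = pooled

    elif preset.name == "fig4_weight_change":
        (label, runs), = frames.items()
        df = pd.concat(runs, ignore_index=True)
        cells, anova = an.weight_change_table(
            df, tc.recorded_state, block_length=tc.block_length
        )
        tables["weight_change_cells"] = cells
        anova_out = anova.reset_index(names="effect")
        tables["anova"] = anova_out
        summary["cells"] = cells.to_dict("records")
        summary["anova_p"] = {
            str(r["effect"]): (None if pd.isna(r["PR(>F)"]) else float(r["PR(>F)"]))
            for _, r in anova_out.iterrows()
        }
    else:
        raise ValueError(f"no analysis defined for preset {preset.name!r}")

    summary["tables"] = tables
    return summary


def run_experiment(
    preset: ExperimentPreset | str,
    output_dir: str | Path,
    seed: int,
    scale: float = 1.0,
    keep_records: bool = False,
) -> dict:
    """Execute a preset end to end and write its result bundle.

    Writes per-analysis CSV tables, a ``summary.json`` and a ``manifest.json``
    (preset config, master and per-run seeds, scale, package version) into
    ``output_dir``; with ``keep_records`` also one records CSV per run.
    Deterministic given ``seed``.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    scaled = _scaled(preset, scale)
    frames, seeds = run_preset_sessions(preset, seed, scale)
    if keep_records:
        for label, runs in frames.items():
            for i, df in enumerate(runs):
                write_records_csv(df, out / f"records_{label}_run{i:02d}.csv")

    summary = analyze_preset(scaled, frames)
    tables = summary.pop("tables")
    for label, table in tables.items():
        table.to_csv(out / f"{label}.csv", index=False)

    manifest = {
        "preset": preset.name,
        "scale": scale,
        "master_seed": seed,
        "run_seeds": seeds,
        "task": asdict(scaled.task),
        "learning": asdict(scaled.learning),
        "gain": scaled.gain,
        "conditions": [
            {"label": c.label, "n_runs": c.n_runs, "stim": asdict(c.stim)}
            for c in scaled.conditions
        ],
        "package_version": __version__,
        "python": platform.python_version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    summary["tables"] = tables
    return summary
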