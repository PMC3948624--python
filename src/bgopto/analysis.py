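"""Statistical procedures for the simulated sessions.

Three analyses mirror the behavioural readouts of the modelled experiment:

* **Value-binned selection curves** — trials are binned by the pre-stimulation
  left action value; the left-selection ratio per bin is fitted with a logistic
  sigmoid by least squares, separately for stimulated and unstimulated trials.
* **Reward-history conditioning** — trials whose previous two (recorded-state)
  selections were the same side are split into the eight cases given by that
  side and the two outcomes; left-selection ratios per case are compared across
  simulation runs with Student's t-tests.
* **Weight-change statistics** — the D1 weight change of the (state, selected
  action) connection on the first/last trials of each block, split by outcome
  and stimulation flag, with a factorial ANOVA over the three factors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "HistoryCase",
    "BinSummary",
    "bin_selection_by_value",
    "fit_sigmoid",
    "classify_history",
    "history_cases",
    "history_side_ratio",
    "compare_runs",
    "significance_stars",
    "weight_change_table",
    "recorded_trials",
]


@dataclass(frozen=True)
class HistoryCase:
    """One of the 8 two-back conditions: common side × the two past outcomes."""

    side: str           # "left" | "right" — action selected on both previous trials
    outcome_2back: str  # "rewarded" | "unrewarded"
    outcome_1back: str

    @property
    def label(self) -> str:
        s = {"left": "L", "right": "R"}[self.side]
        o = {"rewarded": "+", "unrewarded": "-"}
        return f"{s}{o[self.outcome_2back]}{o[self.outcome_1back]}"


def history_cases() -> list[HistoryCase]:
    """All 8 cases in a fixed order (LL first, older outcome first)."""
    return [
        HistoryCase(s, o2, o1)
        for s, o2, o1 in itertools.product(
            ("left", "right"), ("rewarded", "unrewarded"), ("rewarded", "unrewarded")
        )
    ]


@dataclass
class BinSummary:
    """Binned left-selection curve and its least-squares sigmoid fit."""

    bin_edges: np.ndarray
    bin_value_mean: np.ndarray   # mean binning value per occupied bin
    left_ratio: np.ndarray
    count: np.ndarray
    sem: np.ndarray
    midpoint: float
    slope: float
    slope_se: float
    p_slope: float               # one-sided p for slope > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": self.bin_value_mean,
                "left_ratio": self.left_ratio,
                "count": self.count,
                "sem": self.sem,
            }
        )


def recorded_trials(df: pd.DataFrame, recorded_state: int) -> pd.DataFrame:
    """Trials of the analysed state, in session order."""
    return df[df["state"] == recorded_state].reset_index(drop=True)


def _sigmoid(x: np.ndarray, midpoint: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-slope * (x - midpoint)))


def fit_sigmoid(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares logistic fit of ratios vs values.

    Returns (midpoint, slope, slope_se, one-sided p for positive slope), the p
    from a t statistic with n-2 degrees of freedom on the slope estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        return float("nan"), float("nan"), float("nan"), float("nan")
    p0 = (float(np.median(x)), 4.0)
    try:
        popt, pcov = scipy.optimize.curve_fit(_sigmoid, x, y, p0=p0, maxfev=20000)
    except RuntimeError:
        return float("nan"), float("nan"), float("nan"), float("nan")
    midpoint, slope = float(popt[0]), float(popt[1])
    slope_se = float(np.sqrt(max(pcov[1, 1], 0.0)))
    if slope_se == 0 or not np.isfinite(slope_se):
        p = 0.0 if slope > 0 else 1.0
    else:
        t = slope / slope_se
        p = float(scipy.stats.t.sf(t, df=max(x.size - 2, 1)))
    return midpoint, slope, slope_se, p


def bin_selection_by_value(
    df: pd.DataFrame,
    recorded_state: int,
    left_action: int,
    n_bins: int = 11,
    value: str = "aL",
    binning: str = "quantile",
) -> dict[str, BinSummary]:
    """Left-selection ratio vs binned pre-stimulation action value, per stim group.

    Bin edges come from the pooled distribution of the binning variable over
    all recorded-state trials (``quantile`` intervals of the distribution by
    default, ``width`` for equal-width bins); the same edges are used for the
    stimulated and unstimulated groups so the curves are comparable.  ``value``
    is the left action value ``aL`` or the differential value ``diff``
    (aL - aR).  Empty bins are excluded from the curve and the fit.
    """
    rec = recorded_trials(df, recorded_state)
    v = (rec["aL"] - rec["aR"]) if value == "diff" else rec[value]
    v = v.to_numpy(dtype=float)
    if binning == "quantile":
        edges = np.unique(np.quantile(v, np.linspace(0, 1, n_bins + 1)))
    elif binning == "width":
        edges = np.linspace(v.min(), v.max(), n_bins + 1)
    else:
        raise ValueError("binning must be 'quantile' or 'width'")

    out: dict[str, BinSummary] = {}
    for name, grp in (("unstim", rec[~rec["stim"]]), ("stim", rec[rec["stim"]])):
        gv = ((grp["aL"] - grp["aR"]) if value == "diff" else grp[value]).to_numpy(float)
        is_left = (grp["action"] == left_action).to_numpy(float)
        idx = np.clip(np.searchsorted(edges, gv, side="right") - 1, 0, len(edges) - 2)
        means, ratios, counts, sems = [], [], [], []
        for b in range(len(edges) - 1):
            sel = idx == b
            n = int(sel.sum())
            if n == 0:
                continue  # empty bin: reported as missing, excluded from the fit
            r = is_left[sel]
            means.append(gv[sel].mean())
            ratios.append(r.mean())
            counts.append(n)
            sems.append(r.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan)
        means_a, ratios_a = np.asarray(means), np.asarray(ratios)
        midpoint, slope, slope_se, p = fit_sigmoid(means_a, ratios_a)
        out[name] = BinSummary(
            bin_edges=edges,
            bin_value_mean=means_a,
            left_ratio=ratios_a,
            count=np.asarray(counts, dtype=int),
            sem=np.asarray(sems),
            midpoint=midpoint,
            slope=slope,
            slope_se=slope_se,
            p_slope=p,
        )
    return out


def classify_history(
    df: pd.DataFrame,
    recorded_state: int,
    left_action: int,
    right_action: int,
    split_by_flag: bool = True,
) -> pd.DataFrame:
    """Left-selection ratio of the current trial, per two-back reward-history case.

    A recorded-state trial qualifies when the previous two recorded-state
    trials selected the same side; the case is that side plus the two
    outcomes, oldest first.  With ``split_by_flag`` the current trial's
    stimulation flag splits each case into 'stim'/'unstim' groups (the within-
    session comparison); without it all qualifying trials form one 'all' group
    (for comparisons against separate no-stimulation sessions).

    Returns a tidy frame with columns side, outcome_2back, outcome_1back,
    group, n, left_ratio; cases with no trials are absent.
    """
    rec = recorded_trials(df, recorded_state)
    if len(rec) < 3:
        return pd.DataFrame(
            columns=["side", "outcome_2back", "outcome_1back", "group", "n", "left_ratio"]
        )
    act = rec["action"].to_numpy()
    rew = (rec["reward"].to_numpy() > 0)
    stim = rec["stim"].to_numpy(bool)
    is_left_now = act == left_action

    a1, a2 = act[1:-1], act[:-2]          # t-1, t-2 relative to current act[2:]
    qual = a1 == a2
    side = np.where(a1 == left_action, "left", "right")
    o2 = np.where(rew[:-2], "rewarded", "unrewarded")
    o1 = np.where(rew[1:-1], "rewarded", "unrewarded")

    cur = pd.DataFrame(
        {
            "side": side[qual],
            "outcome_2back": o2[qual],
            "outcome_1back": o1[qual],
            "left": is_left_now[2:][qual].astype(float),
            "group": np.where(stim[2:][qual], "stim", "unstim") if split_by_flag else "all",
        }
    )
    if cur.empty:
        return pd.DataFrame(
            columns=["side", "outcome_2back", "outcome_1back", "group", "n", "left_ratio"]
        )
    out = (
        cur.groupby(["side", "outcome_2back", "outcome_1back", "group"], as_index=False)
        .agg(n=("left", "size"), left_ratio=("left", "mean"))
    )
    return out


def history_side_ratio(
    df: pd.DataFrame,
    recorded_state: int,
    left_action: int,
    right_action: int,
    side: str,
) -> tuple[float, int]:
    """Left-selection ratio pooled over all trials whose previous two selections
    were ``side`` ('left'/'right'), regardless of the past outcomes.

    Returns (ratio, n); ratio is NaN when no trial qualifies.
    """
    rec = recorded_trials(df, recorded_state)
    if len(rec) < 3:
        return float("nan"), 0
    act = rec["action"].to_numpy()
    prev_act = left_action if side == "left" else right_action
    qual = (act[1:-1] == prev_act) & (act[:-2] == prev_act)
    cur = act[2:][qual]
    if cur.size == 0:
        return float("nan"), 0
    return float(np.mean(cur == left_action)), int(cur.size)


def compare_runs(ratios_a: np.ndarray, ratios_b: np.ndarray) -> tuple[float, float, str]:
    """Two-sample Student's t-test of per-run selection ratios.

    Returns (t, p, note); degenerate (zero-variance) inputs are reported via
    the note rather than raising.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size < 2 or b.size < 2:
        return float("nan"), float("nan"), "need >= 2 runs per group"
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, "degenerate: both groups constant and equal"
        return float("inf"), 0.0, "degenerate: both groups constant, means differ"
    t, p = scipy.stats.ttest_ind(a, b)
    return float(t), float(p), ""


def significance_stars(p: float) -> str:
    """Figure convention: '*' for p < 0.05, '**' for p < 0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def weight_change_table(
    df: pd.DataFrame,
    recorded_state: int,
    block_length: int = 20,
    early_k: int = 2,
    late_k: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Early/late-block D1 weight-change cells and their factorial ANOVA.

    Uses recorded-state trials at block positions 1..early_k ('early') and
    block_length-late_k+1..block_length ('late').  Cells are stimulation flag ×
    outcome × position; the ANOVA includes the three factors and all
    interactions.  Returns (cell table, ANOVA table); empty cells appear in the
    cell table with n=0.
    """
    rec = recorded_trials(df, recorded_state)
    early = rec["pos"] <= early_k
    late = rec["pos"] > block_length - late_k
    sub = rec[early | late].copy()
    sub["phase"] = np.where(sub["pos"] <= early_k, "early", "late")
    sub["outcome"] = np.where(sub["reward"] > 0, "rewarded", "unrewarded")
    sub["stim_grp"] = np.where(sub["stim"], "stim", "unstim")

    cells = []
    for s, o, ph in itertools.product(("stim", "unstim"), ("rewarded", "unrewarded"), ("early", "late")):
        c = sub[(sub.stim_grp == s) & (sub.outcome == o) & (sub.phase == ph)]["dw_d1"]
        cells.append(
            {
                "stim": s,
                "outcome": o,
                "phase": ph,
                "n": len(c),
                "mean_dw": c.mean() if len(c) else np.nan,
                "sd_dw": c.std(ddof=1) if len(c) > 1 else np.nan,
            }
        )
    cell_table = pd.DataFrame(cells)

    model = smf.ols("dw_d1 ~ C(stim_grp) * C(outcome) * C(phase)", data=sub).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    return cell_table, anova
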