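"""Reward-history-conditioned effect of D1L stimulation on selection.

Trials are grouped by the two previous (same-side) choices and their outcomes
— eight cases such as "L++" (left chosen twice, both rewarded) or "R--"
(right twice, never rewarded).  D1L stimulation (intensity 0.5, 6% of trials)
boosts the "right" action; its effect is largest when recent rewards were
inconsistent or absent, i.e. when the agent is uncertain.

Runs 8 reduced sessions (100 blocks) of the D1L condition; the published
analysis uses 20 runs of 200 blocks.
"""

from bgopto.experiments import (
    ExperimentPreset,
    analyze_preset,
    run_preset_sessions,
    validate_config,
)

base = validate_config({"preset": "fig2_history", "n_blocks": 100, "n_runs": 8})
d1l = tuple(c for c in base.conditions if c.label == "D1L_norp")
preset = ExperimentPreset(base.name, base.task, d1l, base.learning, base.gain)

frames, _ = run_preset_sessions(preset, seed=1)
table = analyze_preset(preset, frames)["tables"]["history_ttests"]

print("case  left-ratio(no stim)  left-ratio(stim)   diff      p")
for row in table.itertuples():
    print(f"{row.case:4s}  {row.mean_unstim:18.3f}  {row.mean_stim:16.3f}  "
          f"{row.mean_stim - row.mean_unstim:+.3f}  {row.p:.2e} {row.stars}")

# Stimulation lowers the left ratio everywhere (it favours "right"), but the
# drop after consistent double rewards (L++/R++) is a fraction of the drop
# after inconsistent or absent rewards — uncertainty amplifies the bias.
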