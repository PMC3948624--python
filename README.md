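# bgopto

An abstract actor–critic model of the basal ganglia with simulated
optogenetic stimulation, for studying how phasic activation of the direct
(D1) or indirect (D2) striatal pathway — or of the dopaminergic reward
prediction itself — biases action selection and plasticity in a two-choice
block-reversal task.

The package is aimed at computational neuroscientists who want a small,
fully reproducible model of channelrhodopsin-style striatal stimulation:
every experiment is a preset that can be re-run from a seed, and every
analysis (psychometric curves, reward-history conditioning, weight-change
statistics) is an importable function over plain trial records.

## The model

Cortical states *i* project to action units *j* through two plastic
pathways. The support an action unit receives from pathway X ∈ {D1, D2} is

    s_j^X = β_j^X + Σ_i w_ij^X · o_i

with *o* the one-hot state vector, and the net action activation subtracts
the inhibitory indirect pathway:

    a_j = s_j^D1 − s_j^D2

One of the two task actions is then drawn from a softmax with gain γ = 2:

    P(j) = exp(γ a_j) / Σ_k exp(γ a_k)

A reward-prediction (RP) system — the Critic — stores the expected reward of
every state–action pairing; after selection it emits the prediction for the
chosen pairing, and the reward-prediction error δ = r − RP(s, a) gates all
plasticity as the third factor of a three-factor rule. Weights are BCPNN
log-probability ratios derived from exponentially smoothed activity traces,

    w_ij = log( p_ij / (p_i · p_j) ),   β_j = log p_j,

updated at rate α·|δ| with δ's sign routing credit: positive δ reinforces
the co-active (state, selected action) pairing in D1 and the non-selected
alternatives in D2; negative δ does the converse.

Stimulation injects a transient activation (0.15, 0.5 or 2.0) into one
action's D1 or D2 unit just before selection, and/or inflates (deflates, for
D2, floored at zero) the reward prediction before the RPE is computed —
nothing is ever written into the stored weights directly.

## Worked example

```python
from bgopto import TaskConfig, run_session

tc = TaskConfig(n_blocks=300, seed=1)   # rewarded side flips every 20 trials
res = run_session(tc)
df = res.to_frame()
rec = df[(df.state == tc.recorded_state) & (df.block >= 20)]
for lo, hi in ((1, 5), (16, 20)):
    m = (rec.action == rec.side)[(rec.pos >= lo) & (rec.pos <= hi)].mean()
    print(f"positions {lo}-{hi}: rewarded side selected {m:.3f}")
```

prints

```
positions 1-5: rewarded side selected 0.340
positions 16-20: rewarded side selected 0.914
```

Right after a reversal the agent still prefers the previously rewarded side
(0.34 < 0.5); by the end of the 20-trial block it has re-learned the new
contingency (0.91). `examples/` contains one narrative script per
capability: block-reversal learning, the stimulation intensity sweep,
reward-history conditioning, and the weight-change analysis under a biased
reward prediction.

## Command line

```
bgopto presets                                   # list experiment presets
bgopto run --preset fig2_history --seed 1 --out results/fig2
bgopto analyze results/fig2/records_D1L_norp_run00.csv --out results/reanalysis
```

Each run writes CSV tables, a `summary.json`, and a `manifest.json` (config,
master and per-run seeds, package version) from which the bundle can be
reproduced exactly.

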