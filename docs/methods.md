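# Methods

## Model

The network is a grandmother-cell actor–critic abstraction of the basal
ganglia. `n_states` cortical units (default 5) project to `n_actions` action
units (default 4, two of which — "left" and "right" — are selectable) through
two independent plastic pathways. The direct (D1) pathway's support promotes
an action; the indirect (D2) pathway's support is subtracted from it,
implementing suppression. Selection is a softmax with gain γ = 2 restricted
to the two task actions; the non-task action units exist, carry weights and
are updated, but are never selected.

The Critic (`rp_pred`) stores a non-negative expected reward per state–action
pairing. Exactly one prediction is read per trial — the one for the current
state and the just-selected action — and the reward-prediction error
δ = r − RP(s, a) gates all plasticity.

### Plasticity

Both actor pathways use BCPNN-style probability traces: exponentially
smoothed estimates of pre-synaptic (`p_pre`), post-synaptic (`p_post`) and
joint (`p_joint`) activity, floored at ε and capped at 1. Weights and biases
are *derived* quantities, recomputed after every update:

    w = log(p_joint / (p_pre · p_post)),  β = log(p_post)

so they can never drift away from the probability semantics (the test suite
checks this identity to 1e−12 after arbitrary update sequences).

The trial's update smooths the traces toward the current activity pattern at
an effective rate α_actor·|δ|. The RPE's sign routes which post-units count
as active: for δ > 0, the selected action in D1 and the non-selected eligible
actions in D2; for δ < 0, the converse. This is a hard (0/1) routing of the
qualitative credit-assignment rule; a graded variant would interpolate the
post-activity instead and is not implemented. With a single-state network the
joint and post traces coincide, so state→action weights are degenerate
(always 0) and learning is carried entirely by the biases — the weight-change
analysis therefore always uses a multi-state network.

The Critic uses a plain delta rule, RP ← max(0, RP + α_rp·δ), on the visited
pairing only, with a deliberately slower rate than the actor.

### Parameters

| parameter | default | meaning |
|---|---|---|
| γ (softmax gain) | 2.0 | sharpness of selection (dimensionless) |
| α_actor | 0.05 | actor trace rate per unit |δ|, per trial |
| α_rp | 0.01 | critic rate (slower pathway), per trial |
| ε | 1e−4 | probability-trace floor (keeps log-ratios finite) |
| reward_magnitude | 1.0 | value of one delivered reward |

α_actor = 0.05 makes preference saturate within a 20-trial block yet reverse
within the next one; α_rp = 0.01 converges to a Bernoulli(0.75) mean within
roughly 500 visits (the convergence test allows ±0.05 after 2000). The
published experiments fix all of them; they are exposed in `LearningParams` /
`PolicyParams` for exploration.

## Task

Two-choice block-reversal bandit: the rewarded side pays with probability
0.75, the other side never pays, and the sides swap every `block_length`
(20) trials. States are drawn uniformly each trial and all share the block's
contingency; analyses use only the trials of one recorded state. Block
boundaries are counted in recorded-state trials by default (matching a
single-context task); counting all trials is a config switch. The first
rewarded side defaults to "left".

## Stimulation

A `StimulationSpec` names a site (D1L/D1R/D2L/D2R, RP_ONLY, or NONE), an
intensity, a per-trial probability, and a reward-prediction mode. Sites
follow the unilateral-hemisphere convention: the letter is the stimulated
hemisphere and the targeted action is contralateral (D1L excites the D1 unit
of action "right"). On a flagged trial the intensity is added to the
targeted action's pathway support just before selection (raising the net
activation for D1 sites, lowering it for D2 sites; action activations are
not floored). The reward prediction can be co-biased between selection and
the RPE: +intensity for D1-linked bias, −intensity floored at zero for
D2-linked, +intensity for RP_ONLY. `action_dependent` mode biases only when
the selected action is the targeted one; `action_independent` biases every
flagged trial. Injections are never written into weights or stored
predictions: a stimulated trial differs from its counterfactual only through
the learning update its (possibly biased) RPE triggers. The biased δ also
drives the critic's own update, so under frequent stimulation the stored
prediction gradually absorbs the bias — the behavioural effects that remain
are those of the transient mismatch and of the zero floor.

## Analyses

* **Value-binned selection curves** — recorded trials are binned by the
  pre-stimulation left action value (11 quantile intervals by default; the
  bin count and equal-width binning are options, as is binning on the
  left−right differential value). Left-selection ratios per bin, split by the
  trial's stimulation flag, are fitted with a logistic sigmoid by least
  squares; the slope's one-sided positivity p-value uses a t statistic with
  n_bins−2 degrees of freedom.
* **Reward-history cases** — a recorded trial qualifies when the two previous
  recorded trials chose the same side; the case is that side plus the two
  outcomes (8 cases). Ratios are computed per run and compared across runs
  with two-sample Student's t-tests (star convention: p < 0.05 and
  p < 0.001). Within-session comparisons split trials by the per-trial flag;
  comparisons against separate no-stimulation runs use all qualifying trials.
  A pooled per-side ratio (all qualifying trials with a given previous side)
  summarises each run in one number for the headline test. Degenerate
  (zero-variance) groups are reported, not fatal.
* **Weight-change table** — D1 weight change of the (state, selected action)
  connection on the first two and last two trials of each block, split by
  stimulation flag and outcome; cell means/s.d. plus a factorial
  (three-factor, all interactions) ANOVA. The published label for this
  analysis is a "Two-Way ANOVA" over the three listed factors; the full
  factorial is what is computed here.

## Experiment presets

* `fig1_intensity_sweep` — validation network (1 state, 2 actions; every
  trial recorded, so 200 blocks = 4000 trials), D1R at 6% probability, one
  session per intensity {0.15, 0.5, 2.0}.
* `fig2_history` — full 5×4 network, 200 blocks, D1L and D2L at 0.5 / 6%,
  with `rp_mode` none and action_dependent; 20 runs per condition.
* `fig3_rp_only` — validation network, RP_ONLY +0.5 at 6% (action-dependent)
  and 94% (both modes) plus matched no-stimulation runs; 20 runs each. The
  two-action network is used because the published comparison chains back to
  the validation set-up; on the full network the reward-prediction-only
  effect is diluted below detectability at these run counts.
* `fig4_weight_change` — full network, RP_ONLY +0.5 action-independent at
  15%, one 5000-block session (the acceptance run uses 1000 blocks, which
  leaves every ANOVA effect far below p = 0.001 while keeping the run in
  seconds).

Per-run seeds fan out from one master seed via `numpy.random.SeedSequence`
and are recorded in the result manifest; identical seeds give byte-identical
bundles.

## What the generator does and does not emulate

Sessions are synthetic by construction: stationary uniform state sequencing,
instantaneous trials, a strict alternation of rewarded sides, and a reward
that is either 0 or 1. Passing tests therefore show that the *model*
reproduces the published selection and plasticity phenomena under the task's
idealised statistics — not that it fits mouse behaviour, which includes
reaction times, satiation, lapses and stimulation-timing effects outside
this model's scope (no real time, delays, or spiking dynamics).

## Numerical choices and degenerate inputs

Softmax is computed after subtracting the maximum activation (shift
invariance to 1e−12). δ = 0 performs no update at all. Probability traces
are clipped to [ε, 1] after every smoothing step. The sigmoid fit starts at
(median value, slope 4) and reports NaN parameters when fewer than three
bins are occupied or the fit fails; empty bins are excluded. t-tests with
fewer than two runs per group, and ANOVA cells with no trials, are reported
as missing rather than raised. `rp_pred` is clamped at zero from below, and
RPE itself is never clamped.

## Known limitations

The trace formulation is a functional BCPNN reconstruction, not a bit-level
one; constants were chosen for the stated behavioural criteria. Hard 0/1
credit routing is one of several defensible readings of the qualitative
rule. The action-independent reward-prediction bias produces its selection
shift mainly through histories containing missed rewards; its per-case
significance in consistently-rewarded histories is weaker than the pooled
effect. Only one unit is stimulated per session; combined or bilateral
stimulation is not modelled.
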