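# competing-critics

A simulator for a dual-critic model of human reward learning and
decision-making, aimed at computational-psychiatry and decision-neuroscience
work on risk sensitivity, deliberation, and the opponent roles of dopamine
and serotonin.

## The model

The learner maintains two tabular state-action value functions updated from
the same experience stream by risk-sensitive Q-learning:

    Q⁺(S,A) ← Q⁺(S,A) + α[(1 + k⁺)·1{δ⁺>0} + (1 − k⁺)·1{δ⁺<0}]·δ⁺
    Q⁻(S,A) ← Q⁻(S,A) + α[(1 − k⁻)·1{δ⁻>0} + (1 + k⁻)·1{δ⁻<0}]·δ⁻

with per-critic TD errors δ± = R + γ·maxₐQ±(S′,a) − Q±(S,A). The optimist Q⁺
over-weights good surprises, the pessimist Q⁻ over-weights bad ones; at
k⁺ = k⁻ = 0 both reduce to the classic risk-neutral Q-learner. To choose, a
utility U(a) ~ Uniform[Q⁻(S,a), Q⁺(S,a)] is drawn per action and the learner
acts ε-greedily on the realized U. Behavior decomposes along two rotated
axes: risk sensitivity s_r = k⁺ − k⁻ (shifts the interval midpoint) and
uncertainty sensitivity s_u = k⁺ + k⁻ (widens the interval, i.e. the scope of
deliberation).

The package bundles the learner with four simulation tasks — a single-state
task with moment-specified rewards (mean/SD/skew/kurtosis via a
Pearson-system sampler), the Iowa Gambling Task, the two-stage Markov task,
and a stock-market betting task with counterfactually centered rewards — and
the readouts used to characterize them: value-function geometry, deck
preferences, stay probabilities, a reaction-time proxy F(U) = exp(−b·U), and
dopamine-like (ΔQ⁺) / serotonin-like (−ΔQ⁻) update transients conditioned on
a task-level reward prediction error.

## Worked example

```python
from competing_critics import (CriticParams, MomentSpec, SimulationConfig,
                               run_replicates, summarize_q, deck_frequencies)

cfg = SimulationConfig(
    task="stationary",
    task_kwargs={"spec": MomentSpec(mu=0.5, sigma=0.2, skew=0.0, kurt=2.5)},
    replicates=2000, trials=100, seed=1,
)
summary = summarize_q(run_replicates(cfg))
for key in ("q_plus", "q_neutral", "q_minus", "midpoint", "gap"):
    print(f"{key:10s} {summary.asymptote[key]:.3f}")
```

prints

```
q_plus     0.743
q_neutral  0.499
q_minus    0.254
midpoint   0.499
gap        0.489
```

With balanced asymmetry (k⁺ = k⁻ = 0.9) the critics bracket the risk-neutral
value: the optimist settles well above the 0.5 reward mean, the pessimist
symmetrically below, and their midpoint recovers the mean (zero-skew
rewards). The gap is the width of the deliberation interval and scales with
the reward SD. Switching to the Iowa Gambling Task with imbalanced weights,

```python
igt = SimulationConfig(task="igt", params=CriticParams(k_plus=0.9, k_minus=0.1),
                       replicates=2000, trials=100, seed=1)
print(deck_frequencies(run_replicates(igt)).round(3))
```

```
A    0.226
B    0.334
C    0.202
D    0.238
```

the risk-seeking learner prefers "bad" deck B — large one-time gains despite
a negative expected net payoff — whereas balanced weights prefer good deck C.

A CLI mirrors the library: `ccritics run`, `ccritics sweep`,
`ccritics report`, and `ccritics reproduce --figure {2|3|4|6|7|8|9}` write
tidy CSV tables plus a JSON manifest with content hashes. See
`docs/methods.md` for model assumptions, task parameterizations, and
numerical choices.

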