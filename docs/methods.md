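# Methods

## Model

The learner keeps two tabular state-action value functions, an optimistic
critic Q⁺ and a pessimistic critic Q⁻, both initialized to zero and updated
from the same experience by risk-sensitive Q-learning. Each critic forms its
own TD error δ± = R + γ·maxₐQ±(S′,a) − Q±(S,A) and applies a learning rate
asymmetry: Q⁺ multiplies positive errors by (1 + k⁺) and negative errors by
(1 − k⁺); Q⁻ does the reverse with k⁻. Both asymmetry weights live in
[0, 1]; at k⁺ = k⁻ = 0 the two updates are identical to the classic
risk-neutral rule, and the engine can carry a third, risk-neutral table Q on
the same reward stream as a reference curve.

Decisions integrate the two critics through a random utility: for each
available action, U(a) is drawn uniformly from the interval between Q⁻(S,a)
and Q⁺(S,a), and the learner acts ε-greedily on the realized U values. Wide
intervals (large s_u = k⁺ + k⁻) make similarly-valued actions genuinely
competitive; the interval midpoint relative to expected reward tracks
s_r = k⁺ − k⁻.

Assumptions worth making explicit: both critics share one learning rate α
and one discount γ; the asymmetry enters only through the error weighting;
exploration is a separate ε mechanism that never bypasses the utility draw
(U is realized and logged on every trial so latency readouts exist
everywhere, with ε only overriding which action is returned).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| α | learning rate (unitless) | 0.5 | shared by all three tables |
| ε | exploration probability | 0.3 | uniform over non-greedy actions |
| γ | discount factor | 0 | 0.9 on the two-stage task, where value must flow between stages |
| k⁺, k⁻ | optimism / pessimism weights | 0.9, 0.9 | the balanced reference learner |
| replicates | independent runs per condition | 30,000 | desk-scale analyses use 2,000 (see below) |
| trials | decisions per run | 100 | 80 on the two-stage task, 120 (6 markets × 20) on the market task |
| b | latency scale, 1/reward units | 1 | only orderings and variability of exp(−b·U) are interpreted |

## Reward generator

The single-state task draws i.i.d. rewards specified purely by four
moments (mean μ, SD σ, skew, raw kurtosis; the standard configuration is
μ = 0.5, σ = 0.2, skew 0, kurtosis 2.5). The generator selects a
Pearson-system member from the (skew², kurtosis) plane — normal, symmetric
or skewed four-parameter beta, gamma, scaled Student t, or the two-point
boundary law — and falls back to a Fleishman cubic polynomial of a standard
normal in the Type-IV region where no classical closed form applies.
Because every downstream result depends on the reward law only through its
moments, the generator is validated by moment recovery (each of the four
moments within Monte-Carlo error at 10⁶ draws) rather than by family
identity. Raw kurtosis 2.5 is platykurtic (excess −0.5); reading the target
as excess kurtosis would flip the Pearson type and is not supported by the
feasibility region of the remaining configurations.

## Task environments

All four tasks implement one vectorized MDP contract (`reset`/`step` over a
replicate axis).

- **Iowa Gambling Task.** One state, four decks, i.i.d. net payoffs per
  draw. Deck C is uniform on {+50, 0}. The remaining decks follow the
  canonical net-payoff structure on the same scale: A pays +100 with a
  0.5-probability −250 loss, B pays +100 with a 0.1-probability −1250 loss,
  D pays +50 with a 0.1-probability −250 loss, giving expected nets
  (−25, −25, +25, +25) and concentrating B's risk in rare, very large
  losses. The scheme is a config object so alternative payoff tables drop
  in.
- **Two-stage Markov task.** States {1, 2, 3}; the first-stage choice
  reaches second-stage state 1 + a with probability 0.7 (common) and the
  other state with 0.3 (rare); first-stage rewards are zero. Second-stage
  options pay 1 with probabilities following independent reflecting
  Gaussian random walks on [0.25, 0.75] (step SD 0.025), the standard
  design for this task. The return to stage one is an ordinary state
  transition, and γ = 0.9 carries value across stages; there are no
  terminal episodes. Stay probabilities are computed over consecutive
  first-stage trials, conditioned on the earlier trial's reward and
  transition type.
- **Market task.** Six markets of 20 decisions. Prices follow a
  multiplicative Gaussian random walk p_{t+1} = p_t(1 + η),
  η ~ N(0, 0.05²) bounded above −0.9, restarting at 100 per market (the
  original experiment used real price series; only signs, splits and
  relative magnitudes of the readouts are interpreted, so any reasonable
  positive-price walk serves). Bets are the two levels {25%, 75%}; the
  learning reward is the percent gain centered on the counterfactual
  neutral bet, R = f·(A − 50) with f the fractional price change. Trials
  are episodic for learning while the price path persists. The task-level
  reward prediction error is the realized percent gain f·A z-scored
  against its past values within the same market (sample SD, n−1
  denominator); with fewer than two past values or zero past SD the RPE is
  defined as 0 and such trials are excluded from sign-conditioned
  summaries.

## Numerical and design choices

- **Simultaneous update.** Both δ± are computed from the pre-update tables,
  then both tables are written.
- **δ = 0.** The gain/loss indicators leave the weight at zero error
  undefined; the update is zero either way and the logged weight is 0.
- **Inverted intervals.** Nothing forces Q⁻ ≤ Q⁺ in every transient regime,
  so the utility draw orders the endpoints first (Uniform(min, max)),
  keeping the rule total while preserving the interval semantics.
- **Ties.** The utility argmax breaks ties uniformly (this matters on the
  first trials, when all tables are exactly zero); the ε branch draws
  uniformly over the non-greedy actions, which for fully tied draws makes
  the overall choice uniform over all actions.
- **Terminal transitions** drop the bootstrap term (max over next actions
  defined as 0), needed for the market task's episodic trials.
- **Lockstep vectorization.** All replicates advance together with value
  tables of shape (R, S, A) and a single seeded Generator; replicates are
  statistically independent, and a (config, seed) pair reproduces the whole
  run bit for bit. Per-replicate RNG substreams were deliberately traded
  away for array-level speed; the reproducibility unit is the run, not the
  individual replicate.
- **Asymptotes** are means over the final 20 of 100 trials; at α = 0.5 the
  value curves are flat well before trial 80. The slowest transient is the
  pessimist's gain side, which relaxes at rate 1 − α(1 − k⁻) per trial
  (0.95 at defaults), so horizons well beyond 100 trials are used wherever a
  fully converged Q⁻ is required.
- **Replicate counts.** Headline figures use 30,000 replicates; the test
  suite and the acceptance script use 2,000 (and 500-per-point grids) with
  3-standard-error tolerances, which this package treats as its desk-scale
  standard. Every directional claim was checked to be stable at these
  sizes; the two-stage stay-gap contrast is the exception and is run at
  30,000 replicates (a few seconds under vectorization).
- **Sweeps** run an 11×11 (k⁺, k⁻) lattice by default with per-point seeds
  derived from the base seed; map orientations are summarized by rank
  correlations with s_r and s_u rather than by surface values.

## What the generators do and do not emulate

The synthetic tasks reproduce the structural features the model's claims
rest on: moment-controlled reward laws, good/bad deck asymmetries with rare
large losses, common/rare transition statistics with drifting second-stage
payoffs, and counterfactually centered market gains. They do not emulate
real market price dynamics, human payoff calibration, session effects, or
individual parameter variation. Passing tests therefore demonstrate the
model's internal behavioral signatures under the stated conditions, not fits
to human data.

## Known limitations

- The two-stage reward × transition stay signature is strongly attenuated
  relative to human data: because the stage-two-to-stage-one switch is an
  ordinary state transition, a reward influences the first-stage values only
  after the *next* first-stage update, so the immediate stay decision picks
  up the reward only through the persistence of the drifting reward
  probabilities. The common/rare gap contrast across s_u is reliable in
  direction but small in magnitude (~0.005 vs ~0.003 at 30,000 replicates).
- The ordering Q⁻ ≤ Q ≤ Q⁺ is exercised at the balanced k = 0.9 setting
  (single state, γ = 0); it is not guaranteed for extreme or very small
  asymmetry weights.
- The latency transform saturates to infinity for very negative utilities
  (e.g. after large IGT losses with b = 1); only orderings and variability
  of the latency proxy are meaningful.
- The Fleishman fallback does not cover the entire Type-IV moment region;
  infeasible or unreachable moment combinations raise an explicit error
  rather than sampling approximately.
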