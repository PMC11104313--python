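"""The four simulated decision tasks behind one environment contract.

Every task is a discrete Markov decision process exposed through a
vectorized interface: ``reset(n)`` returns the initial state for ``n``
independent replicates and ``step(states, actions, rng)`` advances all
replicates one decision at a time.  The scalar contract of the model is
the ``n = 1`` case.

Tasks
-----
- ``StationaryEnv``: one state, one action; rewards are i.i.d. draws with
  specified mean/SD/skew/kurtosis.  Isolates pure value learning.
- ``IGTEnv``: Iowa Gambling Task; one state, four decks with net payoffs
  per draw.  Good decks (C, D) gain on average, bad decks (A, B) lose,
  with deck B hiding rare, very large losses.
- ``TwoStageEnv``: two-stage Markov task; a first-stage choice leads to
  one of two second-stage states through common (p = 0.7) / rare (p = 0.3)
  transitions, second-stage choices pay Bernoulli rewards whose
  probabilities drift over trials, and the task loops back to stage one.
- ``MarketEnv``: stock-market betting; each trial the agent bets low (25%)
  or high (75%) on a random price move and is rewarded with the percent
  gain relative to the counterfactual neutral 50% bet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rewards import MomentSpec, sample_rewards

__all__ = [
    "StepResult",
    "Environment",
    "DeckScheme",
    "StationaryEnv",
    "IGTEnv",
    "TwoStageEnv",
    "MarketEnv",
    "compute_rpe",
    "rpe_zscores",
    "make_environment",
]


@dataclass(frozen=True)
class StepResult:
    rewards: np.ndarray  # (n,)
    next_states: np.ndarray  # (n,) state occupied at the next decision
    terminal: np.ndarray  # (n,) bool; True kills the bootstrap term
    metadata: dict[str, np.ndarray] = field(default_factory=dict)


class Environment:
    """Vectorized MDP contract; subclasses define the Markov kernel."""

    n_states: int
    n_actions: int

    def reset(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def step(
        self, states: np.ndarray, actions: np.ndarray, rng: np.random.Generator
    ) -> StepResult:
        raise NotImplementedError


class StationaryEnv(Environment):
    """Trivial state and action space; learning sees only the reward law."""

    n_states = 1
    n_actions = 1

    def __init__(self, spec: MomentSpec | None = None):
        self.spec = spec if spec is not None else MomentSpec()

    def reset(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.zeros(n, dtype=np.int64)

    def step(self, states, actions, rng) -> StepResult:
        n = len(states)
        rewards = sample_rewards(self.spec, n, rng)
        return StepResult(
            rewards=rewards,
            next_states=np.zeros(n, dtype=np.int64),
            terminal=np.zeros(n, dtype=bool),
        )


@dataclass(frozen=True)
class DeckScheme:
    """Net-payoff law per IGT deck: discrete support and probabilities.

    The default follows the canonical net-payoff structure scaled so that
    deck C pays uniformly from {+50, 0}: decks A and B lose 25 per draw on
    average (B through a rare, very large loss), decks C and D gain 25.
    """

    support: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = field(
        default_factory=lambda: {
            "A": ((100.0, -150.0), (0.5, 0.5)),
            "B": ((100.0, -1150.0), (0.9, 0.1)),
            "C": ((50.0, 0.0), (0.5, 0.5)),
            "D": ((50.0, -200.0), (0.9, 0.1)),
        }
    )

    def __post_init__(self) -> None:
        for deck, (vals, probs) in self.support.items():
            if len(vals) != len(probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"deck {deck}: probabilities must align and sum to 1")
        means = self.expected_net
        for deck in ("A", "B"):
            if deck in means and not means[deck] < 0:
                raise ValueError(f"bad deck {deck} must have negative expected net value")
        for deck in ("C", "D"):
            if deck in means and not means[deck] > 0:
                raise ValueError(f"good deck {deck} must have positive expected net value")

    @property
    def decks(self) -> tuple[str, ...]:
        return tuple(self.support)

    @property
    def expected_net(self) -> dict[str, float]:
        return {
            deck: float(np.dot(vals, probs)) for deck, (vals, probs) in self.support.items()
        }


class IGTEnv(Environment):
    """Iowa Gambling Task: one state, four decks, i.i.d. net payoffs."""

    n_states = 1

    def __init__(self, scheme: DeckScheme | None = None):
        self.scheme = scheme if scheme is not None else DeckScheme()
        self.n_actions = len(self.scheme.decks)

    def reset(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.zeros(n, dtype=np.int64)

    def step(self, states, actions, rng) -> StepResult:
        n = len(states)
        rewards = np.empty(n)
        for idx, deck in enumerate(self.scheme.decks):
            mask = actions == idx
            if not mask.any():
                continue
            vals, probs = self.scheme.support[deck]
            rewards[mask] = rng.choice(np.asarray(vals), size=int(mask.sum()), p=np.asarray(probs))
        return StepResult(
            rewards=rewards,
            next_states=np.zeros(n, dtype=np.int64),
            terminal=np.zeros(n, dtype=bool),
            metadata={"deck": actions.astype(np.int8)},
        )


class TwoStageEnv(Environment):
    """Two-stage Markov task with drifting second-stage reward probabilities.

    State 0 is the first stage (reward always 0); action a leads to
    second-stage state 1 + a with probability ``p_common``, to the other
    with the complement.  Second-stage choices pay ``reward_value`` with a
    per-(state, action) Bernoulli probability following an independent
    reflecting Gaussian random walk on ``prob_bounds``; the task then
    returns to state 0 as an ordinary state transition (no terminal
    episodes), so a discount factor near 1 carries value across stages.
    """

    n_states = 3
    n_actions = 2

    def __init__(
        self,
        p_common: float = 0.7,
        reward_value: float = 1.0,
        prob_bounds: tuple[float, float] = (0.25, 0.75),
        drift_sd: float = 0.025,
    ):
        if not 0.0 <= p_common <= 1.0:
            raise ValueError("p_common must be a probability")
        self.p_common = p_common
        self.reward_value = reward_value
        self.prob_bounds = prob_bounds
        self.drift_sd = drift_sd
        self._probs: np.ndarray | None = None  # (n, 2, 2): (stage-2 state - 1, action)

    def reset(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.prob_bounds
        self._probs = rng.uniform(lo, hi, size=(n, 2, 2))
        return np.zeros(n, dtype=np.int64)

    def _drift(self, mask: np.ndarray, rng: np.random.Generator) -> None:
        lo, hi = self.prob_bounds
        step = rng.normal(0.0, self.drift_sd, size=self._probs[mask].shape)
        p = self._probs[mask] + step
        # reflect at the bounds
        p = np.where(p > hi, 2 * hi - p, p)
        p = np.where(p < lo, 2 * lo - p, p)
        self._probs[mask] = np.clip(p, lo, hi)

    def step(self, states, actions, rng) -> StepResult:
        if self._probs is None:
            raise RuntimeError("call reset() before step()")
        n = len(states)
        rewards = np.zeros(n)
        next_states = np.zeros(n, dtype=np.int64)
        common = np.zeros(n, dtype=bool)
        stage1 = states == 0
        if stage1.any():
            is_common = rng.random(int(stage1.sum())) < self.p_common
            a = actions[stage1]
            dest = np.where(is_common, 1 + a, 2 - a)
            next_states[stage1] = dest
            common[stage1] = is_common
        stage2 = ~stage1
        if stage2.any():
            rows = np.flatnonzero(stage2)
            p = self._probs[rows, states[rows] - 1, actions[rows]]
            rewards[rows] = self.reward_value * (rng.random(len(rows)) < p)
            next_states[rows] = 0
            self._drift(stage2, rng)
        return StepResult(
            rewards=rewards,
            next_states=next_states,
            terminal=np.zeros(n, dtype=bool),
            metadata={"stage": np.where(stage1, 1, 2).astype(np.int8), "common": common},
        )


class MarketEnv(Environment):
    """Stock-market betting with counterfactually centered rewards.

    Each trial the agent bets low (25%) or high (75%) on the next price
    move of a synthetic market (multiplicative Gaussian random walk).
    With fractional price change f, the learning reward is
    ``R = f * (bet - 50)`` — the percent gain relative to the neutral 50%
    bet — so a +10% move under a 75% bet pays +2.5 and under a 25% bet
    pays -2.5.  Trials are episodic for learning (terminal after the
    reward) while the price path persists within each of the
    ``n_markets`` blocks of ``trials_per_market`` decisions.  Metadata
    records the realized percent monetary gain ``f * bet`` used for the
    task-level reward-prediction-error split.
    """

    n_states = 1
    n_actions = 2
    bet_levels = (25.0, 75.0)

    def __init__(
        self,
        n_markets: int = 6,
        trials_per_market: int = 20,
        volatility: float = 0.05,
        p0: float = 100.0,
    ):
        if p0 <= 0:
            raise ValueError("initial price must be positive")
        self.n_markets = n_markets
        self.trials_per_market = trials_per_market
        self.volatility = volatility
        self.p0 = p0
        self._t = 0
        self._price: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.n_markets * self.trials_per_market

    def reset(self, n: int, rng: np.random.Generator) -> np.ndarray:
        self._t = 0
        self._price = np.full(n, self.p0)
        return np.zeros(n, dtype=np.int64)

    def step(self, states, actions, rng) -> StepResult:
        if self._price is None:
            raise RuntimeError("call reset() before step()")
        n = len(states)
        if self._t >= self.n_trials:
            raise RuntimeError(f"market task has only {self.n_trials} decisions")
        if self._t % self.trials_per_market == 0:
            self._price[:] = self.p0  # new market
        frac = np.maximum(rng.normal(0.0, self.volatility, size=n), -0.9)
        self._price *= 1.0 + frac
        if not np.all(self._price > 0):
            raise FloatingPointError("market price became non-positive")
        bets = np.asarray(self.bet_levels)[actions]
        rewards = frac * (bets - 50.0)
        market = np.full(n, self._t // self.trials_per_market, dtype=np.int8)
        self._t += 1
        return StepResult(
            rewards=rewards,
            next_states=np.zeros(n, dtype=np.int64),
            terminal=np.ones(n, dtype=bool),
            metadata={
                "market": market,
                "frac_change": frac,
                "pct_gain": frac * bets,
                "bet": bets,
            },
        )


def compute_rpe(history: np.ndarray, current: float) -> float:
    """Task-level RPE: current percent gain z-scored against its own past.

    Uses the sample (n-1 denominator) standard deviation of the past
    values.  With fewer than two past values, or a zero past SD, the RPE
    is defined as 0 (warm-up / degenerate-scale convention).
    """
    history = np.asarray(history, dtype=float)
    if history.size < 2:
        return 0.0
    sd = float(np.std(history, ddof=1))
    if sd == 0.0:
        return 0.0
    return (float(current) - float(np.mean(history))) / sd


def rpe_zscores(pct_gains: np.ndarray, market_ids: np.ndarray) -> np.ndarray:
    """Per-trial RPEs for a (replicates, trials) percent-gain array.

    The past window is all previous trials within the same market.
    """
    pct_gains = np.atleast_2d(pct_gains)
    market_ids = np.asarray(market_ids)
    out = np.zeros_like(pct_gains, dtype=float)
    for m in np.unique(market_ids):
        cols = np.flatnonzero(market_ids == m)
        for j, t in enumerate(cols):
            if j < 2:
                continue
            past = pct_gains[:, cols[:j]]
            mean = past.mean(axis=1)
            sd = past.std(axis=1, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (pct_gains[:, t] - mean) / sd
            out[:, t] = np.where(sd > 0, z, 0.0)
    return out


def make_environment(task: str, **kwargs) -> Environment:
    """Factory keyed by task name: stationary | igt | two_stage | market."""
    factories = {
        "stationary": StationaryEnv,
        "igt": IGTEnv,
        "two_stage": TwoStageEnv,
        "market": MarketEnv,
    }
    try:
        return factories[task](**kwargs)
    except KeyError:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(factories)}") from None
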