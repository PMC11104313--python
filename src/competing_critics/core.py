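"""The competing-critics learner.

Two tabular state-action value functions are learned from the same stream
of experience: an optimistic critic Q+ that over-weights positive
prediction errors, and a pessimistic critic Q- that over-weights negative
ones.  Each critic runs a risk-sensitive Q-learning update

    Q+(S,A) += alpha * [(1 + k+) 1{d+ > 0} + (1 - k+) 1{d+ < 0}] * d+
    Q-(S,A) += alpha * [(1 - k-) 1{d- > 0} + (1 + k-) 1{d- < 0}] * d-

with per-critic prediction errors d± = R + gamma * max_a Q±(S', a) - Q±(S, A).
At k+ = k- = 0 both collapse to the classic risk-neutral Q-learner.

Decisions are made by drawing, for each available action, a utility
U(a) ~ Uniform over the interval spanned by Q-(S,a) and Q+(S,a), and then
acting epsilon-greedily on the realized U values.  The width of the
[Q-, Q+] interval therefore controls how much superficially sub-optimal
but competitive actions are deliberated over.

Two derived coordinates summarize a parameter pair (k+, k-):
risk sensitivity s_r = k+ - k- (shifts the interval midpoint relative to
the expected reward) and uncertainty sensitivity s_u = k+ + k- (widens
the interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CriticParams",
    "SensitivityCoords",
    "CriticPair",
    "Transition",
    "UpdateRecord",
    "UtilityDraw",
    "gain_loss_weight",
    "compute_prediction_errors",
    "apply_asymmetric_update",
    "update_neutral",
    "draw_utilities",
    "select_action",
    "sensitivity_coords",
]

#: Default parameter tuple (alpha, epsilon, gamma, k+, k-) used throughout
#: the simulation experiments unless a task overrides it.
DEFAULT_PARAMS = (0.5, 0.3, 0.0, 0.9, 0.9)


@dataclass(frozen=True)
class SensitivityCoords:
    """45-degree rotation of the (k+, k-) parameter plane."""

    s_r: float  #: risk sensitivity, k+ - k-, in [-1, 1]
    s_u: float  #: uncertainty sensitivity, k+ + k-, in [0, 2]

    def to_k(self) -> tuple[float, float]:
        """Invert back to (k_plus, k_minus)."""
        return (self.s_u + self.s_r) / 2.0, (self.s_u - self.s_r) / 2.0


@dataclass(frozen=True)
class CriticParams:
    """Learner parameters; all unitless.

    alpha    learning rate in (0, 1]
    gamma    discount factor in [0, 1)
    epsilon  exploration probability in [0, 1]
    k_plus   optimism weight in [0, 1]
    k_minus  pessimism weight in [0, 1]
    """

    alpha: float = DEFAULT_PARAMS[0]
    epsilon: float = DEFAULT_PARAMS[1]
    gamma: float = DEFAULT_PARAMS[2]
    k_plus: float = DEFAULT_PARAMS[3]
    k_minus: float = DEFAULT_PARAMS[4]

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must lie in [0, 1), got {self.gamma}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        for name in ("k_plus", "k_minus"):
            k = getattr(self, name)
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {k}")


def sensitivity_coords(p: CriticParams) -> SensitivityCoords:
    """Map (k+, k-) to the (s_r, s_u) risk/uncertainty axes."""
    return SensitivityCoords(s_r=p.k_plus - p.k_minus, s_u=p.k_plus + p.k_minus)


@dataclass
class CriticPair:
    """Tabular Q+ / Q- (and optional risk-neutral Q) over (state, action).

    Arrays may carry arbitrary leading batch axes; the trailing two axes
    index (state, action).  Tables start at zero.
    """

    q_plus: np.ndarray
    q_minus: np.ndarray
    q_neutral: np.ndarray | None = None

    @classmethod
    def zeros(
        cls, n_states: int, n_actions: int, *, neutral: bool = False, batch: tuple[int, ...] = ()
    ) -> "CriticPair":
        shape = (*batch, n_states, n_actions)
        return cls(
            q_plus=np.zeros(shape),
            q_minus=np.zeros(shape),
            q_neutral=np.zeros(shape) if neutral else None,
        )

    @property
    def n_states(self) -> int:
        return self.q_plus.shape[-2]

    @property
    def n_actions(self) -> int:
        return self.q_plus.shape[-1]


@dataclass(frozen=True)
class Transition:
    """One experienced transition (S, A, R, S'); empty next_actions = terminal."""

    state: int
    action: int
    reward: float
    next_state: int
    next_actions: tuple[int, ...] = ()


@dataclass(frozen=True)
class UpdateRecord:
    """Prediction errors and the table increments actually applied."""

    delta_plus: float
    delta_minus: float
    d_q_plus: float
    d_q_minus: float


@dataclass(frozen=True)
class UtilityDraw:
    """Per-action utility realizations and the resulting choice."""

    actions: tuple[int, ...]
    u: np.ndarray  # aligned with `actions`
    greedy_action: int
    chosen_action: int


def gain_loss_weight(delta: np.ndarray, k: float, optimistic: bool) -> np.ndarray:
    """Asymmetric error weight: (1 ± k) on gains, (1 ∓ k) on losses.

    ``optimistic=True`` amplifies positive errors (Q+ side); ``False``
    amplifies negative errors (Q- side).  The weight at delta == 0 is 0,
    which is immaterial since it multiplies a zero error.
    """
    sign = 1.0 if optimistic else -1.0
    delta = np.asarray(delta)
    return (1.0 + sign * k) * (delta > 0) + (1.0 - sign * k) * (delta < 0)


def _next_max(q: np.ndarray, t: Transition) -> float:
    if not t.next_actions:
        return 0.0
    return float(np.max(q[t.next_state, list(t.next_actions)]))


def compute_prediction_errors(
    critics: CriticPair, t: Transition, gamma: float
) -> tuple[float, float]:
    """Per-critic TD errors d± for a transition, without touching the tables."""
    delta_plus = t.reward + gamma * _next_max(critics.q_plus, t) - critics.q_plus[t.state, t.action]
    delta_minus = (
        t.reward + gamma * _next_max(critics.q_minus, t) - critics.q_minus[t.state, t.action]
    )
    if not (np.isfinite(delta_plus) and np.isfinite(delta_minus)):
        raise FloatingPointError(
            f"non-finite prediction error (d+={delta_plus}, d-={delta_minus}) at "
            f"(state={t.state}, action={t.action}); check gamma/reward configuration"
        )
    return float(delta_plus), float(delta_minus)


def apply_asymmetric_update(critics: CriticPair, t: Transition, p: CriticParams) -> UpdateRecord:
    """Apply the paired asymmetric updates in place and return the record.

    Both errors are computed from the pre-update tables, then both tables
    are written (simultaneous update).
    """
    dp, dm = compute_prediction_errors(critics, t, p.gamma)
    inc_plus = p.alpha * float(gain_loss_weight(dp, p.k_plus, optimistic=True)) * dp
    inc_minus = p.alpha * float(gain_loss_weight(dm, p.k_minus, optimistic=False)) * dm
    critics.q_plus[t.state, t.action] += inc_plus
    critics.q_minus[t.state, t.action] += inc_minus
    return UpdateRecord(delta_plus=dp, delta_minus=dm, d_q_plus=inc_plus, d_q_minus=inc_minus)


def update_neutral(critics: CriticPair, t: Transition, p: CriticParams) -> float:
    """Classic risk-neutral Q-learning update on the reference table."""
    if critics.q_neutral is None:
        raise ValueError("neutral critic not enabled on this CriticPair")
    delta = (
        t.reward + p.gamma * _next_max(critics.q_neutral, t) - critics.q_neutral[t.state, t.action]
    )
    inc = p.alpha * delta
    critics.q_neutral[t.state, t.action] += inc
    return float(inc)


def draw_utilities(
    critics: CriticPair,
    state: int,
    actions: tuple[int, ...],
    rng: np.random.Generator,
    epsilon: float = 0.0,
) -> UtilityDraw:
    """Draw U(a) ~ Uniform over [Q-(S,a), Q+(S,a)] and pick an action.

    Endpoints are ordered before sampling so the rule stays total if a
    transient regime inverts the interval; a degenerate interval returns
    the common value.  Ties in the argmax are broken uniformly.  The
    epsilon branch never bypasses the draw: U is always realized.
    """
    if not actions:
        raise ValueError("actions must be non-empty")
    acts = list(actions)
    qp = critics.q_plus[state, acts]
    qm = critics.q_minus[state, acts]
    lo, hi = np.minimum(qp, qm), np.maximum(qp, qm)
    u = lo + (hi - lo) * rng.random(len(acts))
    winners = np.flatnonzero(u == u.max())
    greedy = int(winners[rng.integers(len(winners))]) if len(winners) > 1 else int(winners[0])
    chosen = _epsilon_branch(len(acts), greedy, epsilon, rng)
    return UtilityDraw(
        actions=tuple(acts), u=u, greedy_action=acts[greedy], chosen_action=acts[chosen]
    )


def _epsilon_branch(n_actions: int, greedy: int, epsilon: float, rng: np.random.Generator) -> int:
    if n_actions == 1:
        return greedy
    if rng.random() < epsilon:
        other = int(rng.integers(n_actions - 1))
        return other + (other >= greedy)
    return greedy


def select_action(draw: UtilityDraw, epsilon: float, rng: np.random.Generator) -> int:
    """Epsilon-greedy selection on an existing utility draw.

    With probability 1 - epsilon the greedy action (argmax U, ties broken
    uniformly at draw time) is returned; otherwise a uniform draw over the
    non-greedy actions.  Single-action states always return that action.
    """
    greedy_idx = draw.actions.index(draw.greedy_action)
    idx = _epsilon_branch(len(draw.actions), greedy_idx, epsilon, rng)
    return draw.actions[idx]
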