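"""Seeded replicate runner, aggregate summaries, and (k+, k-) sweeps.

All replicates of a simulation advance in lockstep: value tables are held
as arrays of shape (replicates, states, actions) and every per-trial
operation — utility draws, epsilon-greedy selection, the environment
kernel, and the asymmetric updates — is vectorized across the replicate
axis.  A single seeded Generator drives the whole run, so a
(config, seed) pair reproduces a SimulationResult bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import CriticParams, gain_loss_weight
from .environments import Environment, make_environment

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "run_replicates",
    "summarize_q",
    "QSummary",
    "sweep",
    "lattice",
    "deck_frequencies",
    "stay_probabilities",
]

#: Replicate count used for the headline simulation summaries.
FULL_REPLICATES = 30_000


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation: learner parameters, task, and run sizes."""

    params: CriticParams = field(default_factory=CriticParams)
    task: str = "stationary"
    task_kwargs: dict = field(default_factory=dict)
    trials: int = 100
    replicates: int = FULL_REPLICATES
    seed: int = 0
    track_neutral: bool = True

    def __post_init__(self) -> None:
        if self.trials < 1 or self.replicates < 1:
            raise ValueError("trials and replicates must both be >= 1")

    def make_env(self) -> Environment:
        return make_environment(self.task, **self.task_kwargs)


@dataclass
class SimulationResult:
    """Replicate x trial logs of one run; arrays are (R, T[, ...])."""

    config: SimulationConfig
    states: np.ndarray  # (R, T) state visited
    actions: np.ndarray  # (R, T) chosen action
    greedy_actions: np.ndarray  # (R, T) argmax of the utility draw
    explored: np.ndarray  # (R, T) bool, epsilon branch taken
    rewards: np.ndarray  # (R, T)
    utilities: np.ndarray  # (R, T, A)
    delta_plus: np.ndarray  # (R, T)
    delta_minus: np.ndarray
    dq_plus: np.ndarray  # (R, T) applied update to Q+
    dq_minus: np.ndarray
    q_plus: np.ndarray  # (R, T, S, A) table snapshot after the trial's update
    q_minus: np.ndarray
    q_neutral: np.ndarray | None
    metadata: dict[str, np.ndarray]

    @property
    def n_replicates(self) -> int:
        return self.actions.shape[0]

    @property
    def n_trials(self) -> int:
        return self.actions.shape[1]

    @property
    def max_utility(self) -> np.ndarray:
        """(R, T) array of max_a U_t(a), the reaction-time statistic."""
        return self.utilities.max(axis=-1)

    def to_trials_frame(self) -> pd.DataFrame:
        """Tidy long-format per-trial log (one row per replicate x trial)."""
        r_idx, t_idx = np.indices(self.actions.shape)
        cols = {
            "replicate": r_idx.ravel(),
            "trial": t_idx.ravel(),
            "state": self.states.ravel(),
            "action": self.actions.ravel(),
            "greedy_action": self.greedy_actions.ravel(),
            "explored": self.explored.ravel(),
            "reward": self.rewards.ravel(),
            "max_utility": self.max_utility.ravel(),
            "delta_plus": self.delta_plus.ravel(),
            "delta_minus": self.delta_minus.ravel(),
            "dq_plus": self.dq_plus.ravel(),
            "dq_minus": self.dq_minus.ravel(),
        }
        for key, arr in self.metadata.items():
            cols[key] = arr.ravel()
        return pd.DataFrame(cols)


def run_replicates(config: SimulationConfig) -> SimulationResult:
    """Run R independent replicates of T decisions each.

    Per-trial loop: draw utilities -> epsilon-greedy selection ->
    environment step -> prediction errors from the pre-update tables ->
    simultaneous asymmetric updates (plus the optional risk-neutral
    reference update on the same experience stream).
    """
    p = config.params
    env = config.make_env()
    rng = np.random.default_rng(config.seed)
    R, T = config.replicates, config.trials
    S, A = env.n_states, env.n_actions
    rows = np.arange(R)

    states = env.reset(R, rng)
    q_plus = np.zeros((R, S, A))
    q_minus = np.zeros((R, S, A))
    q_neutral = np.zeros((R, S, A)) if config.track_neutral else None

    log = {
        "states": np.empty((R, T), dtype=np.int16),
        "actions": np.empty((R, T), dtype=np.int16),
        "greedy_actions": np.empty((R, T), dtype=np.int16),
        "explored": np.empty((R, T), dtype=bool),
        "rewards": np.empty((R, T)),
        "utilities": np.empty((R, T, A)),
        "delta_plus": np.empty((R, T)),
        "delta_minus": np.empty((R, T)),
        "dq_plus": np.empty((R, T)),
        "dq_minus": np.empty((R, T)),
        "q_plus": np.empty((R, T, S, A)),
        "q_minus": np.empty((R, T, S, A)),
    }
    q_neutral_log = np.empty((R, T, S, A)) if config.track_neutral else None
    meta_log: dict[str, list[np.ndarray]] = {}

    for t in range(T):
        qp_s = q_plus[rows, states]  # (R, A)
        qm_s = q_minus[rows, states]
        lo = np.minimum(qp_s, qm_s)
        hi = np.maximum(qp_s, qm_s)
        u = lo + (hi - lo) * rng.random((R, A))

        # greedy = argmax U with uniform tie-break
        tie_keys = rng.random((R, A))
        greedy = np.argmax(np.where(u == u.max(axis=1, keepdims=True), tie_keys, -1.0), axis=1)
        if A > 1:
            explored = rng.random(R) < p.epsilon
            alt = rng.integers(0, A - 1, size=R)
            alt += alt >= greedy  # uniform over the non-greedy actions
            chosen = np.where(explored, alt, greedy)
        else:
            explored = np.zeros(R, dtype=bool)
            chosen = greedy

        step = env.step(states, chosen, rng)
        boot_plus = np.where(step.terminal, 0.0, q_plus[rows, step.next_states].max(axis=1))
        boot_minus = np.where(step.terminal, 0.0, q_minus[rows, step.next_states].max(axis=1))
        delta_plus = step.rewards + p.gamma * boot_plus - q_plus[rows, states, chosen]
        delta_minus = step.rewards + p.gamma * boot_minus - q_minus[rows, states, chosen]
        if not (np.isfinite(delta_plus).all() and np.isfinite(delta_minus).all()):
            bad = int(np.flatnonzero(~np.isfinite(delta_plus) | ~np.isfinite(delta_minus))[0])
            raise FloatingPointError(
                f"non-finite prediction error in replicate {bad} at trial {t}; "
                "check gamma/reward configuration"
            )
        inc_plus = p.alpha * gain_loss_weight(delta_plus, p.k_plus, optimistic=True) * delta_plus
        inc_minus = (
            p.alpha * gain_loss_weight(delta_minus, p.k_minus, optimistic=False) * delta_minus
        )
        q_plus[rows, states, chosen] += inc_plus
        q_minus[rows, states, chosen] += inc_minus
        if q_neutral is not None:
            boot_n = np.where(step.terminal, 0.0, q_neutral[rows, step.next_states].max(axis=1))
            delta_n = step.rewards + p.gamma * boot_n - q_neutral[rows, states, chosen]
            q_neutral[rows, states, chosen] += p.alpha * delta_n
            q_neutral_log[:, t] = q_neutral

        log["states"][:, t] = states
        log["actions"][:, t] = chosen
        log["greedy_actions"][:, t] = greedy
        log["explored"][:, t] = explored
        log["rewards"][:, t] = step.rewards
        log["utilities"][:, t] = u
        log["delta_plus"][:, t] = delta_plus
        log["delta_minus"][:, t] = delta_minus
        log["dq_plus"][:, t] = inc_plus
        log["dq_minus"][:, t] = inc_minus
        log["q_plus"][:, t] = q_plus
        log["q_minus"][:, t] = q_minus
        for key, arr in step.metadata.items():
            meta_log.setdefault(key, []).append(arr)
        states = step.next_states

    metadata = {key: np.stack(chunks, axis=1) for key, chunks in meta_log.items()}
    return SimulationResult(
        config=config, q_neutral=q_neutral_log, metadata=metadata, **log
    )


@dataclass(frozen=True)
class QSummary:
    """Per-trial value-function summary plus tail-window asymptotes."""

    table: pd.DataFrame  # per trial: mean / q25 / q75 for Q+, Q-, (Q)
    asymptote: dict[str, float]


def summarize_q(result: SimulationResult, tail: int = 20) -> QSummary:
    """Mean and IQR of Q+, Q-, (Q) per trial, and tail-window asymptotes.

    Only defined for a single-(state, action) task, where the value
    tables reduce to one trajectory per replicate.  The asymptote of each
    curve is the replicate mean of its average over the final ``tail``
    trials; the ``gap``/``midpoint``/``iqr_*`` entries are derived from
    the same window.
    """
    if result.q_plus.shape[2] != 1 or result.q_plus.shape[3] != 1:
        raise ValueError("summarize_q requires a single-state, single-action task")
    if result.n_trials < tail:
        raise ValueError(
            f"need at least tail={tail} trials for the asymptote window, "
            f"got {result.n_trials}"
        )
    curves = {"q_plus": result.q_plus[:, :, 0, 0], "q_minus": result.q_minus[:, :, 0, 0]}
    if result.q_neutral is not None:
        curves["q_neutral"] = result.q_neutral[:, :, 0, 0]

    table = pd.DataFrame({"trial": np.arange(result.n_trials)})
    asymptote: dict[str, float] = {}
    for name, vals in curves.items():
        q25, q75 = np.percentile(vals, [25, 75], axis=0)
        table[f"{name}_mean"] = vals.mean(axis=0)
        table[f"{name}_q25"] = q25
        table[f"{name}_q75"] = q75
        asymptote[name] = float(vals[:, -tail:].mean())
        asymptote[f"iqr_{name}"] = float((q75 - q25)[-tail:].mean())
    asymptote["gap"] = asymptote["q_plus"] - asymptote["q_minus"]
    asymptote["midpoint"] = (asymptote["q_plus"] + asymptote["q_minus"]) / 2.0
    return QSummary(table=table, asymptote=asymptote)


def deck_frequencies(result: SimulationResult) -> pd.Series:
    """Per-deck selection proportions pooled over trials and replicates."""
    if result.config.task != "igt":
        raise ValueError("deck_frequencies requires an IGT run")
    env = result.config.make_env()
    labels = env.scheme.decks
    counts = np.bincount(result.actions.ravel(), minlength=len(labels))
    return pd.Series(counts / counts.sum(), index=list(labels), name="selection_proportion")


def stay_probabilities(result: SimulationResult) -> pd.DataFrame:
    """Stay probabilities by previous-trial reward x transition type.

    A pair is two consecutive first-stage trials; "stay" means repeating
    the first-stage action.  Conditions refer to the earlier trial of the
    pair: whether its second-stage outcome was rewarded and whether its
    stage-1 -> stage-2 transition was common or rare.  Cells with no
    qualifying pairs are reported as NaN with a zero count.
    """
    if "stage" not in result.metadata:
        raise ValueError("stay_probabilities requires a two-stage run")
    stage = result.metadata["stage"][0]  # lockstep: identical across replicates
    first = np.flatnonzero(stage == 1)
    if len(first) < 2:
        raise ValueError("need at least two first-stage trials")
    t1, t2 = first[:-1], first[1:]
    stay = result.actions[:, t2] == result.actions[:, t1]
    rewarded = result.rewards[:, t1 + 1] > 0
    common = result.metadata["common"][:, t1]

    records = []
    for rew in (True, False):
        for com in (True, False):
            mask = (rewarded == rew) & (common == com)
            n = int(mask.sum())
            records.append(
                {
                    "rewarded": rew,
                    "transition": "common" if com else "rare",
                    "stay_prob": float(stay[mask].mean()) if n else float("nan"),
                    "n_pairs": n,
                }
            )
    table = pd.DataFrame(records).set_index(["rewarded", "transition"])
    for rew in (True, False):
        table.loc[(rew, "common"), "common_minus_rare"] = (
            table.loc[(rew, "common"), "stay_prob"] - table.loc[(rew, "rare"), "stay_prob"]
        )
    return table


def lattice(n: int = 11) -> list[tuple[float, float]]:
    """An n x n grid of (k+, k-) points on [0, 1]^2."""
    axis = np.linspace(0.0, 1.0, n)
    return [(float(kp), float(km)) for kp in axis for km in axis]


def _default_summary(result: SimulationResult) -> dict[str, float]:
    out: dict[str, float] = {
        "max_u_mean": float(result.max_utility.mean()),
        "max_u_sd": float(result.max_utility.std()),
    }
    if result.q_plus.shape[2] == 1 and result.q_plus.shape[3] == 1:
        summ = summarize_q(result).asymptote
        out["midpoint"] = summ["midpoint"]
        out["gap"] = summ["gap"]
    if result.config.task == "igt":
        freqs = deck_frequencies(result)
        for deck, frac in freqs.items():
            out[f"deck_{deck}"] = float(frac)
        out["bad_deck_rate"] = float(freqs.get("A", 0.0) + freqs.get("B", 0.0))
    if result.config.task == "two_stage":
        table = stay_probabilities(result)
        for (rew, trans), row in table.iterrows():
            out[f"stay_{'rew' if rew else 'unrew'}_{trans}"] = float(row["stay_prob"])
    return out


def sweep(
    grid: list[tuple[float, float]],
    base_config: SimulationConfig,
    summary_fn: Callable[[SimulationResult], dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Run one simulation per (k+, k-) grid point and collect summaries.

    Each point reuses ``base_config`` with only the asymmetry weights
    replaced and gets an independent seed derived from the base seed.
    Returns a tidy frame keyed by (k_plus, k_minus, s_r, s_u).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    for kp, km in grid:
        if not (0.0 <= kp <= 1.0 and 0.0 <= km <= 1.0):
            raise ValueError(f"grid point ({kp}, {km}) outside [0, 1]^2")
    summary_fn = summary_fn or _default_summary
    seeds = np.random.SeedSequence(base_config.seed).generate_state(len(grid)) & 0x7FFFFFFF
    rows = []
    for (kp, km), seed in zip(grid, seeds):
        p = base_config.params
        point_params = CriticParams(
            alpha=p.alpha, epsilon=p.epsilon, gamma=p.gamma, k_plus=kp, k_minus=km
        )
        cfg = SimulationConfig(
            params=point_params,
            task=base_config.task,
            task_kwargs=base_config.task_kwargs,
            trials=base_config.trials,
            replicates=base_config.replicates,
            seed=int(seed),
            track_neutral=base_config.track_neutral,
        )
        row = {"k_plus": kp, "k_minus": km, "s_r": kp - km, "s_u": kp + km}
        row.update(summary_fn(run_replicates(cfg)))
        rows.append(row)
    return pd.DataFrame(rows)
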