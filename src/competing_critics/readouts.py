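"""Reaction-time proxies and neuromodulator-like update transients.

The model reads out two quantities beyond choices themselves.  First, a
strictly decreasing latency transform F(x) = exp(-b x) maps the winning
utility draw to a reaction-time proxy: the larger max_a U(a), the earlier
the choice.  Because F is strictly decreasing, the action selected by
minimal latency is exactly the utility-greedy action.  Second, on the
market task, the per-trial applied updates are interpreted as phasic
neuromodulator transients — dQ+ as dopamine-like and -dQ- as
serotonin-like — and summarized as conditional means split by the sign of
the task-level reward prediction error and the bet level (optionally also
the next trial's bet).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import UtilityDraw
from .engine import SimulationResult
from .environments import rpe_zscores

__all__ = [
    "LatencyMap",
    "reaction_time",
    "reaction_times",
    "max_utility_stats",
    "transient_table",
]


@dataclass(frozen=True)
class LatencyMap:
    """Latency transform F(x) = exp(-b x); b > 0 in inverse reward units."""

    b: float = 1.0

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError(f"latency scale b must be > 0, got {self.b}")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        # extreme negative utilities saturate to inf; only orderings are read out
        with np.errstate(over="ignore"):
            return np.exp(-self.b * np.asarray(x))


def reaction_time(draw: UtilityDraw, latency: LatencyMap) -> tuple[float, int]:
    """Latency and action for one greedy decision.

    The latency is min_a F(U(a)); the selected action is the argmin of F,
    which coincides with the utility argmax because F is strictly
    decreasing.
    """
    f = latency(draw.u)
    return float(f.min()), draw.greedy_action


def reaction_times(
    result: SimulationResult, latency: LatencyMap | None = None, greedy_only: bool = True
) -> pd.DataFrame:
    """Per-trial latency proxies for a run, as a tidy frame.

    Exploration trials still carry a logged utility draw; by default they
    are excluded, matching the framing that the latency mechanism plays
    out only when the learner acts greedily.
    """
    latency = latency or LatencyMap()
    lat = latency(result.max_utility)
    keep = ~result.explored if greedy_only else np.ones_like(result.explored)
    r_idx, t_idx = np.nonzero(keep)
    return pd.DataFrame(
        {
            "replicate": r_idx,
            "trial": t_idx,
            "latency": lat[keep.astype(bool)],
            "action": result.greedy_actions[keep.astype(bool)],
        }
    )


def max_utility_stats(result: SimulationResult, greedy_only: bool = False) -> dict[str, float]:
    """Mean and SD of max_a U_t(a) pooled over replicates and trials.

    Larger means predict faster reactions.  All trials are pooled by
    default; set ``greedy_only`` to drop exploration trials.
    """
    vals = result.max_utility
    if greedy_only:
        vals = vals[~result.explored]
    return {"max_u_mean": float(vals.mean()), "max_u_sd": float(vals.std())}


def _market_rpe(result: SimulationResult) -> np.ndarray:
    if "pct_gain" not in result.metadata or "market" not in result.metadata:
        raise ValueError("transient readouts require a market-task run")
    return rpe_zscores(result.metadata["pct_gain"], result.metadata["market"][0])


def transient_table(result: SimulationResult, with_next_bet: bool = False) -> pd.DataFrame:
    """Conditional means of the dopamine-/serotonin-like transients.

    Cells are keyed by RPE sign and bet level (25 or 75), optionally also
    by the next trial's bet within the same market.  Each cell reports
    the mean applied update dQ+ (dopamine-like), the mean of -dQ-
    (serotonin-like), and its trial count.  Trials with RPE exactly 0
    (warm-up or degenerate past) are excluded; pairs spanning a market
    boundary are excluded from next-bet conditioning.  Empty cells are
    reported as NaN with a zero count rather than fabricated.
    """
    rpe = _market_rpe(result)
    bets = result.metadata["bet"]
    market = result.metadata["market"][0]
    dq_plus = result.dq_plus
    neg_dq_minus = -result.dq_minus

    valid = rpe != 0.0
    cols: dict[str, np.ndarray] = {
        "rpe_sign": np.where(rpe > 0, "positive", "negative"),
        "bet": bets,
    }
    if with_next_bet:
        next_bet = np.full_like(bets, np.nan)
        next_bet[:, :-1] = bets[:, 1:]
        same_market = np.zeros_like(valid)
        same_market[:, :-1] = market[1:] == market[:-1]
        valid = valid & same_market
        cols["next_bet"] = next_bet

    frame = pd.DataFrame({k: v[valid] for k, v in cols.items()})
    frame["dq_plus"] = dq_plus[valid]
    frame["neg_dq_minus"] = neg_dq_minus[valid]
    keys = ["rpe_sign", "bet"] + (["next_bet"] if with_next_bet else [])
    grouped = frame.groupby(keys, observed=False).agg(
        mean_dq_plus=("dq_plus", "mean"),
        mean_neg_dq_minus=("neg_dq_minus", "mean"),
        n=("dq_plus", "size"),
    )
    # materialize every combination so empty cells are explicit
    levels = [["negative", "positive"], [25.0, 75.0]] + (
        [[25.0, 75.0]] if with_next_bet else []
    )
    full_index = pd.MultiIndex.from_product(levels, names=keys)
    grouped = grouped.reindex(full_index)
    grouped["n"] = grouped["n"].fillna(0).astype(int)
    return grouped
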