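"""Magni-risk–based glycemic reward.

The per-measurement reward maps blood glucose ``b`` (mg/dl) to [-1, 1]:

    reward(b) = -1                                        if b < 70
    reward(b) = 1 - clip(10 * (c0*((ln b)^c1 - c2))^2, 0, 15.5) / 7.75   otherwise

with c0 = 1.509, c1 = 1.084, c2 = 5.381.  The quadratic risk term is the
symmetrized Kovatchev/Magni blood-glucose risk index: it vanishes near
112.5 mg/dl (euglycemia) and grows toward both hypo- and hyperglycemia, so the
clipped, rescaled reward peaks at ~1 in range and saturates at -1 at both
extremes.  ``c0`` multiplies the whole bracket ``((ln b)^c1 - c2)`` — the
convention of the original risk-index literature; the alternative literal
grouping ``(c0*(ln b)^c1 - c2)^2`` is available via ``literal_grouping`` for
sensitivity analysis.

Rewards at timeslots with missing glucose are undefined: they are masked
(``None``), never imputed, and excluded from daily sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import mgdl_from_mmol

__all__ = ["RewardParams", "DEFAULT_REWARD_PARAMS", "clip", "magni_reward", "wtr_label",
           "daily_reward", "reward_from_mmol"]


@dataclass(frozen=True)
class RewardParams:
    c0: float = 1.509
    c1: float = 1.084
    c2: float = 5.381
    clip_lo: float = 0.0
    clip_hi: float = 15.5
    scale: float = 7.75
    hypo_cut: float = 70.0  # mg/dl
    wtr_lo: float = 3.9  # mmol/L
    wtr_hi: float = 10.0  # mmol/L
    literal_grouping: bool = False

    def __post_init__(self):
        if self.clip_lo >= self.clip_hi:
            raise ValueError("clip_lo must be < clip_hi")
        if self.wtr_lo >= self.wtr_hi:
            raise ValueError("wtr_lo must be < wtr_hi")


DEFAULT_REWARD_PARAMS = RewardParams()


def clip(x, lo: float, hi: float):
    """min(hi, max(lo, x))."""
    if lo > hi:
        raise ValueError(f"clip bounds inverted: {lo} > {hi}")
    return np.minimum(hi, np.maximum(lo, x))


def magni_reward(b, params: RewardParams = DEFAULT_REWARD_PARAMS):
    """Per-measurement reward in [-1, 1] from glucose ``b`` in mg/dl (scalar or array)."""
    arr = np.asarray(b, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("glucose must be > 0 mg/dl")
    # below hypo_cut the output is -1 regardless; keep ln >= 0 so the
    # fractional power is defined everywhere
    ln = np.log(np.maximum(arr, 1.0))
    if params.literal_grouping:
        risk = 10.0 * (params.c0 * ln**params.c1 - params.c2) ** 2
    else:
        risk = 10.0 * (params.c0 * (ln**params.c1 - params.c2)) ** 2
    out = 1.0 - clip(risk, params.clip_lo, params.clip_hi) / params.scale
    out = np.where(arr < params.hypo_cut, -1.0, out)
    return float(out) if np.isscalar(b) or np.ndim(b) == 0 else out


def wtr_label(g_mmol, params: RewardParams = DEFAULT_REWARD_PARAMS):
    """True iff glucose (mmol/L) is within the 3.9–10.0 target range, bounds inclusive."""
    arr = np.asarray(g_mmol, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("glucose must be > 0 mmol/L")
    out = (arr >= params.wtr_lo) & (arr <= params.wtr_hi)
    return bool(out) if np.ndim(g_mmol) == 0 else out


def daily_reward(rewards_of_day: Sequence[float]) -> float:
    """Sum of a day's per-measurement rewards (used for daily outcome analysis)."""
    vals = [r for r in rewards_of_day]
    if not vals:
        raise ValueError("daily_reward requires at least one reward")
    return float(np.sum(vals))


def reward_from_mmol(g_mmol: float | None, params: RewardParams = DEFAULT_REWARD_PARAMS) -> float | None:
    """Reward for a glucose value in mmol/L; ``None`` stays ``None`` (masked slot)."""
    if g_mmol is None:
        return None
    return float(magni_reward(mgdl_from_mmol(g_mmol), params))
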