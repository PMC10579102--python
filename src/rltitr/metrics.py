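"""Evaluation statistics for dosing and glycemic control.

Dose metrics: mean absolute error against a reference, and the two
agreement categories used to compare dose *adjustments* — "identical"
(same direction, same magnitude) and "clinical" (same direction, dose
difference within 20% of the reference).

Glycemic metrics: fractions of measurements in the standard bands
(<3.0, 3.0–3.8, 3.9–10.0, 10.1–13.9, >13.9 mmol/L, the middle band being
the within-target-range/time-in-range fraction), the coefficient of
variation (100·sd/mean, sample sd), the Noisy-OR aggregation of per-slot
WTR probabilities into a daily probability, and the association between
daily dose excess (given minus recommended) and daily WTR ratio.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "mae",
    "AgreementCategory",
    "agreement",
    "agreement_rates",
    "BAND_EDGES",
    "band_fractions",
    "glycemic_cv",
    "noisy_or_daily_wtr",
    "daily_wtr_ratio",
    "dose_excess_outcome",
]


def mae(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute error between aligned sequences."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred and truth must be non-empty and aligned")
    return float(np.mean(np.abs(p - t)))


#: Agreement categories; an identical match also satisfies the clinical criterion.
AgreementCategory = str  # "identical" | "clinical" | "none"


def agreement(pred_delta: float, ref_delta: float) -> AgreementCategory:
    """Categorize a predicted dose adjustment against the reference adjustment.

    identical: same direction and same magnitude (both zero counts);
    clinical:  same direction and |pred - ref| <= 0.2 |ref|;
    none:      otherwise (including a nonzero prediction against a zero
               reference — directions cannot agree with no adjustment).
    """
    if pred_delta == ref_delta:
        return "identical"
    if ref_delta == 0 or np.sign(pred_delta) != np.sign(ref_delta):
        return "none"
    if abs(pred_delta - ref_delta) <= 0.2 * abs(ref_delta):
        return "clinical"
    return "none"


def agreement_rates(pred_deltas: Sequence[float], ref_deltas: Sequence[float]) -> dict:
    """Fractions of identical and clinical agreement over aligned adjustment pairs
    (identical matches count toward the clinical rate, as identical ⊆ clinical)."""
    cats = [agreement(p, r) for p, r in zip(pred_deltas, ref_deltas)]
    n = len(cats)
    if n == 0:
        raise ValueError("no adjustment pairs supplied")
    identical = sum(c == "identical" for c in cats) / n
    clinical = sum(c in ("identical", "clinical") for c in cats) / n
    return {"identical": identical, "clinical": clinical, "n": n}


BAND_EDGES = (3.0, 3.9, 10.0, 13.9)  # mmol/L
BAND_LABELS = ("<3.0", "3.0-3.8", "3.9-10.0", "10.1-13.9", ">13.9")


def band_fractions(glucose: Sequence[float]) -> dict[str, float]:
    """Fractions of glucose values (mmol/L) in the five standard bands; the
    3.9-10.0 band is the within-target-range fraction."""
    g = np.asarray(glucose, dtype=float)
    if g.size == 0:
        raise ValueError("band_fractions requires at least one value")
    counts = np.array([
        np.sum(g < BAND_EDGES[0]),
        np.sum((g >= BAND_EDGES[0]) & (g < BAND_EDGES[1])),
        np.sum((g >= BAND_EDGES[1]) & (g <= BAND_EDGES[2])),
        np.sum((g > BAND_EDGES[2]) & (g <= BAND_EDGES[3])),
        np.sum(g > BAND_EDGES[3]),
    ])
    fractions = counts / g.size
    return dict(zip(BAND_LABELS, fractions.tolist()))


def glycemic_cv(glucose: Sequence[float]) -> float:
    """Glycemic variability as the coefficient of variation, 100·sd/mean
    (sample sd, n-1 denominator)."""
    g = np.asarray(glucose, dtype=float)
    if g.size < 2:
        raise ValueError("CV requires at least two values")
    mean = g.mean()
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    return float(100.0 * g.std(ddof=1) / mean)


def noisy_or_daily_wtr(point_probs: Sequence[float], all_points_mode: bool = False) -> float:
    """Aggregate per-slot WTR probabilities into a daily probability.

    Default is the Noisy-OR form 1 - prod(1 - p_i); ``all_points_mode``
    gives the conjunctive prod(p_i) (probability every point is in range).
    """
    p = np.asarray(point_probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if all_points_mode:
        return float(np.prod(p))
    return float(1.0 - np.prod(1.0 - p))


def daily_wtr_ratio(glucose: Sequence[float | None], lo: float = 3.9, hi: float = 10.0) -> float:
    """Fraction of a day's *measured* glucose values within [lo, hi] mmol/L."""
    vals = [g for g in glucose if g is not None]
    if not vals:
        raise ValueError("no measured glucose values")
    arr = np.asarray(vals, dtype=float)
    return float(np.mean((arr >= lo) & (arr <= hi)))


def dose_excess_outcome(
    pairs: Sequence[tuple[float, float]],
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Association between daily dose excess (given − recommended, units) and
    daily WTR ratio: per integer-unit excess bin, the mean WTR ratio with a
    bootstrap 95% CI and the bin count."""
    if not pairs:
        raise ValueError("no (excess, wtr) pairs supplied")
    rng = np.random.default_rng(seed)
    bins: dict[int, list[float]] = defaultdict(list)
    for excess, wtr in pairs:
        bins[int(np.floor(excess + 0.5))].append(float(wtr))
    rows = []
    for b in sorted(bins):
        vals = np.asarray(bins[b])
        if len(vals) > 1:
            boots = rng.choice(vals, size=(n_boot, len(vals)), replace=True).mean(axis=1)
            lo_ci, hi_ci = np.percentile(boots, [2.5, 97.5])
        else:
            lo_ci = hi_ci = vals.mean()
        rows.append({"excess": b, "mean_wtr": float(vals.mean()),
                     "ci_lo": float(lo_ci), "ci_hi": float(hi_ci), "n": len(vals)})
    return pd.DataFrame(rows)
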