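"""Traditional (guideline/consensus) insulin titration rules.

Three piecewise rule sets over capillary glucose in mg/dl, used as standard
clinical comparators for the learned policy:

* premixed regimen — the pre-breakfast dose is adjusted on the pre-supper
  glucose and the pre-supper dose on the pre-breakfast glucose, by the
  five-branch table (-2 / 0 / +2 / +4 / +6 units);
* basal-only regimen — the basal dose is adjusted on the pre-breakfast or
  fasting glucose with the same five-branch table;
* basal-bolus regimen — the basal dose rises 20% per day while fasting/mean
  glucose exceeds 140 mg/dl without hypoglycemia, falls 20% after any
  hypoglycemic reading (< 70 mg/dl, which takes precedence), and a
  supplemental bolus is read off a seven-branch post-meal table
  (4..16 units from 141 up through > 400 mg/dl; no change at <= 140).

The tables operate strictly in mg/dl; mmol/L inputs must be converted
through :func:`rltitr.data_model.mgdl_from_mmol` first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Trajectory, mgdl_from_mmol

__all__ = [
    "TitrationDecision",
    "premixed_adjust",
    "basal_adjust",
    "bolus_supplement",
    "basal_bolus_adjust",
    "daily_adjustments",
]


@dataclass(frozen=True)
class TitrationDecision:
    slot: int
    insulin_class: str
    delta_units: int  # signed adjustment, or absolute bolus supplement
    rule_fired: str


def _five_branch(x: float) -> int:
    if x <= 0:
        raise ValueError("glucose must be > 0 mg/dl")
    if x < 80:
        return -2
    if x <= 109:
        return 0
    if x <= 139:
        return 2
    if x <= 179:
        return 4
    return 6


def premixed_adjust(x: float) -> int:
    """Signed dose adjustment (units) for the premixed regimen; ``x`` is the
    corresponding glucose in mg/dl (pre-supper for the morning dose and
    pre-breakfast for the evening dose)."""
    return _five_branch(x)


def basal_adjust(x: float) -> int:
    """Signed basal dose adjustment (units) from pre-breakfast/fasting glucose
    in mg/dl; same five-branch table as the premixed rule."""
    return _five_branch(x)


def bolus_supplement(x: float) -> int:
    """Supplemental bolus dose (units) from post-meal glucose in mg/dl.

    The table starts at 141 mg/dl; at or below 140 no supplement is given.
    """
    if x <= 0:
        raise ValueError("glucose must be > 0 mg/dl")
    if x <= 140:
        return 0
    if x <= 180:
        return 4
    if x <= 220:
        return 6
    if x <= 260:
        return 8
    if x <= 300:
        return 10
    if x <= 350:
        return 12
    if x <= 400:
        return 14
    return 16


def basal_bolus_adjust(
    fasting_or_mean: float,
    hypo_event: bool,
    current_basal: int,
    postmeal: float | None = None,
) -> tuple[int, int]:
    """Daily basal-bolus update: (new basal dose, bolus supplement).

    Basal moves x1.2 when fasting/mean glucose > 140 mg/dl without
    hypoglycemia and x0.8 after a hypoglycemic day (hypoglycemia takes
    precedence when both hold); the result is rounded half-away-from-zero
    and clamped to [1, 40] units.  The bolus supplement comes from the
    post-meal table (0 when no post-meal value is supplied).
    """
    if current_basal <= 0:
        raise ValueError("current basal dose must be positive")
    if hypo_event:
        new_basal = current_basal * 0.8
    elif fasting_or_mean > 140:
        new_basal = current_basal * 1.2
    else:
        new_basal = float(current_basal)
    new_basal = int(np.clip(np.floor(new_basal + 0.5), 1, 40))
    supplement = bolus_supplement(postmeal) if postmeal is not None else 0
    return new_basal, supplement


def daily_adjustments(traj: Trajectory, regimen: str) -> list[dict]:
    """Per-day guideline recommendations for a logged trajectory.

    For each day after the first, applies the regimen's rule set to the
    previous day's measured glucose (converted to mg/dl) and reports the
    adjustments relative to the previous day's doses.
    """
    by_day: dict[int, dict[int, float]] = {}
    doses_by_day: dict[int, dict[int, int]] = {}
    for o, a in zip(traj.observations, traj.actions):
        if o.measured:
            by_day.setdefault(o.day, {})[o.slot] = float(mgdl_from_mmol(o.glucose_mmol))
        if a.is_injection:
            doses_by_day.setdefault(o.day, {})[o.slot] = a.dose_units
    out: list[dict] = []
    days = sorted(by_day)
    for day in days[1:]:
        prev = by_day.get(day - 1, {})
        if not prev:
            continue
        if regimen == "premixed":
            if 4 in prev:  # pre-supper value adjusts the morning dose
                out.append({"day": day, "slot": 0, "insulin_class": "premixed",
                            "delta_units": premixed_adjust(prev[4]),
                            "rule": "premixed_from_presupper"})
            if 0 in prev:
                out.append({"day": day, "slot": 4, "insulin_class": "premixed",
                            "delta_units": premixed_adjust(prev[0]),
                            "rule": "premixed_from_prebreakfast"})
        elif regimen == "basal_only":
            if 0 in prev:
                out.append({"day": day, "slot": 6, "insulin_class": "long_acting",
                            "delta_units": basal_adjust(prev[0]),
                            "rule": "basal_from_fasting"})
        elif regimen == "basal_bolus":
            fasting = prev.get(0, float(np.mean(list(prev.values()))))
            hypo = any(v < 70.0 for v in prev.values())
            basal = doses_by_day.get(day - 1, {}).get(6)
            if basal is not None:
                new_basal, _ = basal_bolus_adjust(fasting, hypo, basal)
                out.append({"day": day, "slot": 6, "insulin_class": "long_acting",
                            "delta_units": new_basal - basal,
                            "rule": "basal_hypo" if hypo else "basal_pct"})
            for post_slot, inj_slot in ((1, 0), (3, 2), (5, 4)):
                if post_slot in prev:
                    out.append({"day": day, "slot": inj_slot,
                                "insulin_class": "short_rapid",
                                "delta_units": bolus_supplement(prev[post_slot]),
                                "rule": "bolus_table"})
        else:
            raise ValueError(f"unknown regimen {regimen!r}")
    return out
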