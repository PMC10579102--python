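"""Core data types for inpatient glucose/insulin trajectories.

A hospital day is divided into seven timeslots (pre/post each main meal plus
bedtime, the "seven-point profile").  A patient's stay is a :class:`Trajectory`
of per-slot observations (glucose in mmol/L, covariates), insulin actions
(class + integer dose in units) and Magni-risk rewards, forming the MDP
trajectory every other module consumes.

Conventions:

* "No injection" is a distinct action class (``"none"``), never dose 0 — the
  dose vocabulary starts at 1 U.
* Missing glucose is an explicit ``None`` carried through serialization as
  JSON ``null``; it is never imputed at the data layer.
* Glucose is stored in mmol/L; formulas that operate in mg/dl convert through
  :func:`mgdl_from_mmol` (factor 18.0182, molar-mass convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SLOT_LABELS",
    "N_SLOTS",
    "MGDL_PER_MMOL",
    "INSULIN_CLASSES",
    "Timeslot",
    "Observation",
    "DoseAction",
    "Transition",
    "Trajectory",
    "MDPConfig",
    "SchemaError",
    "ValidationError",
    "mgdl_from_mmol",
    "mmol_from_mgdl",
    "step_after",
    "read_trajectories",
    "write_trajectories",
]

SLOT_LABELS: tuple[str, ...] = (
    "pre-breakfast",
    "post-breakfast",
    "pre-lunch",
    "post-lunch",
    "pre-dinner",
    "post-dinner",
    "pre-bedtime",
)
N_SLOTS = 7

#: mg/dl per mmol/L of glucose (molar mass 180.182 g/mol).
MGDL_PER_MMOL = 18.0182

INSULIN_CLASSES = ("none", "short_rapid", "long_acting", "premixed")

DOSE_MIN, DOSE_MAX = 1, 40


class SchemaError(ValueError):
    """A file does not conform to the documented column/field schema."""


class ValidationError(ValueError):
    """A structurally valid record violates a trajectory invariant."""


def mgdl_from_mmol(g: float | np.ndarray) -> float | np.ndarray:
    """Convert glucose from mmol/L to mg/dl."""
    if np.any(np.asarray(g) < 0):
        raise ValueError("glucose must be non-negative")
    return g * MGDL_PER_MMOL


def mmol_from_mgdl(g: float | np.ndarray) -> float | np.ndarray:
    """Convert glucose from mg/dl to mmol/L."""
    if np.any(np.asarray(g) < 0):
        raise ValueError("glucose must be non-negative")
    return g / MGDL_PER_MMOL


@dataclass(frozen=True)
class Timeslot:
    """One of the seven daily measurement periods."""

    index: int

    def __post_init__(self):
        if not 0 <= self.index < N_SLOTS:
            raise ValueError(f"slot index must be in 0..{N_SLOTS - 1}, got {self.index}")

    @property
    def label(self) -> str:
        return SLOT_LABELS[self.index]


def step_after(day: int, slot: int, k: int) -> tuple[int, int]:
    """(day, slot) reached k timeslots after (day, slot) on the 7-slot grid."""
    total = N_SLOTS * day + slot + k
    return total // N_SLOTS, total % N_SLOTS


@dataclass(frozen=True)
class DoseAction:
    """An insulin action: class + integer dose in units, or explicit no-dose."""

    insulin_class: str = "none"
    dose_units: int | None = None

    def __post_init__(self):
        if self.insulin_class not in INSULIN_CLASSES:
            raise ValueError(f"unknown insulin class {self.insulin_class!r}")
        if self.insulin_class == "none":
            if self.dose_units is not None:
                raise ValueError("no-dose action must not carry dose_units")
        else:
            if self.dose_units is None or not DOSE_MIN <= int(self.dose_units) <= DOSE_MAX:
                raise ValueError(
                    f"dose_units must be in [{DOSE_MIN}, {DOSE_MAX}], got {self.dose_units}"
                )

    @property
    def is_injection(self) -> bool:
        return self.insulin_class != "none"


NO_DOSE = DoseAction()


@dataclass(frozen=True)
class Observation:
    """Per-slot observation: glucose (possibly missing) and covariates."""

    day: int
    slot: int
    glucose_mmol: float | None = None
    covariates: tuple[float, ...] = ()

    def __post_init__(self):
        if self.day < 1:
            raise ValueError("day numbering starts at 1")
        Timeslot(self.slot)
        g = self.glucose_mmol
        if g is not None and (not np.isfinite(g) or g <= 0):
            raise ValueError(f"glucose must be finite and > 0, got {g}")

    @property
    def measured(self) -> bool:
        return self.glucose_mmol is not None


@dataclass(frozen=True)
class Transition:
    """One (s_t, a_t, r_t) step referencing its position in a trajectory."""

    state_ref: int
    action: DoseAction
    reward: float | None

    def __post_init__(self):
        if self.reward is not None and not -1.0 <= self.reward <= 1.0:
            raise ValueError(f"reward must lie in [-1, 1], got {self.reward}")


@dataclass
class Trajectory:
    """A patient's aligned (observation, action, reward) sequence."""

    patient_id: str
    observations: list[Observation]
    actions: list[DoseAction]
    rewards: list[float | None]

    def __post_init__(self):
        self.validate()

    @property
    def tau(self) -> int:
        return len(self.observations)

    def __len__(self) -> int:
        return self.tau

    def validate(self):
        if not (len(self.observations) == len(self.actions) == len(self.rewards)):
            raise ValidationError(
                f"patient {self.patient_id}: observations/actions/rewards lengths differ"
            )
        prev = None
        cov_len = None
        for obs in self.observations:
            key = (obs.day, obs.slot)
            if prev is not None and key <= prev:
                raise ValidationError(
                    f"patient {self.patient_id}: timeslots not strictly increasing at {key}"
                )
            prev = key
            if cov_len is None:
                cov_len = len(obs.covariates)
            elif len(obs.covariates) != cov_len:
                raise ValidationError(
                    f"patient {self.patient_id}: covariate length varies within trajectory"
                )
        for r in self.rewards:
            if r is not None and not -1.0 <= r <= 1.0:
                raise ValidationError(
                    f"patient {self.patient_id}: reward {r} outside [-1, 1]"
                )

    def transitions(self) -> list[Transition]:
        return [Transition(t, a, r) for t, (a, r) in enumerate(zip(self.actions, self.rewards))]

    def with_glucose(self, values: Sequence[float | None], rewards: Sequence[float | None]) -> "Trajectory":
        """Copy with replaced glucose values and rewards (masks included)."""
        obs = [replace(o, glucose_mmol=v) for o, v in zip(self.observations, values)]
        return Trajectory(self.patient_id, obs, list(self.actions), list(rewards))


@dataclass(frozen=True)
class MDPConfig:
    """Action vocabulary size and discount of the dosing MDP."""

    n_actions: int = DOSE_MAX + 1  # no-dose token + doses 1..40
    gamma: float = 0.9

    def __post_init__(self):
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in (0, 1], got {self.gamma}")


# ---------------------------------------------------------------------------
# Interchange I/O
# ---------------------------------------------------------------------------


def _slot_record(obs: Observation, action: DoseAction, reward: float | None) -> dict:
    return {
        "day": obs.day,
        "slot": obs.slot,
        "glucose_mmol": obs.glucose_mmol,
        "action": (
            {"class": action.insulin_class, "dose": action.dose_units}
            if action.is_injection
            else None
        ),
        "reward": reward,
        "covariates": list(obs.covariates),
    }


def _parse_slot(rec: dict, patient_id: str, lineno: int) -> tuple[Observation, DoseAction, float | None]:
    try:
        obs = Observation(
            day=int(rec["day"]),
            slot=int(rec["slot"]),
            glucose_mmol=None if rec.get("glucose_mmol") is None else float(rec["glucose_mmol"]),
            covariates=tuple(float(c) for c in rec.get("covariates", ())),
        )
    except KeyError as e:
        raise SchemaError(f"line {lineno}: slot record missing field {e}") from e
    act = rec.get("action")
    action = NO_DOSE if act is None else DoseAction(act["class"], int(act["dose"]))
    reward = None if rec.get("reward") is None else float(rec["reward"])
    return obs, action, reward


def write_trajectories(trajs: Iterable[Trajectory], path, format: str = "jsonl") -> None:
    """Serialize trajectories; jsonl is canonical, csv a long-format convenience."""
    path = Path(path)
    trajs = list(trajs)
    if format == "jsonl":
        with open(path, "w") as fh:
            for traj in trajs:
                doc = {
                    "patient_id": traj.patient_id,
                    "slots": [
                        _slot_record(o, a, r)
                        for o, a, r in zip(traj.observations, traj.actions, traj.rewards)
                    ],
                }
                fh.write(json.dumps(doc) + "\n")
    elif format == "csv":
        rows = []
        for traj in trajs:
            for o, a, r in zip(traj.observations, traj.actions, traj.rewards):
                row = {
                    "patient_id": traj.patient_id,
                    "day": o.day,
                    "slot": o.slot,
                    "glucose_mmol": o.glucose_mmol,
                    "insulin_class": a.insulin_class,
                    "dose_units": a.dose_units,
                    "reward": r,
                }
                for i, c in enumerate(o.covariates):
                    row[f"cov_{i}"] = c
                rows.append(row)
        cols = ["patient_id", "day", "slot", "glucose_mmol", "insulin_class", "dose_units", "reward"]
        if rows:
            cols += [c for c in rows[0] if c.startswith("cov_")]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_trajectories(path, format: str | None = None) -> list[Trajectory]:
    """Read trajectories from a jsonl or csv cohort file (format inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "jsonl"
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_jsonl(path: Path) -> list[Trajectory]:
    trajs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                doc = json.loads(line)
            except json.JSONDecodeError as e:
                raise SchemaError(f"line {lineno}: invalid JSON ({e})") from e
            if "patient_id" not in doc or "slots" not in doc:
                raise SchemaError(f"line {lineno}: record requires patient_id and slots")
            obs, actions, rewards = [], [], []
            for rec in doc["slots"]:
                o, a, r = _parse_slot(rec, doc["patient_id"], lineno)
                obs.append(o)
                actions.append(a)
                rewards.append(r)
            trajs.append(Trajectory(str(doc["patient_id"]), obs, actions, rewards))
    return trajs


def _read_csv(path: Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    required = {"patient_id", "day", "slot", "glucose_mmol", "insulin_class", "dose_units", "reward"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"csv missing required columns: {sorted(missing)}")
    cov_cols = sorted(
        (c for c in df.columns if c.startswith("cov_")), key=lambda c: int(c.split("_")[1])
    )
    trajs = []
    for pid, group in df.groupby("patient_id", sort=False):
        obs, actions, rewards = [], [], []
        for _, row in group.iterrows():
            obs.append(
                Observation(
                    day=int(row["day"]),
                    slot=int(row["slot"]),
                    glucose_mmol=None if pd.isna(row["glucose_mmol"]) else float(row["glucose_mmol"]),
                    covariates=tuple(float(row[c]) for c in cov_cols),
                )
            )
            if isinstance(row["insulin_class"], str) and row["insulin_class"] != "none":
                actions.append(DoseAction(row["insulin_class"], int(row["dose_units"])))
            else:
                actions.append(NO_DOSE)
            rewards.append(None if pd.isna(row["reward"]) else float(row["reward"]))
        trajs.append(Trajectory(str(pid), obs, actions, rewards))
    return trajs
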