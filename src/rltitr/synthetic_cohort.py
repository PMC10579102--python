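"""Synthetic inpatient cohort generator with known ground-truth insulin response.

Real inpatient EHR cohorts for this problem are not shareable, so every
learning and evaluation stage is exercised against a seeded simulator that
emulates their structure: seven glucose timeslots per day, at least two
treatment days, three insulin regimen families, dose-dependent glucose
response, inter-patient heterogeneity in insulin sensitivity, and optional
missingness/noise degradation.

Response model (per timeslot t, slot = t mod 7, all glucose in mmol/L)::

    g[t] = basal_glucose + meal_effect(slot) - insulin_sensitivity * E[t] + noise

where ``E[t]`` accumulates the effective dose reaching slot t under minimal
class kinetics:

* short/rapid-acting: the full dose acts on the immediately following slot;
* long-acting (bedtime): the dose acts uniformly on each of the next seven
  slots, i.e. it depresses glucose throughout the following day;
* premixed: half the dose acts on the next slot (prandial component) and
  half uniformly on each of the next seven slots (basal component).

Meal rises apply at the three post-meal slots.  Insulin sensitivity varies
across patients (log-normal, modulated by one covariate so static features
are informative), making dosing genuinely patient-specific.

Each patient carries *oracle doses*: the integer doses (1–40 U) minimizing
squared deviation of steady-state glucose from the 6.5 mmol/L target.  The
logged behavior policy emulates bedside practice with therapeutic inertia:
it starts conservatively below the oracle (default −6 U bias, 3 U jitter) and
titrates each injection daily by the five-branch guideline step applied to
the previous day's glucose at the affected slot, plus discrete jitter.  The
log therefore contains genuine within-patient dose-response variation (so a
dynamics model can identify individual insulin sensitivity) while remaining
deliberately sub-optimal on average, so improvement by reinforcement
learning over pure imitation is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data_model import (
    MGDL_PER_MMOL,
    N_SLOTS,
    DoseAction,
    NO_DOSE,
    Observation,
    Trajectory,
)
from .reward import RewardParams, DEFAULT_REWARD_PARAMS, reward_from_mmol

__all__ = [
    "REGIMEN_SCHEDULES",
    "PatientLatents",
    "CohortConfig",
    "generate_cohort",
    "generate_patient",
    "degrade_trajectory",
    "add_observation_noise",
    "simulate_policy",
    "response_glucose",
]

#: Injection slots and insulin class per regimen family.
REGIMEN_SCHEDULES: dict[str, dict[int, str]] = {
    "premixed": {0: "premixed", 4: "premixed"},
    "basal_only": {6: "long_acting"},
    "basal_bolus": {0: "short_rapid", 2: "short_rapid", 4: "short_rapid", 6: "long_acting"},
}

POST_MEAL_SLOTS = {1: 0, 3: 1, 5: 2}  # slot -> meal index (breakfast, lunch, dinner)

GLUCOSE_FLOOR = 1.5  # mmol/L; physiological floor of the response model


@dataclass(frozen=True)
class PatientLatents:
    """Ground-truth generative parameters of one synthetic patient."""

    insulin_sensitivity: float  # mmol/L drop per effective unit
    basal_glucose: float  # mmol/L
    meal_effect: tuple[float, float, float]  # mmol/L rise per meal
    noise_sd: float  # mmol/L
    regimen: str
    oracle_doses: dict[int, int]  # slot -> dose minimizing deviation from target
    covariates: tuple[float, ...]


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 200
    n_days: int = 5
    regimen_mix: dict[str, float] = field(
        default_factory=lambda: {"premixed": 0.4, "basal_only": 0.3, "basal_bolus": 0.3}
    )
    basal_glucose_mean: float = 10.5
    basal_glucose_sd: float = 1.5
    sensitivity_median: float = 0.30
    sensitivity_log_sd: float = 0.25
    meal_effect_mean: float = 2.5
    meal_effect_sd: float = 0.5
    noise_sd: float = 0.3
    behavior_bias: float = -6.0  # conservative day-1 under-dosing of the logged policy
    behavior_jitter_sd: float = 3.0
    behavior_titrate: bool = True  # daily guideline-step feedback titration
    target_glucose: float = 6.5  # mmol/L, oracle dosing target
    cov_dim: int = 6
    seed: int = 0

    def __post_init__(self):
        total = sum(self.regimen_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"regimen_mix proportions must sum to 1, got {total}")
        if any(k not in REGIMEN_SCHEDULES for k in self.regimen_mix):
            raise ValueError(f"unknown regimen in mix: {sorted(self.regimen_mix)}")
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2 (patients treated < 2 days are excluded)")


# ---------------------------------------------------------------------------
# Response model
# ---------------------------------------------------------------------------


def _effect_profile(doses: dict[tuple[int, int], tuple[str, int]], n_steps: int) -> np.ndarray:
    """Effective units reaching each timeslot, from injections keyed by (day, slot)."""
    effect = np.zeros(n_steps + N_SLOTS + 1)
    for (day, slot), (cls, dose) in doses.items():
        t = (day - 1) * N_SLOTS + slot
        if cls == "short_rapid":
            effect[t + 1] += dose
        elif cls == "long_acting":
            effect[t + 1 : t + 1 + N_SLOTS] += dose
        elif cls == "premixed":
            effect[t + 1] += dose / 2.0
            effect[t + 1 : t + 1 + N_SLOTS] += dose / 2.0
        else:
            raise ValueError(f"unknown insulin class {cls!r}")
    return effect[:n_steps]


def response_glucose(
    latents: PatientLatents,
    doses: dict[tuple[int, int], tuple[str, int]],
    n_days: int,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Glucose at every timeslot of ``n_days`` under the documented response model."""
    n_steps = n_days * N_SLOTS
    effect = _effect_profile(doses, n_steps)
    slots = np.arange(n_steps) % N_SLOTS
    meal = np.zeros(n_steps)
    for slot, meal_idx in POST_MEAL_SLOTS.items():
        meal[slots == slot] = latents.meal_effect[meal_idx]
    g = latents.basal_glucose + meal - latents.insulin_sensitivity * effect
    sd = latents.noise_sd if noise_sd is None else noise_sd
    if rng is not None and sd > 0:
        g = g + rng.normal(0.0, sd, size=n_steps)
    return np.maximum(g, GLUCOSE_FLOOR)


def _steady_day(latents: PatientLatents, doses_per_slot: dict[int, tuple[str, int]]) -> np.ndarray:
    """Steady-state glucose over one day when the same doses repeat daily."""
    doses = {(d, s): cd for d in (1, 2, 3) for s, cd in doses_per_slot.items()}
    g = response_glucose(latents, doses, 3)
    return g[2 * N_SLOTS :]


def _oracle_doses(latents: PatientLatents, target: float) -> dict[int, int]:
    """Brute-force steady-state dose choice, documented two-stage rule.

    Premixed patients take an equal dose at both injections; basal-bolus
    patients get the basal chosen first against the no-meal slots, then each
    bolus against its own post-meal slot (boluses act on a single slot, so
    they decouple given the basal).
    """
    schedule = REGIMEN_SCHEDULES[latents.regimen]

    def sse(doses_per_slot, eval_slots):
        g = _steady_day(latents, doses_per_slot)
        return float(np.sum((g[list(eval_slots)] - target) ** 2))

    if latents.regimen == "premixed":
        best = min(
            range(1, 41),
            key=lambda d: (sse({0: ("premixed", d), 4: ("premixed", d)}, range(N_SLOTS)), d),
        )
        return {0: best, 4: best}
    if latents.regimen == "basal_only":
        best = min(range(1, 41), key=lambda d: (sse({6: ("long_acting", d)}, range(N_SLOTS)), d))
        return {6: best}
    # basal_bolus
    basal = min(range(1, 41), key=lambda d: (sse({6: ("long_acting", d)}, (0, 2, 4, 6)), d))
    doses = {6: basal}
    for slot in (0, 2, 4):
        current = {s: (schedule[s], d) for s, d in doses.items()}
        bolus = min(
            range(1, 41),
            key=lambda d: (sse({**current, slot: ("short_rapid", d)}, (slot + 1,)), d),
        )
        doses[slot] = bolus
    return {s: doses[s] for s in sorted(doses)}


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _draw_latents(cfg: CohortConfig, rng: np.random.Generator, regimen: str) -> PatientLatents:
    cov = rng.normal(0.0, 1.0, size=cfg.cov_dim)
    if cfg.cov_dim > 0:
        cov[-1] = float(rng.integers(0, 2))  # one binary presence flag (e.g. sex)
    sens_mod = 0.25 * cov[0] if cfg.cov_dim > 0 else 0.0
    sensitivity = cfg.sensitivity_median * np.exp(
        rng.normal(0.0, cfg.sensitivity_log_sd) + sens_mod
    )
    basal = max(7.0, rng.normal(cfg.basal_glucose_mean, cfg.basal_glucose_sd))
    meals = tuple(
        float(max(0.5, rng.normal(cfg.meal_effect_mean, cfg.meal_effect_sd))) for _ in range(3)
    )
    lat = PatientLatents(
        insulin_sensitivity=float(sensitivity),
        basal_glucose=float(basal),
        meal_effect=meals,
        noise_sd=cfg.noise_sd,
        regimen=regimen,
        oracle_doses={},
        covariates=tuple(np.round(cov, 6)),
    )
    oracle = _oracle_doses(lat, cfg.target_glucose)
    return PatientLatents(
        lat.insulin_sensitivity, lat.basal_glucose, lat.meal_effect, lat.noise_sd,
        regimen, oracle, lat.covariates,
    )


def _titration_ref_slot(cls: str, slot: int) -> int:
    """Slot whose previous-day glucose steers the daily adjustment of an
    injection: the covered post-meal slot for boluses, fasting for basal,
    and the opposite end of the day for premixed (guideline convention)."""
    if cls == "short_rapid":
        return slot + 1
    if cls == "long_acting":
        return 0
    return 4 if slot == 0 else 0  # premixed


def _guideline_step(g_mgdl: float) -> int:
    if g_mgdl < 80:
        return -2
    if g_mgdl <= 109:
        return 0
    if g_mgdl <= 139:
        return 2
    if g_mgdl <= 179:
        return 4
    return 6


def generate_patient(
    cfg: CohortConfig,
    latents: PatientLatents,
    rng: np.random.Generator,
    patient_id: str,
    reward_params: RewardParams = DEFAULT_REWARD_PARAMS,
) -> Trajectory:
    """Simulate one patient under the conservative feedback-titration behavior
    policy (day-1 bias below oracle, daily guideline steps thereafter)."""
    schedule = REGIMEN_SCHEDULES[latents.regimen]
    doses: dict[tuple[int, int], tuple[str, int]] = {}
    prev_dose: dict[int, int] = {}
    g = np.zeros(cfg.n_days * N_SLOTS)
    for day in range(1, cfg.n_days + 1):
        for slot, cls in sorted(schedule.items()):
            if day == 1 or not cfg.behavior_titrate:
                jitter = rng.normal(cfg.behavior_bias, cfg.behavior_jitter_sd)
                dose = int(np.clip(latents.oracle_doses[slot] + round(jitter), 1, 40))
            else:
                ref = _titration_ref_slot(cls, slot)
                g_ref = g[(day - 2) * N_SLOTS + ref]
                step = _guideline_step(g_ref * MGDL_PER_MMOL)
                dose = int(np.clip(
                    prev_dose[slot] + step + round(rng.normal(0.0, 1.0)), 1, 40
                ))
            doses[(day, slot)] = (cls, dose)
            prev_dose[slot] = dose
        clean = response_glucose(latents, doses, day)
        lo, hi = (day - 1) * N_SLOTS, day * N_SLOTS
        day_g = clean[lo:hi]
        if latents.noise_sd > 0:
            day_g = np.maximum(
                day_g + rng.normal(0.0, latents.noise_sd, size=N_SLOTS), GLUCOSE_FLOOR
            )
        g[lo:hi] = day_g
    obs, actions, rewards = [], [], []
    for t in range(cfg.n_days * N_SLOTS):
        day, slot = t // N_SLOTS + 1, t % N_SLOTS
        value = float(np.round(g[t], 4))
        obs.append(Observation(day, slot, value, latents.covariates))
        cd = doses.get((day, slot))
        actions.append(DoseAction(cd[0], cd[1]) if cd else NO_DOSE)
        rewards.append(reward_from_mmol(value, reward_params))
    return Trajectory(patient_id, obs, actions, rewards)


def generate_cohort(
    cfg: CohortConfig, reward_params: RewardParams = DEFAULT_REWARD_PARAMS
) -> tuple[list[Trajectory], list[PatientLatents]]:
    """Deterministically generate a cohort; all randomness flows from ``cfg.seed``
    through per-patient substreams."""
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_patients + 1)
    assign_rng = np.random.default_rng(streams[0])
    names = sorted(cfg.regimen_mix)
    probs = np.array([cfg.regimen_mix[k] for k in names])
    regimens = assign_rng.choice(names, size=cfg.n_patients, p=probs)
    trajs, latents = [], []
    for i in range(cfg.n_patients):
        rng = np.random.default_rng(streams[i + 1])
        lat = _draw_latents(cfg, rng, str(regimens[i]))
        trajs.append(generate_patient(cfg, lat, rng, f"synth-{i:04d}", reward_params))
        latents.append(lat)
    return trajs, latents


# ---------------------------------------------------------------------------
# Degraded-data simulation
# ---------------------------------------------------------------------------


def degrade_trajectory(traj: Trajectory, max_glucose_per_day: int, seed: int) -> Trajectory:
    """Randomly discard glucose so no day keeps more than ``max_glucose_per_day``
    measurements; actions and covariates are untouched."""
    if max_glucose_per_day < 0:
        raise ValueError("max_glucose_per_day must be >= 0")
    rng = np.random.default_rng(seed)
    by_day: dict[int, list[int]] = {}
    for i, o in enumerate(traj.observations):
        if o.measured:
            by_day.setdefault(o.day, []).append(i)
    keep: set[int] = set()
    for day in sorted(by_day):
        idx = by_day[day]
        if len(idx) <= max_glucose_per_day:
            keep.update(idx)
        else:
            chosen = rng.choice(len(idx), size=max_glucose_per_day, replace=False)
            keep.update(idx[j] for j in chosen)
    values = [
        (o.glucose_mmol if i in keep else None) for i, o in enumerate(traj.observations)
    ]
    rewards = [(r if i in keep else None) for i, r in enumerate(traj.rewards)]
    return traj.with_glucose(values, rewards)


def add_observation_noise(
    traj: Trajectory, sd: float, seed: int,
    reward_params: RewardParams = DEFAULT_REWARD_PARAMS,
) -> Trajectory:
    """Add i.i.d. N(0, sd²) measurement noise to measured glucose (0.1 mmol/L floor);
    masked slots stay masked and rewards are recomputed from the noisy values."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    values, rewards = [], []
    for o in traj.observations:
        if o.glucose_mmol is None:
            values.append(None)
            rewards.append(None)
        else:
            v = max(0.1, o.glucose_mmol + (rng.normal(0.0, sd) if sd > 0 else 0.0))
            values.append(float(v))
            rewards.append(reward_from_mmol(float(v), reward_params))
    return traj.with_glucose(values, rewards)


# ---------------------------------------------------------------------------
# On-policy simulation (the ground-truth environment for policy evaluation)
# ---------------------------------------------------------------------------

PolicyFn = Callable[[Trajectory, int, int, str], int]


def simulate_policy(
    latents: PatientLatents,
    policy_fn: PolicyFn,
    n_days: int,
    seed: int,
    noise_sd: float | None = None,
    patient_id: str = "sim",
    reward_params: RewardParams = DEFAULT_REWARD_PARAMS,
) -> Trajectory:
    """Roll the true response model forward under an arbitrary dosing policy.

    ``policy_fn(partial_trajectory, day, slot, insulin_class) -> dose`` is
    queried at each scheduled injection slot after that slot's glucose has
    been observed, mirroring bedside decision timing.
    """
    schedule = REGIMEN_SCHEDULES[latents.regimen]
    rng = np.random.default_rng(seed)
    sd = latents.noise_sd if noise_sd is None else noise_sd
    doses: dict[tuple[int, int], tuple[str, int]] = {}
    obs: list[Observation] = []
    actions: list[DoseAction] = []
    rewards: list[float | None] = []
    n_steps = n_days * N_SLOTS
    for t in range(n_steps):
        day, slot = t // N_SLOTS + 1, t % N_SLOTS
        effect = _effect_profile(doses, t + 1)[t]
        meal = latents.meal_effect[POST_MEAL_SLOTS[slot]] if slot in POST_MEAL_SLOTS else 0.0
        g = latents.basal_glucose + meal - latents.insulin_sensitivity * effect
        if sd > 0:
            g += rng.normal(0.0, sd)
        g = float(np.round(max(g, GLUCOSE_FLOOR), 4))
        obs.append(Observation(day, slot, g, latents.covariates))
        rewards.append(reward_from_mmol(g, reward_params))
        if slot in schedule:
            partial = Trajectory(patient_id, list(obs), list(actions) + [NO_DOSE],
                                 list(rewards))
            cls = schedule[slot]
            dose = int(np.clip(policy_fn(partial, day, slot, cls), 1, 40))
            actions.append(DoseAction(cls, dose))
            doses[(day, slot)] = (cls, dose)
        else:
            actions.append(NO_DOSE)
    return Trajectory(patient_id, obs, actions, rewards)


def oracle_policy_fn(latents: PatientLatents) -> PolicyFn:
    """The generative oracle as a policy (upper reference in simulator studies)."""

    def fn(_traj, _day, slot, _cls):
        return latents.oracle_doses[slot]

    return fn
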