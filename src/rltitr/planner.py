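"""K-step decision-time planning over the learned patient model via beam search.

From a hidden state s_t the planner expands candidate dose sequences through
the dynamics function, scoring a partial sequence by its accumulated
discounted model reward plus a terminal value bootstrap, and keeps the top-B
partial plans at every step.  A complete K-step plan is valued as

    v = sum_{i=0}^{K-1} gamma^i r_{t+i}  +  gamma^K V(s_{t+K})

and the highest-value plan is returned.  Candidate doses at an injection slot
are either the policy's top-M tokens (default, M=5) or the full vocabulary;
slots where the regimen schedule prescribes no injection are forced to the
no-dose action.  Equal-value plans break ties toward the lexicographically
smaller dose sequence (a safety bias toward less insulin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import N_SLOTS, DoseAction, NO_DOSE, Trajectory
from .patient_model import CLASS_INDEX, N_ACTION_TOKENS, PatientModel
from .policy_model import PolicyModel, infer_schedule

__all__ = ["PlanConfig", "Plan", "plan", "recommend_day"]


@dataclass(frozen=True)
class PlanConfig:
    K: int = 7
    B: int = 10
    gamma: float = 0.9
    candidates: int = 5  # top-M policy proposals per expansion
    expand_all: bool = False  # propose every dose token instead

    def __post_init__(self):
        if self.K < 1 or self.B < 1:
            raise ValueError("plan horizon K and beam size B must be >= 1")
        if self.candidates < 1:
            raise ValueError("candidate count must be >= 1")


@dataclass
class Plan:
    actions: list[DoseAction]
    value: float
    rewards: list[float]
    states: list[np.ndarray] = field(repr=False, default_factory=list)
    terminal_value: float = 0.0

    def recompute_value(self, gamma: float) -> float:
        v = sum(gamma**i * r for i, r in enumerate(self.rewards))
        return float(v + gamma ** len(self.rewards) * self.terminal_value)


def _candidate_tokens(policy: PolicyModel, state: np.ndarray, cfg: PlanConfig) -> list[int]:
    if cfg.expand_all:
        return list(range(1, N_ACTION_TOKENS))
    mask = np.zeros(N_ACTION_TOKENS, dtype=bool)
    mask[1:] = True
    p = policy.action_probs(state, mask)
    top = np.argsort(-p, kind="stable")[: cfg.candidates]
    return sorted(int(t) for t in top if t > 0)


def plan(
    s_t: np.ndarray,
    patient_model: PatientModel,
    policy: PolicyModel,
    cfg: PlanConfig,
    slot_classes: list[str],
) -> Plan:
    """Beam-search the best K-step dose sequence from state ``s_t``.

    ``slot_classes`` gives, for each of the K planning steps, the insulin
    class scheduled at the slot the action applies to ("none" for no
    injection).
    """
    if len(slot_classes) != cfg.K:
        raise ValueError(f"need {cfg.K} per-step insulin classes, got {len(slot_classes)}")
    # beam entries: (dose token sequence, state, rewards, discounted cum reward)
    beams = [((), np.asarray(s_t, dtype=float), (), 0.0)]
    for i, cls in enumerate(slot_classes):
        expansions = []
        for seq, state, rewards, cum in beams:
            if cls == "none":
                tokens = [0]
            else:
                tokens = _candidate_tokens(policy, state, cfg)
            states = np.repeat(state[None, :], len(tokens), axis=0)
            tok = np.asarray(tokens)
            cls_idx = np.where(tok > 0, CLASS_INDEX[cls] if cls != "none" else 0, 0)
            nxt, rew = patient_model.step_batch(states, tok, cls_idx)
            boot = policy.value_np(nxt)
            for j, t in enumerate(tokens):
                cum_j = cum + cfg.gamma**i * float(rew[j])
                score = cum_j + cfg.gamma ** (i + 1) * float(boot[j])
                expansions.append(
                    (score, seq + (t,), nxt[j], rewards + (float(rew[j]),), cum_j)
                )
        expansions.sort(key=lambda e: (-e[0], e[1]))
        beams = [(seq, st, rw, cum) for _, seq, st, rw, cum in expansions[: cfg.B]]
    final = []
    for seq, state, rewards, cum in beams:
        tv = float(policy.value_np(state))
        v = cum + cfg.gamma**cfg.K * tv
        final.append((v, seq, rewards, state, tv))
    final.sort(key=lambda e: (-e[0], e[1]))
    v, seq, rewards, state, tv = final[0]
    actions = [
        DoseAction(slot_classes[i], t) if t > 0 else NO_DOSE for i, t in enumerate(seq)
    ]
    return Plan(actions=actions, value=float(v), rewards=list(rewards),
                states=[state], terminal_value=tv)


def recommend_day(
    traj_prefix: Trajectory,
    patient_model: PatientModel,
    policy: PolicyModel,
    cfg: PlanConfig = PlanConfig(),
    schedule: dict[int, str] | None = None,
) -> list[dict]:
    """Plan the next day's seven slots from a prefix ending at pre-bedtime.

    Returns one record per slot: {day, slot, insulin_class, dose, plan_value}.
    """
    last = traj_prefix.observations[-1]
    if last.slot != N_SLOTS - 1:
        raise ValueError("prefix must end at the pre-bedtime slot to plan a full day")
    if schedule is None:
        schedule = infer_schedule(traj_prefix)
    if cfg.K != N_SLOTS:
        raise ValueError("recommend_day plans exactly one day (K = 7)")
    # the first planned action is taken *at* the bedtime slot (affects slot 0);
    # plan over the 7 actions taken at slots [6, 0, 1, ..., 5]
    action_slots = [(last.slot + i) % N_SLOTS for i in range(cfg.K)]
    slot_classes = [schedule.get(s, "none") for s in action_slots]
    s = patient_model.encode(traj_prefix)
    best = plan(s, patient_model, policy, cfg, slot_classes)
    out = []
    for i, a in enumerate(best.actions):
        day = last.day if action_slots[i] == N_SLOTS - 1 else last.day + 1
        out.append(
            {
                "day": int(day),
                "slot": int(action_slots[i]),
                "insulin_class": a.insulin_class,
                "dose": a.dose_units,
                "plan_value": best.value,
            }
        )
    return out
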