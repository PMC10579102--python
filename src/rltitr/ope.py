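"""Off-policy evaluation by importance sampling and weighted importance sampling.

Given logged trajectories generated by a behavior policy pi0 (the clinicians)
and a target policy pi1 (the learned model), the per-step ratio is
rho_t = pi1(a_t|s_t) / pi0(a_t|s_t) and the trajectory weight the product
w = prod_t rho_t.  With the discounted return G_i = sum_t gamma^(t-1) r_{i,t}
(t starting at 1):

    V_IS  = sum_i (w_i / N) G_i
    V_WIS = sum_i (w_i / sum_j w_j) G_i          (self-normalized)
    ESS   = (sum_i w_i)^2 / sum_i w_i^2          (effective sample size)

WIS trades a small bias for a large variance reduction; the ESS reports how
many equally weighted trajectories the estimate effectively rests on.

The estimators operate on per-step probability arrays, so they serve both
toy MDPs and the full trajectory/model stack (see
:func:`evaluate_policy_against_log` and :func:`fit_behavior_policy`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import Trajectory
from .patient_model import PatientModel
from .policy_model import PolicyConfig, PolicyModel, train_policy

__all__ = [
    "OPEResult",
    "SupportViolation",
    "is_ratios",
    "discounted_return",
    "v_is",
    "v_wis",
    "fit_behavior_policy",
    "trajectory_probs",
    "evaluate_policy_against_log",
]


class SupportViolation(ValueError):
    """The behavior policy assigns zero probability to a logged action."""


@dataclass
class OPEResult:
    weights: np.ndarray  # per-trajectory self-normalized weights (sum to 1)
    v_is: float
    v_wis: float
    effective_sample_size: float
    n: int


def is_ratios(behavior_probs: Sequence[float], target_probs: Sequence[float]
              ) -> tuple[np.ndarray, float]:
    """Per-step ratios rho_t and the trajectory weight w = prod rho_t."""
    p0 = np.asarray(behavior_probs, dtype=float)
    p1 = np.asarray(target_probs, dtype=float)
    if p0.shape != p1.shape:
        raise ValueError("behavior and target probability sequences differ in length")
    zero = np.nonzero(p0 <= 0.0)[0]
    if zero.size:
        raise SupportViolation(
            f"behavior policy has zero probability at step {int(zero[0])}"
        )
    rho = p1 / p0
    return rho, float(np.prod(rho))


def discounted_return(rewards: Sequence[float], gamma: float) -> float:
    """sum_t gamma^(t-1) r_t with t starting at 1 (the printed OPE convention)."""
    r = np.asarray([x if x is not None else 0.0 for x in rewards], dtype=float)
    return float(np.sum(gamma ** np.arange(len(r)) * r))


def _weights_and_returns(trajs_probs, gamma):
    ws, gs = [], []
    for p0, p1, rewards in trajs_probs:
        _, w = is_ratios(p0, p1)
        ws.append(w)
        gs.append(discounted_return(rewards, gamma))
    return np.asarray(ws), np.asarray(gs)


def v_is(trajs_probs: Sequence[tuple], gamma: float) -> float:
    """Ordinary importance sampling: mean of w_i x discounted return.

    Each element of ``trajs_probs`` is (behavior probs, target probs, rewards).
    """
    if not trajs_probs:
        raise ValueError("need at least one trajectory")
    w, g = _weights_and_returns(trajs_probs, gamma)
    return float(np.mean(w * g))


def v_wis(trajs_probs: Sequence[tuple], gamma: float) -> OPEResult:
    """Self-normalized (weighted) importance sampling with effective sample size."""
    if not trajs_probs:
        raise ValueError("need at least one trajectory")
    w, g = _weights_and_returns(trajs_probs, gamma)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate WIS estimate: all trajectory weights are zero")
    wn = w / total
    ess = float(total**2 / np.sum(w**2))
    return OPEResult(
        weights=wn,
        v_is=float(np.mean(w * g)),
        v_wis=float(np.sum(wn * g)),
        effective_sample_size=ess,
        n=len(trajs_probs),
    )


# ---------------------------------------------------------------------------
# Model-backed evaluation on cohorts
# ---------------------------------------------------------------------------


def trajectory_probs(traj: Trajectory, patient_model: PatientModel,
                     policy: PolicyModel) -> np.ndarray:
    """Probability the policy assigns to each logged action along a trajectory.

    Probabilities are conditioned on the regimen schedule (the same masking
    used in training and planning): at slots with no scheduled injection both
    policies place probability 1 on the no-dose action, so those steps do not
    perturb the importance ratios.
    """
    from .policy_model import allowed_tokens, infer_schedule

    schedule = infer_schedule(traj)
    states = patient_model.encode_states(traj)
    allowed = np.stack([
        allowed_tokens(schedule, o.slot) for o in traj.observations
    ])
    probs = policy.action_probs(states, allowed)
    out = np.empty(len(traj))
    for t, a in enumerate(traj.actions):
        token = a.dose_units if a.is_injection else 0
        out[t] = probs[t, token]
    return out


def fit_behavior_policy(
    cohort: Sequence[Trajectory],
    patient_model: PatientModel,
    epochs: int = 15,
    prob_floor: float = 1e-3,
    seed: int = 0,
) -> PolicyModel:
    """Estimate the clinicians' policy pi0: the same policy architecture trained
    with the supervised imitation loss only, probabilities floored at
    ``prob_floor`` (renormalized) to guarantee support for the ratios."""
    cfg = PolicyConfig.scaled_down(
        hidden_dim=patient_model.cfg.hidden_dim,
        sl_only=True, eps1=0.0, eps2=1.0, value_coef=0.0,
        epochs=epochs, seed=seed,
    )
    behavior, _ = train_policy(cohort, patient_model, cfg)
    behavior.prob_floor = prob_floor
    return behavior


def evaluate_policy_against_log(
    cohort: Sequence[Trajectory],
    patient_model: PatientModel,
    behavior: PolicyModel,
    target: PolicyModel,
    gamma: float = 0.9,
) -> OPEResult:
    """WIS evaluation of ``target`` against logged data under estimated pi0."""
    trajs_probs = []
    for traj in cohort:
        p0 = trajectory_probs(traj, patient_model, behavior)
        p1 = trajectory_probs(traj, patient_model, target)
        rewards = [r if r is not None else 0.0 for r in traj.rewards]
        trajs_probs.append((p0, p1, rewards))
    return v_wis(trajs_probs, gamma)
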