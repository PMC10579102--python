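"""Dosing policy learned with a joint supervised + policy-gradient objective.

The policy pi maps the patient-model hidden state s_t to a categorical
distribution over 41 action tokens (no-dose plus doses 1..40 U); the insulin
class at an injection slot comes from the patient's regimen schedule, the
policy chooses the dose.  Training minimizes

    L = L_RL1 + eps1 * L_RL2 + eps2 * L_SL

where L_SL is the cross-entropy of the clinician's logged action (imitation,
keeping recommendations inside clinically seen ranges), L_RL1 is a policy
gradient on logged trajectories weighted by discounted Magni-risk returns,
and L_RL2 is the same policy-gradient form on trajectories *generated* by
alternating policy sampling with learned-dynamics steps, letting the policy
explore doses beyond the logged data.  For stable training both RL terms use
the advantage R - V(s) with a learnable value head V regressed on returns
(raw-return weighting is available via ``use_advantage=False``).

Two-stage schedule: the patient model is trained first; ``train_policy``
refuses an untrained patient model unless explicitly overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from . import nn
from .data_model import N_SLOTS, DoseAction, Trajectory, mgdl_from_mmol
from .patient_model import (
    CLASS_INDEX,
    GLU_CENTER,
    GLU_SCALE,
    N_ACTION_TOKENS,
    PatientModel,
    featurize,
)
from .reward import magni_reward

__all__ = [
    "PolicyConfig",
    "ReturnSeries",
    "PolicyModel",
    "discounted_returns",
    "sl_loss",
    "rl_loss_logged",
    "rl_loss_modelbased",
    "train_policy",
    "infer_schedule",
    "make_policy_fn",
]


@dataclass(frozen=True)
class PolicyConfig:
    hidden_dim: int = 256
    policy_mlp_layers: int = 3
    value_mlp_layers: int = 3
    gamma: float = 0.9
    eps1: float = 1.0  # weight of the model-based RL term
    eps2: float = 1.0  # weight of the supervised imitation term
    rollout_depth: int = 7
    use_advantage: bool = True
    value_coef: float = 0.5
    sl_only: bool = False  # imitation-only fit (behavior-policy estimation)
    label_smoothing_sd: float = 1.5  # ordinal smoothing of dose labels, in units
    sl_warmup_epochs: int = 5  # imitation-only epochs before the RL terms engage
    normalize_advantage: bool = True  # standardize advantages within each batch
    epochs: int = 100
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 1e-4
    seed: int = 0
    allow_untrained_patient_model: bool = False

    def __post_init__(self):
        if self.eps1 < 0 or self.eps2 < 0:
            raise ValueError("eps1 and eps2 must be >= 0")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")

    @staticmethod
    def scaled_down(**overrides) -> "PolicyConfig":
        base = dict(hidden_dim=32, policy_mlp_layers=2, value_mlp_layers=2, epochs=15)
        base.update(overrides)
        return PolicyConfig(**base)


@dataclass
class ReturnSeries:
    """Per-step discounted returns and (optionally) value estimates."""

    returns: np.ndarray
    values: np.ndarray | None = None

    def check_recursion(self, rewards: np.ndarray, gamma: float, atol: float = 1e-9) -> bool:
        R = self.returns
        nxt = np.append(R[1:], 0.0)
        return bool(np.allclose(R, rewards + gamma * nxt, atol=atol))


def discounted_returns(rewards: Sequence[float], gamma: float) -> ReturnSeries:
    """R_t = sum_i gamma^i r_{t+i}, computed by the backward recursion."""
    r = np.asarray(rewards, dtype=float)
    R = np.zeros_like(r)
    acc = 0.0
    for t in range(len(r) - 1, -1, -1):
        acc = r[t] + gamma * acc
        R[t] = acc
    return ReturnSeries(returns=R)


class PolicyModel(nn.Module):
    """Policy head pi(a|s) and value head V(s) over patient-model states."""

    def __init__(self, cfg: PolicyConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        H = cfg.hidden_dim
        self.cfg = cfg
        self.policy_mlp = nn.MLP(H, H, N_ACTION_TOKENS, cfg.policy_mlp_layers, rng)
        self.value_mlp = nn.MLP(H, H, 1, cfg.value_mlp_layers, rng)
        self.prob_floor = 0.0  # used by behavior-policy estimates

    def logits(self, s: nn.Tensor, allowed: np.ndarray | None = None) -> nn.Tensor:
        out = self.policy_mlp(s)
        if allowed is not None:
            out = out + np.where(allowed, 0.0, -1e9)
        return out

    def action_probs(self, s: np.ndarray, allowed: np.ndarray | None = None) -> np.ndarray:
        """pi(.|s): non-negative, sums to 1 over the action vocabulary."""
        was = self.training
        self.eval()
        logits = self.logits(nn.Tensor(np.asarray(s)), allowed).data
        if was:
            self.train()
        z = logits - logits.max(axis=-1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=-1, keepdims=True)
        if self.prob_floor > 0.0:
            p = (1.0 - N_ACTION_TOKENS * self.prob_floor) * p + self.prob_floor
        return p

    def value_np(self, s: np.ndarray) -> np.ndarray:
        was = self.training
        self.eval()
        v = self.value_mlp(nn.Tensor(np.asarray(s))).data[..., 0]
        if was:
            self.train()
        return v

    def save(self, path):
        nn.save_archive(path, self.state_dict(),
                        {"kind": "policy_model", "config": asdict(self.cfg),
                         "prob_floor": self.prob_floor})

    @classmethod
    def load(cls, path) -> "PolicyModel":
        arrays, meta = nn.load_archive(path)
        if meta.get("kind") != "policy_model":
            raise ValueError(f"{path} is not a policy-model checkpoint")
        model = cls(PolicyConfig(**meta["config"]))
        model.load_state_dict(arrays)
        model.prob_floor = float(meta.get("prob_floor", 0.0))
        model.eval()
        return model


# ---------------------------------------------------------------------------
# Scalar reference losses
# ---------------------------------------------------------------------------


def sl_loss(policy_probs: np.ndarray, clinician_action: DoseAction) -> float:
    """Cross-entropy of the clinician's action token under pi (imitation loss)."""
    token = clinician_action.dose_units if clinician_action.is_injection else 0
    p = np.asarray(policy_probs, dtype=float)
    if token >= p.shape[-1]:
        raise ValueError(f"action token {token} outside vocabulary {p.shape[-1]}")
    return float(-np.log(max(p[token], 1e-300)))


def rl_loss_logged(traj: Trajectory, patient_model: PatientModel,
                   policy: PolicyModel, gamma: float,
                   use_advantage: bool = True) -> float:
    """Policy-gradient loss -sum (R_t - V(s_t)) log pi(a_t|s_t) on a logged trajectory."""
    states = patient_model.encode_states(traj)
    rewards = np.array([r if r is not None else 0.0 for r in traj.rewards])
    R = discounted_returns(rewards, gamma).returns
    base = policy.value_np(states) if use_advantage else np.zeros_like(R)
    probs = policy.action_probs(states)
    total = 0.0
    for t, a in enumerate(traj.actions):
        token = a.dose_units if a.is_injection else 0
        total -= (R[t] - base[t]) * np.log(max(probs[t, token], 1e-300))
    return float(total)


def rl_loss_modelbased(patient_model: PatientModel, policy: PolicyModel,
                       start_states: np.ndarray, start_slots: np.ndarray,
                       schedules: Sequence[dict[int, str]], depth: int,
                       gamma: float, rng: np.random.Generator,
                       use_advantage: bool = True) -> float:
    """Reference (inference-mode) value of L_RL2; the differentiable version
    lives inside :func:`train_policy`."""
    loss, _ = _modelbased_rollout(
        patient_model, policy, start_states, start_slots, schedules, depth,
        gamma, rng, use_advantage, build_graph=False,
    )
    return float(loss.data if isinstance(loss, nn.Tensor) else loss)


# ---------------------------------------------------------------------------
# Schedules and masks
# ---------------------------------------------------------------------------


def infer_schedule(traj: Trajectory) -> dict[int, str]:
    """Slot -> insulin class map recovered from a patient's logged injections."""
    schedule: dict[int, str] = {}
    for o, a in zip(traj.observations, traj.actions):
        if a.is_injection:
            schedule.setdefault(o.slot, a.insulin_class)
    return schedule


def allowed_tokens(schedule: dict[int, str], slot: int) -> np.ndarray:
    """Boolean mask over the 41 tokens valid at ``slot`` under ``schedule``."""
    mask = np.zeros(N_ACTION_TOKENS, dtype=bool)
    if slot in schedule:
        mask[1:] = True
    else:
        mask[0] = True
    return mask


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def model_reward(patient_model: PatientModel, states: np.ndarray) -> np.ndarray:
    """Model-derived reward of rolled-out states: the analytic Magni-risk
    reward of the glucose predicted by f_P.  Grounding the reward in the
    glucose prediction (rather than the learned reward head) preserves the
    hypoglycemia cliff exactly even for doses rarely seen in the log."""
    was = patient_model.training
    patient_model.eval()
    z = patient_model.predict_tensor(nn.Tensor(np.asarray(states))).data[..., 0]
    if was:
        patient_model.train()
    g_mmol = np.maximum(z * GLU_SCALE + GLU_CENTER, 0.6)
    return magni_reward(mgdl_from_mmol(g_mmol))


def _modelbased_rollout(patient_model, policy, start_states, start_slots,
                        schedules, depth, gamma, rng, use_advantage,
                        build_graph=True, normalize_advantage=False):
    """Sampled policy/dynamics roll-outs; returns (L_RL2 tensor, diagnostics).

    Dynamics run in inference mode (gradients reach the policy only through
    log pi of the sampled actions, the REINFORCE route); non-injection slots
    are forced to the no-dose token and contribute no gradient.
    """
    n = start_states.shape[0]
    s = np.asarray(start_states)
    logps: list[nn.Tensor] = []
    includes: list[np.ndarray] = []
    rewards = np.zeros((depth, n))
    values0 = policy.value_np(s)
    for i in range(depth):
        slots = (start_slots + 1 + i) % N_SLOTS
        allowed = np.stack([allowed_tokens(schedules[j], slots[j]) for j in range(n)])
        probs = policy.action_probs(s, allowed)
        u = rng.random(n)
        tokens = (probs.cumsum(axis=-1) > u[:, None]).argmax(axis=-1)
        cls = np.array([
            CLASS_INDEX[schedules[j].get(slots[j], "none")] if tokens[j] > 0 else 0
            for j in range(n)
        ])
        if build_graph:
            lt = nn.log_softmax(policy.logits(nn.Tensor(s), allowed), axis=-1)
            logps.append(lt[np.arange(n), tokens])
        else:
            logps.append(np.log(np.maximum(probs[np.arange(n), tokens], 1e-300)))
        includes.append(np.array([slots[j] in schedules[j] for j in range(n)], dtype=float))
        s, _r_head = patient_model.step_batch(s, tokens, cls)
        if not np.all(np.isfinite(s)):
            raise RuntimeError("model-based roll-out diverged to non-finite states")
        rewards[i] = model_reward(patient_model, s)
    bootstrap = policy.value_np(s)
    returns = np.zeros((depth, n))
    acc = bootstrap
    for i in range(depth - 1, -1, -1):
        acc = rewards[i] + gamma * acc
        returns[i] = acc
    base = values0 if use_advantage else np.zeros(n)
    advs = returns - base[None, :]
    inc = np.stack(includes)
    if normalize_advantage and inc.sum() > 1:
        sel = inc > 0
        advs = (advs - advs[sel].mean()) / (advs[sel].std() + 1e-8)
    denom = max(float(inc.sum()), 1.0)
    if build_graph:
        loss = nn.Tensor(0.0)
        for i in range(depth):
            loss = loss + (logps[i] * (-advs[i] * includes[i])).sum()
        loss = loss * (1.0 / denom)
    else:
        total = 0.0
        for i in range(depth):
            total += float(np.sum(-advs[i] * includes[i] * logps[i]))
        loss = nn.Tensor(total / denom)
    return loss, {"mean_model_reward": float(rewards.mean())}


def train_policy(
    cohort: Sequence[Trajectory],
    patient_model: PatientModel,
    cfg: PolicyConfig,
) -> tuple[PolicyModel, list[dict]]:
    """Joint SL + RL policy optimization against the (frozen) patient model."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if not patient_model.trained and not cfg.allow_untrained_patient_model:
        raise ValueError(
            "patient model is untrained; train it first (two-stage schedule) "
            "or set allow_untrained_patient_model=True"
        )
    if cfg.hidden_dim != patient_model.cfg.hidden_dim:
        raise ValueError("policy hidden_dim must match the patient model")
    rng = np.random.default_rng(cfg.seed)
    policy = PolicyModel(cfg, seed=cfg.seed)
    policy.train()
    opt = nn.Adam(policy.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)

    cov_dim = patient_model.cov_dim
    patient_model.eval()
    feats = featurize(list(cohort), cov_dim, patient_model.cfg.pad_length)
    states_all = patient_model.encode_features(feats).data  # frozen encoder
    N, T, _ = states_all.shape
    tokens_all = feats["tokens"]
    valid_all = feats["valid"]
    slots_all = feats["slots"]
    rewards_all = feats["rewards"] * feats["reward_mask"]
    returns_all = np.zeros((N, T))
    for i in range(N):
        returns_all[i] = discounted_returns(rewards_all[i], cfg.gamma).returns
    schedules = [infer_schedule(t) for t in cohort]
    # Ordinal label smoothing: the dose vocabulary is ordered, so the imitation
    # target is a discretized Gaussian around the logged dose (over dose tokens
    # only), which shares evidence between neighboring doses.
    targets_all = np.zeros((N, T, N_ACTION_TOKENS))
    dose_axis = np.arange(1, N_ACTION_TOKENS)
    for i in range(N):
        for t in range(T):
            tok = tokens_all[i, t]
            if tok == 0 or cfg.label_smoothing_sd <= 0:
                targets_all[i, t, tok] = 1.0
            else:
                q = np.exp(-0.5 * ((dose_axis - tok) / cfg.label_smoothing_sd) ** 2)
                targets_all[i, t, 1:] = q / q.sum()
    allowed_all = np.zeros((N, T, N_ACTION_TOKENS), dtype=bool)
    for i in range(N):
        for t in range(T):
            allowed_all[i, t] = allowed_tokens(schedules[i], slots_all[i, t])
    # model-based roll-out starts: each day's last slot except the final day
    starts: list[tuple[int, int]] = [
        (i, t)
        for i in range(N)
        for t in range(T - 1)
        if valid_all[i, t] and slots_all[i, t] == N_SLOTS - 1
    ]

    history: list[dict] = []
    B = cfg.batch_size
    for epoch in range(cfg.epochs):
        perm = rng.permutation(N)
        ep = {"epoch": epoch, "L_RL1": 0.0, "L_RL2": 0.0, "L_SL": 0.0,
              "value_loss": 0.0, "total": 0.0, "n": 0}
        for bstart in range(0, N, B):
            idx = perm[bstart : bstart + B]
            S = nn.Tensor(states_all[idx])
            valid = valid_all[idx]
            logits = policy.logits(S, allowed_all[idx])
            lsm = nn.log_softmax(logits, axis=-1)
            flat = lsm.reshape(-1, N_ACTION_TOKENS)
            picked = flat[np.arange(flat.shape[0]), tokens_all[idx].reshape(-1)]
            vmask = valid.reshape(-1)
            denom = max(vmask.sum(), 1.0)
            q = targets_all[idx].reshape(-1, N_ACTION_TOKENS)
            l_sl = -((flat * q).sum(axis=-1) * vmask).sum() * (1.0 / denom)

            warmup = cfg.sl_only or epoch < cfg.sl_warmup_epochs
            if cfg.sl_only:
                value_loss = nn.Tensor(0.0)
                l_rl1 = nn.Tensor(0.0)
            elif warmup:
                # fit the value head during warm-up, hold the policy to imitation
                v = policy.value_mlp(S)[..., 0]
                R = returns_all[idx]
                dv = v - R
                value_loss = ((dv * dv) * valid).sum() * (1.0 / denom)
                l_rl1 = nn.Tensor(0.0)
            else:
                v = policy.value_mlp(S)[..., 0]
                R = returns_all[idx]
                dv = v - R
                value_loss = ((dv * dv) * valid).sum() * (1.0 / denom)
                base = v.data if cfg.use_advantage else np.zeros_like(R)
                adv = R - base
                if cfg.normalize_advantage:
                    sel = valid > 0
                    adv = (adv - adv[sel].mean()) / (adv[sel].std() + 1e-8)
                adv = adv * valid
                l_rl1 = (picked * (-adv.reshape(-1))).sum() * (1.0 / denom)

            idx_set = set(idx.tolist())
            bstarts = [(i, t) for (i, t) in starts if i in idx_set]
            if bstarts and cfg.eps1 > 0 and not warmup:
                s0 = np.stack([states_all[i, t] for i, t in bstarts])
                sl0 = np.array([slots_all[i, t] for i, t in bstarts])
                sch = [schedules[i] for i, _ in bstarts]
                l_rl2, _ = _modelbased_rollout(
                    patient_model, policy, s0, sl0, sch, cfg.rollout_depth,
                    cfg.gamma, rng, cfg.use_advantage,
                    normalize_advantage=cfg.normalize_advantage,
                )
            else:
                l_rl2 = nn.Tensor(0.0)

            total = l_rl1 + l_rl2 * cfg.eps1 + l_sl * cfg.eps2 + value_loss * cfg.value_coef
            if not np.isfinite(total.data):
                raise RuntimeError(f"policy training diverged (NaN loss, epoch {epoch})")
            opt.zero_grad()
            total.backward()
            opt.step()
            ep["L_RL1"] += float(l_rl1.data)
            ep["L_RL2"] += float(l_rl2.data)
            ep["L_SL"] += float(l_sl.data)
            ep["value_loss"] += float(value_loss.data)
            ep["total"] += float(total.data)
            ep["n"] += 1
        for key in ("L_RL1", "L_RL2", "L_SL", "value_loss", "total"):
            ep[key] /= max(ep["n"], 1)
        history.append(ep)
    policy.eval()
    return policy, history


# ---------------------------------------------------------------------------
# Simulator adapter
# ---------------------------------------------------------------------------


def make_policy_fn(policy: PolicyModel, patient_model: PatientModel,
                   mode: str = "expected", seed: int = 0):
    """Adapter turning (policy, patient model) into a bedside dosing callable
    for :func:`rltitr.synthetic_cohort.simulate_policy`.

    ``mode``: "expected" rounds the probability-weighted mean dose (the
    ordinal point estimate), "argmax" takes the modal token, "sample" draws
    from pi.
    """
    rng = np.random.default_rng(seed)

    def fn(partial: Trajectory, day: int, slot: int, insulin_class: str) -> int:
        s = patient_model.encode(partial)
        mask = np.zeros(N_ACTION_TOKENS, dtype=bool)
        mask[1:] = True  # called only at injection slots; dose required
        p = policy.action_probs(s, mask)
        if mode == "expected":
            return int(round(float(np.dot(p, np.arange(N_ACTION_TOKENS)))))
        if mode == "argmax":
            return int(np.argmax(p))
        return int(rng.choice(N_ACTION_TOKENS, p=p))

    return fn
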