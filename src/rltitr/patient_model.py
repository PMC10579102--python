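"""Learned patient environment: representation, dynamics and prediction.

Three jointly trained functions model how an inpatient's glycemic state
evolves under insulin dosing:

* representation ``f_R``: a causal transformer over the per-slot observation
  sequence; the hidden vector at position t summarizes O_{1:t} and is the
  MDP state s_t (the last position gives the initial state for planning);
* dynamics ``f_T``: maps (s_t, a_t) to (s_{t+1}, r̂_t), where r̂_t estimates
  the Magni-risk reward at the state resulting from a_t;
* prediction ``f_P``: maps s_t to the patient status y_t — a glucose point
  prediction and a within-target-range probability.

Training unrolls the dynamics K steps from every position with the logged
(teacher-forced) actions and minimizes  L = mu * L_T + L_P  where L_T is a
consistency loss tying rolled-out states to the encoded state at the same
absolute timestep, and L_P sums a glucose MSE, a WTR cross-entropy and a
reward-head MSE over unmasked slots.  All three functions share the encoder
and are optimized end-to-end with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from . import nn
from .data_model import (
    INSULIN_CLASSES,
    N_SLOTS,
    DoseAction,
    Trajectory,
)
from .reward import wtr_label

__all__ = [
    "PatientModelConfig",
    "TrainConfig",
    "StatusPrediction",
    "PatientModel",
    "featurize",
    "consistency_loss",
    "prediction_loss",
    "train_patient_model",
    "one_day_ahead_mae",
]

GLU_CENTER = 8.0  # mmol/L, centering for the glucose channel
GLU_SCALE = 4.0
MAX_DAYS = 64  # capacity of the learned day embedding

N_ACTION_TOKENS = 41  # no-dose token 0 + doses 1..40
CLASS_INDEX = {c: i for i, c in enumerate(INSULIN_CLASSES)}


@dataclass(frozen=True)
class PatientModelConfig:
    """Architecture and loss weights.  Defaults are the full-scale settings;
    :meth:`scaled_down` gives the small profile used for desk-scale runs."""

    hidden_dim: int = 256
    encoder_layers: int = 3
    dynamics_layers: int = 3
    predictor_mlp_layers: int = 3
    attn_heads: int = 8
    consistency_weight: float = 0.1  # mu
    rollout_depth: int = 7  # K; 7 = one day ahead
    pad_length: int = 128
    dropout_p: float = 0.4

    def __post_init__(self):
        if min(self.hidden_dim, self.encoder_layers, self.dynamics_layers,
               self.predictor_mlp_layers, self.attn_heads, self.rollout_depth,
               self.pad_length) < 1:
            raise ValueError("all architecture sizes must be positive")
        if self.consistency_weight < 0:
            raise ValueError("consistency weight mu must be >= 0")

    @staticmethod
    def scaled_down(**overrides) -> "PatientModelConfig":
        base = dict(hidden_dim=32, encoder_layers=2, dynamics_layers=2,
                    predictor_mlp_layers=2, attn_heads=2, dropout_p=0.1,
                    pad_length=64)
        base.update(overrides)
        return PatientModelConfig(**base)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 1e-4
    val_fraction: float = 0.2
    seed: int = 0

    @staticmethod
    def scaled_down(**overrides) -> "TrainConfig":
        base = dict(epochs=20)
        base.update(overrides)
        return TrainConfig(**base)


@dataclass(frozen=True)
class StatusPrediction:
    """Predicted patient status at one timeslot."""

    glucose_mmol: float
    wtr_prob: float

    def __post_init__(self):
        if not 0.0 <= self.wtr_prob <= 1.0:
            raise ValueError("wtr_prob must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------


def feature_width(cov_dim: int) -> int:
    # glucose-z, glucose mask, 7 slot one-hots, day, prev-class one-hots, prev dose
    return 2 + N_SLOTS + 1 + len(INSULIN_CLASSES) + 1 + cov_dim


def featurize(trajs: Sequence[Trajectory], cov_dim: int, max_len: int) -> dict[str, np.ndarray]:
    """Pack trajectories into padded arrays for the sequence models.

    The input at position t contains o_t plus the action taken at t-1, so the
    encoder state at t never sees the action it is asked to evaluate.
    Sequences longer than ``max_len`` keep their most recent ``max_len`` steps.
    """
    B = len(trajs)
    T = min(max(len(t) for t in trajs), max_len)
    F = feature_width(cov_dim)
    X = np.zeros((B, T, F))
    glu_z = np.zeros((B, T))
    glu_mask = np.zeros((B, T))
    wtr = np.zeros((B, T), dtype=np.intp)
    tokens = np.zeros((B, T), dtype=np.intp)
    cls_idx = np.zeros((B, T), dtype=np.intp)
    rewards = np.zeros((B, T))
    reward_mask = np.zeros((B, T))
    valid = np.zeros((B, T))
    slots = np.zeros((B, T), dtype=np.intp)
    days = np.zeros((B, T), dtype=np.intp)
    for b, traj in enumerate(trajs):
        start = max(0, len(traj) - T)
        for t in range(start, len(traj)):
            j = t - start
            o = traj.observations[t]
            a = traj.actions[t]
            valid[b, j] = 1.0
            slots[b, j] = o.slot
            days[b, j] = min(o.day, MAX_DAYS) - 1
            if o.glucose_mmol is not None:
                z = (o.glucose_mmol - GLU_CENTER) / GLU_SCALE
                glu_z[b, j] = z
                glu_mask[b, j] = 1.0
                wtr[b, j] = int(wtr_label(o.glucose_mmol))
                X[b, j, 0] = z
                X[b, j, 1] = 1.0
            tokens[b, j] = a.dose_units if a.is_injection else 0
            cls_idx[b, j] = CLASS_INDEX[a.insulin_class]
            r = traj.rewards[t]
            if r is not None:
                rewards[b, j] = r
                reward_mask[b, j] = 1.0
            X[b, j, 2 + o.slot] = 1.0
            X[b, j, 2 + N_SLOTS] = o.day / 10.0
            if t > start:
                pa = traj.actions[t - 1]
                X[b, j, 2 + N_SLOTS + 1 + CLASS_INDEX[pa.insulin_class]] = 1.0
                X[b, j, 2 + N_SLOTS + 1 + len(INSULIN_CLASSES)] = (
                    (pa.dose_units or 0) / 40.0
                )
            if cov_dim:
                X[b, j, -cov_dim:] = o.covariates[:cov_dim]
    return dict(X=X, glu_z=glu_z, glu_mask=glu_mask, wtr=wtr, tokens=tokens,
                cls=cls_idx, rewards=rewards, reward_mask=reward_mask,
                valid=valid, slots=slots, days=days)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class PatientModel(nn.Module):
    def __init__(self, cfg: PatientModelConfig, cov_dim: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        H = cfg.hidden_dim
        self.cfg = cfg
        self.cov_dim = cov_dim
        self.trained = False
        self.input_proj = nn.Linear(feature_width(cov_dim), H, rng)
        self.slot_emb = nn.Embedding(N_SLOTS, H, rng)
        self.day_emb = nn.Embedding(MAX_DAYS, H, rng)
        self.encoder = nn.TransformerEncoder(H, cfg.encoder_layers, cfg.attn_heads,
                                             rng, cfg.dropout_p)
        self.dose_emb = nn.Embedding(N_ACTION_TOKENS, H, rng)
        self.class_emb = nn.Embedding(len(INSULIN_CLASSES), H, rng)
        # numeric dose channel: gives the action encoding an ordinal structure
        # so dynamics generalize monotonically to doses rare in the log
        self.dose_proj = nn.Linear(1, H, rng)
        self.dynamics = nn.MLP(2 * H, H, H + 1, cfg.dynamics_layers, rng,
                               dropout=cfg.dropout_p)
        self.dyn_norm = nn.LayerNorm(H)
        self.predictor = nn.MLP(H, H, 2, cfg.predictor_mlp_layers, rng,
                                dropout=cfg.dropout_p)

    # -- f_R ------------------------------------------------------------------
    def encode_features(self, feats: dict[str, np.ndarray]) -> nn.Tensor:
        x = self.input_proj(nn.Tensor(feats["X"]))
        x = x + self.slot_emb(feats["slots"]) + self.day_emb(feats["days"])
        return self.encoder(x)

    def encode(self, traj: Trajectory) -> np.ndarray:
        """f_R: the hidden state after the last observation (inference mode)."""
        if len(traj) < 1:
            raise ValueError("cannot encode an empty observation sequence")
        return self.encode_states(traj)[-1]

    def encode_states(self, traj: Trajectory) -> np.ndarray:
        """Hidden states at every step of a trajectory (inference mode)."""
        was_training = self.training
        self.eval()
        feats = featurize([traj], self.cov_dim, self.cfg.pad_length)
        states = self.encode_features(feats).data[0]
        if was_training:
            self.train()
        return states

    # -- f_T ------------------------------------------------------------------
    def step_tensor(self, s: nn.Tensor, tokens: np.ndarray, cls: np.ndarray
                    ) -> tuple[nn.Tensor, nn.Tensor]:
        dose_norm = (np.asarray(tokens, dtype=float) / 40.0)[..., None]
        a = self.dose_emb(tokens) + self.class_emb(cls) + self.dose_proj(nn.Tensor(dose_norm))
        out = self.dynamics(nn.concat([s, a], axis=-1))
        H = self.cfg.hidden_dim
        nxt = self.dyn_norm(s + out[..., :H])
        rew = out[..., H].tanh()
        return nxt, rew

    def step(self, s: np.ndarray, action: DoseAction) -> tuple[np.ndarray, float]:
        """f_T on a single state: next hidden state and estimated reward."""
        if action.insulin_class not in CLASS_INDEX:
            raise ValueError(f"unknown action {action}")
        was_training = self.training
        self.eval()
        token = np.array(action.dose_units if action.is_injection else 0)
        cls = np.array(CLASS_INDEX[action.insulin_class])
        nxt, rew = self.step_tensor(nn.Tensor(np.asarray(s)), token, cls)
        if was_training:
            self.train()
        return nxt.data, float(rew.data)

    def step_batch(self, s: np.ndarray, tokens: np.ndarray, cls: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized inference step for planning/rollouts (no gradients)."""
        was_training = self.training
        self.eval()
        nxt, rew = self.step_tensor(nn.Tensor(s), np.asarray(tokens), np.asarray(cls))
        if was_training:
            self.train()
        return nxt.data, rew.data

    # -- f_P ------------------------------------------------------------------
    def predict_tensor(self, s: nn.Tensor) -> nn.Tensor:
        return self.predictor(s)

    def predict(self, s: np.ndarray) -> StatusPrediction:
        """f_P: glucose point prediction and WTR probability for one state."""
        was_training = self.training
        self.eval()
        out = self.predictor(nn.Tensor(np.asarray(s))).data
        if was_training:
            self.train()
        glucose = float(out[..., 0] * GLU_SCALE + GLU_CENTER)
        p = float(1.0 / (1.0 + np.exp(-out[..., 1])))
        return StatusPrediction(glucose_mmol=glucose, wtr_prob=p)

    # -- roll-out -------------------------------------------------------------
    def rollout(self, obs_prefix: Trajectory, actions: Sequence[DoseAction], K: int
                ) -> tuple[list[StatusPrediction], list[float]]:
        """Unroll K steps from the encoded prefix under the given actions."""
        if K < 1:
            raise ValueError("K must be >= 1")
        if len(actions) != K:
            raise ValueError(f"expected exactly {K} actions, got {len(actions)}")
        s = self.encode(obs_prefix)
        preds, rewards = [], []
        for a in actions:
            s, r = self.step(s, a)
            preds.append(self.predict(s))
            rewards.append(r)
        return preds, rewards

    # -- checkpointing --------------------------------------------------------
    def save(self, path):
        meta = {
            "kind": "patient_model",
            "config": asdict(self.cfg),
            "cov_dim": self.cov_dim,
            "trained": self.trained,
        }
        nn.save_archive(path, self.state_dict(), meta)

    @classmethod
    def load(cls, path) -> "PatientModel":
        arrays, meta = nn.load_archive(path)
        if meta.get("kind") != "patient_model":
            raise ValueError(f"{path} is not a patient-model checkpoint")
        model = cls(PatientModelConfig(**meta["config"]), meta["cov_dim"])
        model.load_state_dict(arrays)
        model.trained = bool(meta["trained"])
        model.eval()
        return model


# ---------------------------------------------------------------------------
# Losses (scalar reference forms)
# ---------------------------------------------------------------------------


def consistency_loss(indexed_states: Sequence[tuple[int, np.ndarray]]) -> float:
    """Sum of squared L2 distances between all state pairs sharing an absolute
    timestep (reached via different start/depth splits).  0 when no pairs match."""
    total = 0.0
    found = False
    for i in range(len(indexed_states)):
        for j in range(i + 1, len(indexed_states)):
            ti, si = indexed_states[i]
            tj, sj = indexed_states[j]
            if ti == tj:
                found = True
                d = np.asarray(si, dtype=float) - np.asarray(sj, dtype=float)
                total += float(np.sum(d * d))
    if not found and len(indexed_states) > 1:
        return 0.0
    return total


def prediction_loss(pred: StatusPrediction, truth: tuple[float, bool]) -> float:
    """L_P = glucose MSE + WTR cross-entropy for one slot with measured truth."""
    g, label = truth
    if g is None:
        raise ValueError("prediction loss is undefined on a masked slot")
    mse = ((pred.glucose_mmol - g) / GLU_SCALE) ** 2
    p = min(max(pred.wtr_prob, 1e-12), 1 - 1e-12)
    ce = -np.log(p) if label else -np.log(1.0 - p)
    return float(mse + ce)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _masked_mean(sq: nn.Tensor, mask: np.ndarray) -> nn.Tensor:
    denom = max(float(mask.sum()), 1.0)
    return (sq * mask).sum() * (1.0 / denom)


def batch_losses(model: PatientModel, feats: dict[str, np.ndarray],
                 depth: int, consistency_depth: int) -> tuple[nn.Tensor, nn.Tensor]:
    """(L_T, L_P) on one padded batch, teacher-forcing logged actions.

    Rolled-out states at depth k are paired with the encoded state at the same
    absolute step (consistency, one pair per target step), and their
    predictions/rewards are penalized against the step-(t+k) ground truth.
    """
    T = feats["X"].shape[1]
    S = model.encode_features(feats)
    depth = min(depth, T - 1)
    cur = S
    l_p_terms: list[nn.Tensor] = []
    l_t = nn.Tensor(0.0)
    for k in range(1, depth + 1):
        Tk = T - k
        cur = cur[:, :Tk, :] if k > 1 else cur[:, : T - 1, :]
        tokens = feats["tokens"][:, k - 1 : T - 1]
        cls = feats["cls"][:, k - 1 : T - 1]
        cur, rew = model.step_tensor(cur, tokens, cls)
        vmask = feats["valid"][:, k:]
        gmask = feats["glu_mask"][:, k:] * vmask
        rmask = feats["reward_mask"][:, k:] * vmask
        pred = model.predict_tensor(cur)
        dg = pred[..., 0] - feats["glu_z"][:, k:]
        l_glu = _masked_mean(dg * dg, gmask)
        logits = pred[..., 1]
        # binary CE via log-sigmoid identities
        y = feats["wtr"][:, k:]
        lp1 = logits.sigmoid() * (1 - 2e-12) + 1e-12
        ce = -(lp1.log() * y + (1.0 - lp1).log() * (1 - y))
        l_tir = _masked_mean(ce, gmask)
        dr = rew - feats["rewards"][:, k:]
        l_rwd = _masked_mean(dr * dr, rmask)
        l_p_terms.append(l_glu + l_tir + l_rwd)
        if k == consistency_depth:
            target = S.detach()[:, k:, :]
            diff = cur - target
            l_t = _masked_mean((diff * diff).sum(axis=-1), vmask)
    l_p = l_p_terms[0]
    for term in l_p_terms[1:]:
        l_p = l_p + term
    l_p = l_p * (1.0 / len(l_p_terms))
    return l_t, l_p


def train_patient_model(
    cohort: Sequence[Trajectory],
    cfg: PatientModelConfig,
    train_cfg: TrainConfig = TrainConfig(),
) -> tuple[PatientModel, list[dict]]:
    """Joint training of f_R, f_T, f_P minimizing mu * L_T + L_P."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    cov_dim = len(cohort[0].observations[0].covariates)
    rng = np.random.default_rng(train_cfg.seed)
    model = PatientModel(cfg, cov_dim, seed=train_cfg.seed)
    model.train()
    opt = nn.Adam(model.parameters(), lr=train_cfg.lr,
                  weight_decay=train_cfg.weight_decay)
    n_val = int(round(train_cfg.val_fraction * len(cohort)))
    order = rng.permutation(len(cohort))
    val_idx = set(order[:n_val].tolist())
    train_trajs = [cohort[i] for i in range(len(cohort)) if i not in val_idx]
    history: list[dict] = []
    B = train_cfg.batch_size
    n_batches = 0
    for epoch in range(train_cfg.epochs):
        perm = rng.permutation(len(train_trajs))
        ep = {"epoch": epoch, "L_T": 0.0, "L_P": 0.0, "total": 0.0, "n": 0}
        for start in range(0, len(train_trajs), B):
            batch = [train_trajs[i] for i in perm[start : start + B]]
            feats = featurize(batch, cov_dim, cfg.pad_length)
            c_depth = n_batches % min(cfg.rollout_depth, feats["X"].shape[1] - 1) + 1
            l_t, l_p = batch_losses(model, feats, cfg.rollout_depth, c_depth)
            total = l_t * cfg.consistency_weight + l_p
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"patient-model training diverged (NaN/inf loss at epoch {epoch})"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            n_batches += 1
            ep["L_T"] += float(l_t.data)
            ep["L_P"] += float(l_p.data)
            ep["total"] += float(total.data)
            ep["n"] += 1
        for key in ("L_T", "L_P", "total"):
            ep[key] /= max(ep["n"], 1)
        history.append(ep)
    model.trained = True
    model.eval()
    return model, history


def one_day_ahead_mae(model: PatientModel, trajs: Sequence[Trajectory]) -> float:
    """Held-out 1-day-ahead glucose MAE: encode through each day's last slot,
    unroll the next day (K = 7) with the logged actions, compare predictions
    with the measured values."""
    errors: list[float] = []
    for traj in trajs:
        n_days = traj.observations[-1].day
        for day in range(1, n_days):
            end = next(
                (i for i, o in enumerate(traj.observations)
                 if o.day == day and o.slot == N_SLOTS - 1),
                None,
            )
            if end is None or end + N_SLOTS >= len(traj):
                continue
            prefix = Trajectory(
                traj.patient_id,
                traj.observations[: end + 1],
                traj.actions[: end + 1],
                traj.rewards[: end + 1],
            )
            acts = traj.actions[end : end + N_SLOTS]
            preds, _ = model.rollout(prefix, acts, N_SLOTS)
            for k in range(N_SLOTS):
                truth = traj.observations[end + 1 + k].glucose_mmol
                if truth is not None:
                    errors.append(abs(preds[k].glucose_mmol - truth))
    if not errors:
        raise ValueError("no evaluable day-ahead slots")
    return float(np.mean(errors))
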