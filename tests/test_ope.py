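import numpy as np
import pytest

from rltitr.ope import (
    SupportViolation,
    discounted_return,
    evaluate_policy_against_log,
    fit_behavior_policy,
    is_ratios,
    trajectory_probs,
    v_is,
    v_wis,
)


class ToyMDP:
    """Two-state chain: action 1 tends to move to the rewarding state."""

    def __init__(self, horizon=4):
        self.horizon = horizon

    def episode(self, policy, rng):
        """policy[state] = P(action=1). Returns (actions, states, rewards)."""
        s = 0
        actions, states, rewards = [], [], []
        for _ in range(self.horizon):
            states.append(s)
            a = int(rng.random() < policy[s])
            actions.append(a)
            p_good = 0.8 if a == 1 else 0.2
            s = int(rng.random() < p_good)
            rewards.append(1.0 if s == 1 else 0.0)
        return actions, states, rewards

    def logged_probs(self, policy, actions, states):
        return [policy[s] if a == 1 else 1 - policy[s]
                for a, s in zip(actions, states)]


class TestRatios:
    def test_identical_policies(self):
        rho, w = is_ratios([0.3, 0.5, 0.9], [0.3, 0.5, 0.9])
        assert np.allclose(rho, 1.0)
        assert w == pytest.approx(1.0)

    def test_deterministic_target(self):
        rho, w = is_ratios([0.25, 0.5], [1.0, 1.0])
        assert rho == pytest.approx([4.0, 2.0])
        assert w == pytest.approx(8.0)

    def test_hand_computed_products(self, rng):
        p0 = rng.uniform(0.1, 0.9, size=6)
        p1 = rng.uniform(0.1, 0.9, size=6)
        rho, w = is_ratios(p0, p1)
        assert w == pytest.approx(np.prod(p1 / p0))

    def test_support_violation_named(self):
        with pytest.raises(SupportViolation, match="step 1"):
            is_ratios([0.5, 0.0], [0.5, 0.5])


class TestEstimators:
    def test_identical_policies_recover_mean_return(self, rng):
        gamma = 0.9
        trajs = []
        for _ in range(20):
            r = rng.uniform(-1, 1, size=5)
            p = rng.uniform(0.2, 0.9, size=5)
            trajs.append((p, p.copy(), r))
        returns = [discounted_return(r, gamma) for _, _, r in trajs]
        assert v_is(trajs, gamma) == pytest.approx(np.mean(returns))
        res = v_wis(trajs, gamma)
        assert res.v_wis == pytest.approx(np.mean(returns))
        assert res.effective_sample_size == pytest.approx(len(trajs))
        assert res.weights.sum() == pytest.approx(1.0)

    def test_single_trajectory_weight_two(self):
        trajs = [(np.array([0.5]), np.array([1.0]), [1.0])]
        assert v_is(trajs, 0.9) == pytest.approx(2.0 * 1.0)

    def test_dominant_weight_limit(self):
        trajs = [
            ([0.5], [1.0], [5.0]),   # weight 2
            ([0.5], [1e-6], [-5.0]),  # weight ~0
        ]
        res = v_wis(trajs, 1.0)
        assert res.v_wis == pytest.approx(5.0, abs=1e-4)
        assert res.effective_sample_size == pytest.approx(1.0, abs=1e-4)

    def test_gamma_convention_starts_at_one(self):
        # sum gamma^(t-1) r_t with t from 1: first reward undiscounted
        assert discounted_return([1.0, 1.0], 0.5) == pytest.approx(1.5)

    def test_ess_bounded_by_n(self, rng):
        for _ in range(10):
            trajs = [(p, q, [0.0]) for p, q in
                     zip(rng.uniform(0.2, 0.9, size=(8, 1)),
                         rng.uniform(0.2, 0.9, size=(8, 1)))]
            res = v_wis(trajs, 0.9)
            assert 0 < res.effective_sample_size <= len(trajs) + 1e-9

    def test_degenerate_weights_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            v_wis([([0.5], [0.0], [1.0])], 0.9)
        with pytest.raises(ValueError):
            v_is([], 0.9)


class TestToyMDPConsistency:
    def test_is_and_wis_match_monte_carlo(self):
        """Off-policy estimates at N=10^4 fall within 3 SE of the direct
        on-policy Monte-Carlo value of the target policy."""
        mdp = ToyMDP(horizon=4)
        behavior = {0: 0.5, 1: 0.5}
        target = {0: 0.8, 1: 0.3}
        gamma = 0.9
        rng = np.random.default_rng(77)
        # ground truth: simulate target policy directly
        direct = [
            discounted_return(mdp.episode(target, rng)[2], gamma)
            for _ in range(10_000)
        ]
        truth, se = np.mean(direct), np.std(direct) / np.sqrt(len(direct))
        trajs = []
        for _ in range(10_000):
            actions, states, rewards = mdp.episode(behavior, rng)
            p0 = mdp.logged_probs(behavior, actions, states)
            p1 = mdp.logged_probs(target, actions, states)
            trajs.append((p0, p1, rewards))
        res = v_wis(trajs, gamma)
        is_se = np.std([
            w * g for w, g in zip(
                [is_ratios(p0, p1)[1] for p0, p1, _ in trajs],
                [discounted_return(r, gamma) for _, _, r in trajs])
        ]) / np.sqrt(len(trajs))
        assert abs(res.v_is - truth) < 3 * (is_se + se)
        assert abs(res.v_wis - truth) < 3 * (is_se + se)

    def test_wis_variance_not_larger_than_is(self):
        """Bootstrap over resamples: WIS has no larger variance than IS."""
        mdp = ToyMDP(horizon=4)
        behavior = {0: 0.5, 1: 0.5}
        target = {0: 0.9, 1: 0.2}
        rng = np.random.default_rng(5)
        trajs = []
        for _ in range(400):
            actions, states, rewards = mdp.episode(behavior, rng)
            trajs.append((mdp.logged_probs(behavior, actions, states),
                          mdp.logged_probs(target, actions, states), rewards))
        vis, vwis = [], []
        for _ in range(200):
            idx = rng.integers(0, len(trajs), size=len(trajs))
            sample = [trajs[i] for i in idx]
            vis.append(v_is(sample, 0.9))
            vwis.append(v_wis(sample, 0.9).v_wis)
        assert np.var(vwis) <= np.var(vis)


class TestBehaviorPolicyFit:
    def test_floor_and_normalization(self, small_cohort, trained_patient_model):
        _, trajs, _ = small_cohort
        model, _ = trained_patient_model
        behavior = fit_behavior_policy(trajs[:24], model, epochs=4, prob_floor=1e-3)
        s = model.encode(trajs[0])
        p = behavior.action_probs(s)
        assert p.min() >= 1e-3 - 1e-12
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fitted_behavior_tracks_logged_doses(self, small_cohort, trained_patient_model):
        """The estimated clinician policy concentrates near the doses actually
        logged: its modal dose is closer to the log than the log's marginal
        spread, and every logged action keeps positive probability."""
        from rltitr.policy_model import allowed_tokens, infer_schedule

        _, trajs, _ = small_cohort
        model, _ = trained_patient_model
        behavior = fit_behavior_policy(trajs, model, epochs=30, prob_floor=1e-3)
        gaps, logged = [], []
        for traj in trajs[:15]:
            probs = trajectory_probs(traj, model, behavior)
            schedule = infer_schedule(traj)
            states = model.encode_states(traj)
            allowed = np.stack(
                [allowed_tokens(schedule, o.slot) for o in traj.observations]
            )
            full = behavior.action_probs(states, allowed)
            for t, a in enumerate(traj.actions):
                if a.is_injection:
                    modal = int(np.argmax(full[t, 1:])) + 1
                    gaps.append(abs(modal - a.dose_units))
                    logged.append(a.dose_units)
            assert np.all(probs > 0)
        assert np.mean(gaps) < np.std(logged)

    def test_wis_of_behavior_policy_close_to_log_value(
        self, small_cohort, trained_patient_model
    ):
        """Evaluating the fitted behavior policy against its own log gives
        weights near uniform and an ESS close to N."""
        _, trajs, _ = small_cohort
        model, _ = trained_patient_model
        behavior = fit_behavior_policy(trajs[:20], model, epochs=6)
        res = evaluate_policy_against_log(trajs[:20], model, behavior, behavior)
        assert res.effective_sample_size == pytest.approx(20, abs=1e-6)
        returns = [
            discounted_return([r if r is not None else 0.0 for r in t.rewards], 0.9)
            for t in trajs[:20]
        ]
        assert res.v_wis == pytest.approx(np.mean(returns))
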