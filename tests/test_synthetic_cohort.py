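import numpy as np
import pytest

from rltitr.data_model import MGDL_PER_MMOL, N_SLOTS
from rltitr.reward import magni_reward
from rltitr.synthetic_cohort import (
    GLUCOSE_FLOOR,
    POST_MEAL_SLOTS,
    REGIMEN_SCHEDULES,
    CohortConfig,
    PatientLatents,
    add_observation_noise,
    degrade_trajectory,
    generate_cohort,
    response_glucose,
    simulate_policy,
)


def reference_response(latents, doses, n_days):
    """Independent re-implementation of the documented response equation."""
    n = n_days * N_SLOTS
    effect = np.zeros(n + N_SLOTS + 1)
    for (day, slot), (cls, dose) in doses.items():
        t = (day - 1) * N_SLOTS + slot
        if cls == "short_rapid":
            effect[t + 1] += dose
        elif cls == "long_acting":
            for u in range(t + 1, t + 1 + N_SLOTS):
                effect[u] += dose
        elif cls == "premixed":
            effect[t + 1] += dose / 2
            for u in range(t + 1, t + 1 + N_SLOTS):
                effect[u] += dose / 2
    out = np.zeros(n)
    for t in range(n):
        slot = t % N_SLOTS
        meal = latents.meal_effect[POST_MEAL_SLOTS[slot]] if slot in POST_MEAL_SLOTS else 0.0
        out[t] = max(
            latents.basal_glucose + meal
            - latents.insulin_sensitivity * effect[t],
            GLUCOSE_FLOOR,
        )
    return out


def fixed_latents(regimen="basal_only", sens=0.3, basal=10.5, oracle=None):
    return PatientLatents(
        insulin_sensitivity=sens,
        basal_glucose=basal,
        meal_effect=(2.5, 2.0, 3.0),
        noise_sd=0.0,
        regimen=regimen,
        oracle_doses=oracle or {6: 13},
        covariates=(0.0,) * 6,
    )


class TestGeneration:
    def test_same_seed_identical(self):
        cfg = CohortConfig(n_patients=8, n_days=2, seed=42)
        t1, l1 = generate_cohort(cfg)
        t2, l2 = generate_cohort(cfg)
        assert l1 == l2
        for a, b in zip(t1, t2):
            assert a.actions == b.actions
            assert [o.glucose_mmol for o in a.observations] == [
                o.glucose_mmol for o in b.observations
            ]

    def test_shapes(self):
        trajs, lats = generate_cohort(CohortConfig(n_patients=10, n_days=3, seed=0))
        assert len(trajs) == 10
        assert all(t.tau == 21 for t in trajs)
        assert all(l.regimen in REGIMEN_SCHEDULES for l in lats)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(regimen_mix={"premixed": 0.5})
        with pytest.raises(ValueError):
            CohortConfig(n_days=1)

    def test_noiseless_glucose_matches_reference_oracle(self):
        cfg = CohortConfig(n_patients=6, n_days=3, noise_sd=0.0, seed=5)
        trajs, lats = generate_cohort(cfg)
        for traj, lat in zip(trajs, lats):
            doses = {
                (o.day, o.slot): (a.insulin_class, a.dose_units)
                for o, a in zip(traj.observations, traj.actions)
                if a.is_injection
            }
            ref = reference_response(lat, doses, cfg.n_days)
            got = [o.glucose_mmol for o in traj.observations]
            assert np.allclose(got, ref, atol=1e-3)

    def test_generated_rewards_match_reward_module(self):
        trajs, _ = generate_cohort(CohortConfig(n_patients=4, n_days=2, seed=9))
        for t in trajs:
            for o, r in zip(t.observations, t.rewards):
                assert r == pytest.approx(
                    magni_reward(o.glucose_mmol * MGDL_PER_MMOL), abs=1e-9
                )

    def test_dose_response_monotonicity(self, rng):
        """In the noiseless simulator a larger dose never raises the next
        affected glucose value."""
        for _ in range(20):
            lat = fixed_latents(
                sens=float(rng.uniform(0.1, 0.6)),
                basal=float(rng.uniform(8, 13)),
            )
            d = int(rng.integers(1, 39))
            g_lo = response_glucose(lat, {(1, 6): ("long_acting", d)}, 2)
            g_hi = response_glucose(lat, {(1, 6): ("long_acting", d + 1)}, 2)
            assert np.all(g_hi <= g_lo + 1e-12)

    def test_oracle_doses_match_brute_force(self):
        """Stored oracle doses equal an independent brute-force minimization of
        steady-state squared deviation from target."""
        cfg = CohortConfig(n_patients=12, n_days=2, noise_sd=0.0, seed=21)
        _, lats = generate_cohort(cfg)
        checked = 0
        for lat in lats:
            if lat.regimen != "basal_only":
                continue
            sses = []
            for d in range(1, 41):
                doses = {(day, 6): ("long_acting", d) for day in (1, 2, 3)}
                g = reference_response(lat, doses, 3)[2 * N_SLOTS:]
                sses.append(np.sum((g - cfg.target_glucose) ** 2))
            assert lat.oracle_doses[6] == int(np.argmin(sses)) + 1
            checked += 1
        assert checked > 0


class TestDegradation:
    def test_high_k_is_identity(self, small_cohort):
        _, trajs, _ = small_cohort
        out = degrade_trajectory(trajs[0], 7, seed=1)
        assert [o.glucose_mmol for o in out.observations] == [
            o.glucose_mmol for o in trajs[0].observations
        ]

    def test_cardinality_per_day(self, small_cohort):
        _, trajs, _ = small_cohort
        out = degrade_trajectory(trajs[0], 2, seed=1)
        for day in {o.day for o in out.observations}:
            measured = sum(
                1 for o in out.observations if o.day == day and o.measured
            )
            assert measured == 2
        assert out.actions == trajs[0].actions

    def test_idempotent_under_same_seed(self, small_cohort):
        _, trajs, _ = small_cohort
        once = degrade_trajectory(trajs[0], 3, seed=4)
        twice = degrade_trajectory(once, 3, seed=4)
        surviving = lambda t: [i for i, o in enumerate(t.observations) if o.measured]
        assert surviving(twice) == surviving(once)

    def test_masked_rewards_follow_masked_glucose(self, small_cohort):
        _, trajs, _ = small_cohort
        out = degrade_trajectory(trajs[0], 1, seed=2)
        for o, r in zip(out.observations, out.rewards):
            assert (r is None) == (o.glucose_mmol is None)


class TestObservationNoise:
    def test_zero_sd_is_identity(self, small_cohort):
        _, trajs, _ = small_cohort
        out = add_observation_noise(trajs[0], 0.0, seed=0)
        assert [o.glucose_mmol for o in out.observations] == [
            o.glucose_mmol for o in trajs[0].observations
        ]

    def test_negative_sd_rejected(self, small_cohort):
        _, trajs, _ = small_cohort
        with pytest.raises(ValueError):
            add_observation_noise(trajs[0], -0.1, seed=0)

    def test_noise_is_centered(self):
        """Monte-Carlo: the mean perturbation over many draws is within 3
        standard errors of zero."""
        trajs, _ = generate_cohort(CohortConfig(n_patients=1, n_days=3, noise_sd=0.0, seed=3))
        clean = np.array([o.glucose_mmol for o in trajs[0].observations])
        sd = 0.5
        diffs = []
        for s in range(500):
            noisy = add_observation_noise(trajs[0], sd, seed=s)
            diffs.extend(
                n.glucose_mmol - c.glucose_mmol
                for n, c in zip(noisy.observations, trajs[0].observations)
            )
        diffs = np.array(diffs)
        se = sd / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se

    def test_masked_slots_stay_masked(self, small_cohort):
        _, trajs, _ = small_cohort
        masked = degrade_trajectory(trajs[0], 2, seed=0)
        noisy = add_observation_noise(masked, 0.3, seed=1)
        for a, b in zip(masked.observations, noisy.observations):
            assert a.measured == b.measured


class TestPolicySimulation:
    def test_oracle_policy_reaches_target(self):
        lat = fixed_latents(oracle={6: 13})
        traj = simulate_policy(lat, lambda *_: 13, 3, seed=0, noise_sd=0.0)
        day3 = [o.glucose_mmol for o in traj.observations if o.day == 3]
        # basal covers fasting slots; post-meal slots keep the meal rise
        assert day3[0] == pytest.approx(10.5 - 0.3 * 13, abs=1e-6)
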