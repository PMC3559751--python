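"""Simulator tests: schedule constraints, trial execution, learner dynamics."""

import numpy as np
import pytest

from erraug.augmentation import AugmentationSpec, ConfigurationError
from erraug.curves import extract_catch_series, fit_exponential
from erraug.geometry import ErrorProfile, TargetSpec, trajectory_error
from erraug.simulate import (
    GROUPS,
    LearnerState,
    TrialSpec,
    execute_trial,
    make_schedule,
    records_to_frame,
    simulate_error_sequence,
    simulate_experiment,
    simulate_subject,
    theoretical_gain_limit,
    update_learner,
)


class TestSchedule:
    def test_catch_counts(self, schedule):
        training = schedule.phase("training")
        baseline = schedule.phase("baseline")
        assert sum(t.is_catch for t in training) == 48  # floor(390/8) blocks
        assert sum(t.is_catch for t in baseline) == 15  # 120/8 probe blocks
        assert sum(t.is_catch for t in schedule.phase("washout")) == 0

    def test_no_adjacent_catches(self, schedule):
        flags = [t.is_catch for t in schedule]
        assert not any(a and b for a, b in zip(flags, flags[1:]))

    def test_probes_only_in_latter_baseline(self, schedule):
        probes = [t.phase_index for t in schedule.phase("baseline") if t.is_catch]
        assert min(probes) > 45

    def test_training_remainder_carries_no_catch(self, schedule):
        tail = [t for t in schedule.phase("training") if t.phase_index > 384]
        assert not any(t.is_catch for t in tail)

    def test_training_targets_balanced(self, schedule):
        angles = [t.target.angle_deg for t in schedule.phase("training")]
        assert sorted(set(angles)) == [-30.0, 90.0, 210.0]
        assert all(angles.count(a) == 130 for a in set(angles))

    def test_phase_structure_and_flags(self, schedule):
        assert len(schedule) == 165 + 390 + 165
        assert all(t.rotation_on for t in schedule.phase("training"))
        assert not any(t.rotation_on for t in schedule.phase("washout"))
        for t in schedule.phase("training"):
            assert t.augmentation_on != t.is_catch  # catches drop augmentation

    def test_many_seeds_satisfy_constraints(self):
        for seed in range(20):
            sched = make_schedule(seed)
            flags = [t.is_catch for t in sched]
            assert sum(flags) == 63
            assert not any(a and b for a, b in zip(flags, flags[1:]))

    def test_impossible_block_rejected(self):
        with pytest.raises(ConfigurationError):
            make_schedule(0, probe_block=1)


def _training_spec(target=None, rotation=True):
    return TrialSpec(
        index=200, phase="training", phase_index=36,
        target=target or TargetSpec(90.0, 0.1, "training"),
        rotation_on=rotation, augmentation_on=False, is_catch=False,
    )


class TestExecuteTrial:
    def test_zero_error_gives_straight_path(self):
        state = LearnerState(theta_hat_deg=30.0, motor_noise_sd_deg=0.0)
        traj, perceived, _ = execute_trial(
            state, _training_spec(), AugmentationSpec(), np.random.default_rng(0)
        )
        assert trajectory_error(traj) == pytest.approx(0.0, abs=1e-15)
        assert perceived == pytest.approx(0.0, abs=1e-12)

    def test_initial_exposure_magnitude(self):
        # delta = 30 deg, c = 0.6, R = 0.1 -> peak deviation 0.6*0.1*sin(30) = 0.03 m
        state = LearnerState(theta_hat_deg=0.0, motor_noise_sd_deg=0.0)
        traj, perceived, _ = execute_trial(
            state, _training_spec(), AugmentationSpec(), np.random.default_rng(0)
        )
        assert trajectory_error(traj) == pytest.approx(0.03, rel=1e-2)
        assert perceived == pytest.approx(30.0, rel=1e-3)

    def test_after_effect_mirror(self):
        # rotation off with full compensation: equal magnitude, opposite sign
        adapted = LearnerState(theta_hat_deg=30.0, motor_noise_sd_deg=0.0)
        naive = LearnerState(theta_hat_deg=0.0, motor_noise_sd_deg=0.0)
        on, _, _ = execute_trial(
            naive, _training_spec(rotation=True), AugmentationSpec(), np.random.default_rng(0)
        )
        off, _, _ = execute_trial(
            adapted, _training_spec(rotation=False), AugmentationSpec(), np.random.default_rng(0)
        )
        assert trajectory_error(off) == pytest.approx(-trajectory_error(on), rel=1e-9)

    def test_peak_speed_within_task_window_on_average(self):
        state = LearnerState()
        rng = np.random.default_rng(5)
        speeds = [
            execute_trial(state, _training_spec(), AugmentationSpec(), rng)[2]
            for _ in range(200)
        ]
        assert np.mean(speeds) == pytest.approx(0.45, abs=0.01)
        assert np.std(speeds) == pytest.approx(0.03, abs=0.01)


class TestLearnerUpdate:
    def test_update_rule(self):
        state = LearnerState(theta_hat_deg=5.0, lambda_frac=0.32)
        new = update_learner(state, 10.0)
        assert new.theta_hat_deg == pytest.approx(5.0 + 3.2)
        assert update_learner(state, 10.0, update_enabled=False).theta_hat_deg == 5.0

    @pytest.mark.parametrize(
        "gain, residual", [(1.0, 0.68), (3.1, 1 - 0.32 * 3.1), (6.25, -1.0)]
    )
    def test_one_trial_residual_factor(self, gain, residual):
        # linear regime: perceived error = g * delta, so after one update
        # delta_1/delta_0 = 1 - lambda*g (0.68 unaugmented, 0.008 at the
        # 3.1 stability limit, -1 marginal oscillation at lambda*g = 2)
        delta0 = 10.0
        state = LearnerState(lambda_frac=0.32)
        new = update_learner(state, gain * delta0)
        delta1 = delta0 - new.theta_hat_deg
        assert delta1 / delta0 == pytest.approx(residual, abs=1e-12)

    def test_gain_limit(self):
        assert theoretical_gain_limit(0.32) == pytest.approx(3.125)
        with pytest.raises(ValueError):
            theoretical_gain_limit(1.5)


class TestStabilityRegimes:
    """Trial-to-trial stability trichotomy at a small rotation (linear regime)."""

    def test_stable_monotone_below_limit(self):
        e = simulate_error_sequence(0.32, 1.0, rotation_deg=3.0, n_trials=15)
        assert np.all(e > 0)
        assert np.all(np.diff(np.abs(e)) < 0)

    def test_underdamped_alternates_between_one_and_two(self):
        e = simulate_error_sequence(0.32, 4.7, rotation_deg=3.0, n_trials=10)  # lg=1.504
        assert np.all(np.sign(e[1:]) == -np.sign(e[:-1]))
        assert np.all(np.abs(e[1:]) < np.abs(e[:-1]))

    def test_divergence_beyond_two(self):
        # small rotation keeps perceived error below its arcsin saturation
        e = simulate_error_sequence(0.32, 7.8, rotation_deg=0.5, n_trials=6)  # lg=2.496
        assert np.all(np.abs(e[1:]) > np.abs(e[:-1]))
        assert np.all(np.sign(e[1:]) == -np.sign(e[:-1]))


class TestOffsetFixedPoint:
    def test_error_nulling_learner_converges_to_minus_template(self):
        # an error-nulling learner drives the *displayed* error to zero,
        # so the actual steady-state error approaches -eps_o
        target = TargetSpec(90.0, 0.1, "training")
        grid = np.linspace(0.0, 0.1, 50)
        peak_o = 0.02
        template = ErrorProfile(grid, peak_o * np.sin(np.pi * grid / 0.1), target)
        aug = AugmentationSpec("offset", template=template)
        state = LearnerState(lambda_frac=0.9, motor_noise_sd_deg=0.0)
        rng = np.random.default_rng(0)
        spec = _training_spec(target)
        for _ in range(200):
            _, perceived, _ = execute_trial(state, spec, aug, rng)
            state = update_learner(state, perceived)
        traj, _, _ = execute_trial(state, spec, aug, rng)
        assert trajectory_error(traj) == pytest.approx(-peak_o, rel=0.02)


class TestSimulateSubject:
    def test_record_count_and_determinism(self, schedule):
        a = records_to_frame(simulate_subject("control", schedule, 11))
        b = records_to_frame(simulate_subject("control", schedule, 11))
        assert len(a) == 720
        assert a.equals(b)

    def test_different_seeds_differ(self, schedule):
        a = records_to_frame(simulate_subject("control", schedule, 11))
        b = records_to_frame(simulate_subject("control", schedule, 12))
        assert not a["trajectory_error_m"].equals(b["trajectory_error_m"])

    def test_unknown_group_rejected(self, schedule):
        with pytest.raises(ConfigurationError):
            simulate_subject("sham", schedule, 0)

    def test_noise_free_geometric_decay(self, schedule, noise_free_state):
        # in the angular domain, every un-augmented trial shrinks the
        # error by exactly (1 - lambda) = 0.68
        df = records_to_frame(
            simulate_subject("control", schedule, 0, state=noise_free_state)
        )
        tr = df[df["phase"] == "training"].head(8)
        ang = np.rad2deg(
            np.arcsin(np.clip(tr["trajectory_error_m"].to_numpy() / 0.06, -1, 1))
        )
        assert np.allclose(ang[1:] / ang[:-1], 0.68, rtol=1e-2)

    def test_washout_after_effect_opposite_sign(self, schedule, noise_free_state):
        df = records_to_frame(
            simulate_subject("control", schedule, 0, state=noise_free_state)
        )
        first_training = df[df["phase"] == "training"].iloc[0]
        first_washout = df[df["phase"] == "washout"].iloc[0]
        assert first_training["trajectory_error_m"] > 0
        assert first_washout["trajectory_error_m"] < 0
        assert abs(first_washout["trajectory_error_m"]) == pytest.approx(
            abs(first_training["trajectory_error_m"]), rel=0.1
        )

    def test_gain2_learns_faster_than_control(self, schedule, noise_free_state):
        fits = {}
        for grp in ("control", "x2"):
            df = records_to_frame(
                simulate_subject(grp, schedule, 0, state=noise_free_state)
            )
            fits[grp] = fit_exponential(extract_catch_series(df, "training"))
        assert fits["x2"].B < fits["control"].B

    def test_catch_residual_rms_calibration(self, schedule):
        # catch-trial scatter about the fitted exponential should sit near
        # the 0.94 mm RMS characteristic of this task (+/- 50%)
        rms = []
        for seed in range(4):
            df = records_to_frame(simulate_subject("control", schedule, 100 + seed))
            fit = fit_exponential(extract_catch_series(df, "training"))
            rms.append(fit.residual_rms)
        assert 0.47e-3 <= np.mean(rms) <= 1.41e-3


class TestSimulateExperiment:
    def test_full_design(self):
        df = simulate_experiment(2, group_size=1)
        assert df["subject_id"].nunique() == len(GROUPS)
        assert len(df) == len(GROUPS) * 720
        assert set(df["group"]) == set(GROUPS)
        # all subjects share the catch schedule
        catches = df[df["is_catch"]].groupby("subject_id")["index"].apply(tuple)
        assert catches.nunique() == 1

    def test_group_size_validation(self):
        with pytest.raises(ConfigurationError):
            simulate_experiment(0, group_size=0)
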