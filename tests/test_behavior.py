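"""Behavioral classifiers, escape probability, psychometrics, phases."""

import numpy as np
import pandas as pd
import pytest

from escapekit import behavior as bh
from escapekit.core_io import ArenaGeometry, SessionEvents
from escapekit.kinematics import compute_kinematics
from escapekit.synth import (
    BehaviorGenParams,
    generate_behavior,
    generate_trial_battery,
    scripted_evoked_trial,
    scripted_unstimulated_trial,
    simulate_escape_outcomes,
    track_from_path,
)


def kin_of(scenario):
    return compute_kinematics(scenario.track, scenario.geometry)


class TestEvokedEscape:
    def test_textbook_escape(self, geometry):
        sc = scripted_evoked_trial(30.0, 0.0, "escape", turn_delay=0.8, run_duration=1.5)
        trial = bh.classify_evoked_escape(kin_of(sc), sc.events.table.iloc[0], geometry)
        assert trial.eligible and trial.escaped
        # escape onset = last sample before the turn that follows the 0.8-s delay
        assert trial.escape_onset == pytest.approx(2.0 + 0.8, abs=0.06)
        assert trial.shelter_arrival - trial.stimulus_onset < 5.0

    def test_late_arrival_not_escape(self, geometry):
        sc = scripted_evoked_trial(48.0, 0.0, "escape", turn_delay=2.2, run_duration=3.0)
        trial = bh.classify_evoked_escape(kin_of(sc), sc.events.table.iloc[0], geometry)
        assert trial.eligible and not trial.escaped

    def test_too_close_to_shelter_ineligible(self, geometry):
        sc = scripted_evoked_trial(5.0, 0.0, "escape", run_duration=1.0)
        trial = bh.classify_evoked_escape(kin_of(sc), sc.events.table.iloc[0], geometry)
        assert not trial.eligible and not trial.escaped

    def test_facing_away_ineligible(self, geometry):
        sc = scripted_evoked_trial(30.0, 120.0, "amble")
        trial = bh.classify_evoked_escape(kin_of(sc), sc.events.table.iloc[0], geometry)
        assert not trial.eligible

    def test_tracking_gap_makes_trial_unusable(self, geometry):
        sc = scripted_evoked_trial(30.0, 0.0, "escape")
        sc.track.confidence["body_center"][120:160] = 0.0  # 800-ms gap post-onset
        trial = bh.classify_evoked_escape(kin_of(sc), sc.events.table.iloc[0], geometry)
        assert not trial.usable

    def test_peak_speed_window_rule(self, geometry):
        n = 400
        t = np.arange(n) / 50.0
        speed_profile = np.where((t > 1.0) & (t < 2.0), 60.0, 5.0)
        speed_profile[t > 6.0] = 90.0  # faster later, outside the window
        x = 30.0 + np.cumsum(speed_profile) / 50.0
        tr = track_from_path(t, np.column_stack([x, np.full(n, 13.0)]), np.zeros(n))
        kin = compute_kinematics(tr, geometry)
        assert bh.peak_escape_speed(kin, 0.5) == pytest.approx(60.0, rel=0.02)


class TestFreezing:
    @pytest.mark.parametrize(
        "still_s,expected", [(3.0, True), (1.5, False)], ids=["3s_still", "1.5s_still"]
    )
    def test_still_period_rule(self, geometry, still_s, expected):
        n = 500
        t = np.arange(n) / 50.0
        x = np.full(n, 40.0)
        moving = t > (1.0 + still_s)
        x = np.where(moving, 40.0 + 6.0 * (t - 1.0 - still_s), x)
        tr = track_from_path(t, np.column_stack([x, np.full(n, 13.0)]), np.zeros(n))
        kin = compute_kinematics(tr, geometry)
        assert bh.detect_freezing(kin, 1.0, 4.0) is expected

    def test_continuous_walking_not_freezing(self, geometry):
        n = 300
        t = np.arange(n) / 50.0
        x = 30.0 + 5.0 * t
        tr = track_from_path(t, np.column_stack([x, np.full(n, 13.0)]), np.zeros(n))
        kin = compute_kinematics(tr, geometry)
        assert not bh.detect_freezing(kin, 0.5, 4.0)

    def test_speed_method_matches_on_clean_data(self, geometry):
        sc = scripted_evoked_trial(30.0, 12.0, "freeze")
        kin = kin_of(sc)
        ev = sc.events.table.iloc[0]
        assert bh.detect_freezing(kin, ev.onset_s, ev.duration_s, method="speed")
        assert bh.detect_freezing(kin, ev.onset_s, ev.duration_s, method="displacement")


class TestLaserTiming:
    def build_turning_kin(self, geometry, total_turn_deg, turn_rate=200.0):
        n = 400
        t = np.arange(n) / 50.0
        h = np.clip((t - 1.0) * turn_rate, 0.0, total_turn_deg)
        body = np.tile([45.0, 13.0], (n, 1))
        tr = track_from_path(t, body, h)
        return compute_kinematics(tr, geometry)

    @pytest.mark.parametrize(
        "turn,expected",
        [(10.0, "before_initiation"), (90.0, "after_initiation"), (45.0, "unclassified")],
        ids=["small_turn", "large_turn", "gap_30_60"],
    )
    def test_cumulative_turn_classes(self, geometry, turn, expected):
        kin = self.build_turning_kin(geometry, turn)
        assert bh.classify_laser_timing(kin, 1.0, 3.0) == expected

    def test_near_shelter_excluded(self, geometry):
        n = 300
        t = np.arange(n) / 50.0
        tr = track_from_path(t, np.tile([15.0, 13.0], (n, 1)), np.zeros(n))  # d = 5 cm
        kin = compute_kinematics(tr, geometry)
        assert bh.classify_laser_timing(kin, 1.0, 3.0) == "excluded"


class TestRotationsAndRuns:
    def build(self, geometry, rot_rate, rot_dur, run_speed):
        n = 600
        t = np.arange(n) / 50.0
        h = np.clip((t - 2.0) * rot_rate, 0.0, rot_rate * rot_dur)
        speed = np.where((t > 5.0) & (t < 7.0), run_speed, 0.0)
        x = 40.0 + np.cumsum(speed) / 50.0
        tr = track_from_path(t, np.column_stack([x, np.full(n, 13.0)]), h)
        return compute_kinematics(tr, geometry)

    def test_fast_rotation_duration_rule(self, geometry):
        kin = self.build(geometry, 300.0, 0.15, 0.0)
        rot, _ = bh.detect_fast_rotations_and_runs(kin)
        assert len(rot) == 1

    def test_short_rotation_rejected(self, geometry):
        kin = self.build(geometry, 300.0, 0.06, 0.0)
        rot, _ = bh.detect_fast_rotations_and_runs(kin)
        assert len(rot) == 0

    def test_running_bout_peak_threshold(self, geometry):
        kin = self.build(geometry, 0.0, 0.0, 40.0)
        _, runs = bh.detect_fast_rotations_and_runs(kin)
        assert len(runs) == 1 and not runs.iloc[0]["escape"]
        kin = self.build(geometry, 0.0, 0.0, 30.0)
        _, runs = bh.detect_fast_rotations_and_runs(kin)
        assert len(runs) == 0


class TestSessionDetectors:
    def test_spontaneous_escape_detected(self, geometry):
        sc = scripted_unstimulated_trial("spontaneous_escape")
        prob, table, n_app = bh.detect_spontaneous_escapes(kin_of(sc), sc.events, geometry)
        assert n_app == 1 and len(table) == 1 and prob == 1.0

    def test_slow_return_not_spontaneous(self, geometry):
        sc = scripted_unstimulated_trial("return")
        prob, table, n_app = bh.detect_spontaneous_escapes(kin_of(sc), sc.events, geometry)
        assert len(table) == 0 and n_app == 1
        returns = bh.detect_non_escape_returns(kin_of(sc), sc.events)
        assert len(returns) == 1

    def test_fast_burst_before_arrival_not_a_return(self, geometry):
        sc = scripted_unstimulated_trial("spontaneous_escape", d_peak=60.0, run_duration=1.0)
        returns = bh.detect_non_escape_returns(kin_of(sc), sc.events)
        assert len(returns) == 0  # 60 cm in 1 s is far above the 40 cm/s ceiling

    def test_return_after_stimulus_excluded(self, geometry):
        sc = scripted_unstimulated_trial("return")
        events = SessionEvents(
            pd.DataFrame([{"kind": "loom", "onset_s": 2.0, "duration_s": 2.83, "contrast": 0.6}])
        )
        returns = bh.detect_non_escape_returns(kin_of(sc), events)
        assert len(returns) == 0

    def test_shelter_occupancy(self, geometry):
        n = 200
        t = np.arange(n) / 50.0
        x = np.where(np.arange(n) < 100, 5.0, 40.0)  # half inside
        tr = track_from_path(t, np.column_stack([x, np.full(n, 13.0)]), np.zeros(n))
        kin = compute_kinematics(tr, geometry)
        assert bh.shelter_occupancy(kin) == pytest.approx(0.5, abs=0.02)

    def test_displacement_after_loom_stationary_zero(self, geometry):
        n = 300
        t = np.arange(n) / 50.0
        tr = track_from_path(t, np.tile([40.0, 13.0], (n, 1)), np.zeros(n))
        kin = compute_kinematics(tr, geometry)
        assert bh.displacement_after_loom(kin, 1.0, 2.83) == pytest.approx(0.0, abs=1e-9)


class TestEscapeProbability:
    def trials(self):
        return pd.DataFrame(
            {
                "mouse_id": ["m0"] * 4,
                "contrast": [0.6] * 4,
                "eligible": [True] * 4,
                "usable": [True] * 4,
                "escaped": [True, True, True, False],
            }
        )

    def test_three_of_four(self):
        out = bh.escape_probability(self.trials())
        assert out["escape_probability"].iloc[0] == pytest.approx(0.75)

    def test_permutation_invariant_and_ineligible_ignored(self):
        df = self.trials()
        shuffled = df.sample(frac=1.0, random_state=0)
        extra = pd.concat(
            [df, pd.DataFrame([{"mouse_id": "m0", "contrast": 0.6, "eligible": False, "usable": True, "escaped": True}])]
        )
        p0 = bh.escape_probability(df)["escape_probability"].iloc[0]
        assert bh.escape_probability(shuffled)["escape_probability"].iloc[0] == p0
        assert bh.escape_probability(extra)["escape_probability"].iloc[0] == p0

    def test_empty_cell_is_missing_not_zero(self):
        df = self.trials()
        df["eligible"] = False
        out = bh.escape_probability(df)
        assert len(out) == 0


class TestPsychometric:
    def test_separation_flagged(self):
        df = pd.DataFrame(
            {
                "mouse_id": ["m0"] * 20,
                "contrast_pct": [20.0] * 10 + [98.0] * 10,
                "escaped": [False] * 10 + [True] * 10,
            }
        )
        fit = bh.fit_psychometric(df)
        assert fit.separation

    def test_parameter_recovery(self):
        beta0, beta1 = -2.0, 0.05
        cs = np.array([20.0, 40.0, 60.0, 98.0])
        truth = 1 / (1 + np.exp(-(beta0 + beta1 * cs)))
        hits = 0
        for seed in range(6):
            df = simulate_escape_outcomes(
                beta0, beta1, tuple(cs), 10, 40, np.random.default_rng(seed)
            )
            fit = bh.fit_psychometric(df)
            hits += np.max(np.abs(fit.predict(cs) - truth)) < 0.10
        assert hits >= 5

    def test_flat_generator_recovered_flat(self, rng):
        df = simulate_escape_outcomes(0.0, 0.0, (20.0, 40.0, 60.0, 98.0), 10, 40, rng)
        fit = bh.fit_psychometric(df)
        # flat within uncertainty: slope consistent with zero, curve nearly level
        assert abs(fit.beta1) < 3.0 * np.sqrt(fit.cov[1, 1])
        p = fit.predict(np.array([20.0, 98.0]))
        assert abs(p[1] - p[0]) < 0.15


class TestExperiencePhases:
    def make_trials(self, escapes, contrasts=None, t0=100.0):
        n = len(escapes)
        contrasts = contrasts if contrasts is not None else [0.55] * n
        return pd.DataFrame(
            {
                "stimulus_onset": t0 + 200.0 * np.arange(n),
                "contrast": contrasts,
                "spl_db": np.nan,
                "escaped": escapes,
            }
        )

    def test_first_trial_naive_then_experienced(self):
        trials = self.make_trials([True, True, False])
        phases, _ = bh.label_experience_phase(trials)
        assert phases.tolist()[:2] == ["naive", "experienced"]

    def test_three_consecutive_nonescapes_habituate(self):
        trials = self.make_trials([True, False, False, False, True])
        phases, bounds = bh.label_experience_phase(trials, habituation_start_s=250.0)
        assert phases.tolist()[-1] == "habituated"
        assert bounds["habituated_from_s"] == trials["stimulus_onset"].iloc[3]

    def test_broken_run_does_not_habituate(self):
        trials = self.make_trials([True, False, False, True, False])
        phases, bounds = bh.label_experience_phase(trials)
        assert "habituated" not in phases.tolist()
        assert np.isinf(bounds["habituated_from_s"])

    def test_high_contrast_nonescapes_do_not_count(self):
        trials = self.make_trials([True, False, False, False], contrasts=[0.99] * 4)
        phases, _ = bh.label_experience_phase(trials)
        assert "habituated" not in phases.tolist()


class TestGeneratorAgreement:
    """End-to-end: classifiers reproduce the generator's labels."""

    def test_noise_free_battery_perfect_agreement(self):
        scens = generate_trial_battery(60, noise_sd=0.0, seed=7)
        for sc in scens:
            kin = compute_kinematics(sc.track, sc.geometry)
            got = bh.scenario_label(kin, sc.events, sc.geometry)
            assert got == (sc.kind, sc.eligible, sc.label)

    def test_noisy_battery_high_agreement(self):
        scens = generate_trial_battery(60, noise_sd=0.3, seed=8)
        agree = sum(
            bh.scenario_label(compute_kinematics(sc.track, sc.geometry), sc.events, sc.geometry)
            == (sc.kind, sc.eligible, sc.label)
            for sc in scens
        )
        assert agree >= 0.95 * len(scens)

    def test_full_session_labels_match(self, geometry):
        params = BehaviorGenParams(
            session_length_s=600.0, seed=11, trigger_probability=0.8, min_loom_interval_s=60.0
        )
        track, events, truth = generate_behavior(params, geometry)
        kin = compute_kinematics(track, geometry)
        for (_, ev), (_, want) in zip(events.of_kind("loom").iterrows(), truth.trials.iterrows()):
            trial = bh.classify_evoked_escape(kin, ev, geometry)
            assert trial.escaped == want["escaped"]
            assert bh.detect_freezing(kin, ev["onset_s"], ev["duration_s"]) == want["froze"]
        _, spont, n_app = bh.detect_spontaneous_escapes(kin, events, geometry)
        returns = bh.detect_non_escape_returns(kin, events)
        assert len(spont) == len(truth.spontaneous)
        assert n_app == truth.n_approaches_unstimulated
        assert len(returns) == len(truth.returns)
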