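"""ΔF/F pipeline: detrend, isosbestic correction, z-score, resampling,
event-locked and distance-binned analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as stnum

from escapekit import photometry as ph
from escapekit.core_io import ArenaGeometry, PhotometryRecording, SessionEvents
from escapekit.kinematics import compute_kinematics
from escapekit.synth import (
    BehaviorGenParams,
    PhotometryGenParams,
    generate_behavior,
    generate_photometry,
    track_from_path,
)

FS = 120.0


class TestDetrend:
    def test_constant_trace_zeroed(self):
        out, flags = ph.detrend_running_median(np.full(1000, 7.0), FS, window_s=2.0)
        np.testing.assert_allclose(out, 0.0)

    def test_slow_bleach_attenuated(self):
        # residual drift measured on the window interior, where the centred
        # median is unbiased (the shrunken edge windows carry a small bias)
        t = np.arange(0, 2400, 1 / FS)
        bleach = 10.0 * np.exp(-t / 1800.0)
        out, _ = ph.detrend_running_median(bleach, FS, window_s=600.0)
        interior = slice(int(300 * FS), int(-300 * FS))
        assert np.ptp(out[interior]) < 0.10 * np.ptp(bleach)

    def test_fast_transient_preserved(self):
        t = np.arange(0, 1200, 1 / FS)
        transient = np.exp(-((t - 600.0) ** 2) / (2 * 0.25**2))
        out, _ = ph.detrend_running_median(5.0 + transient, FS, window_s=600.0)
        assert abs(out.max() - transient.max()) < 0.05 * transient.max()

    def test_short_session_flagged(self):
        out, flags = ph.detrend_running_median(np.arange(100.0), FS, window_s=600.0)
        assert "session_shorter_than_detrend_window" in flags


class TestIsosbesticCorrection:
    def test_pure_shared_artifact_cancels(self, rng):
        iso = rng.normal(0, 1, 5000)
        dff, a, b, _ = ph.isosbestic_correct(2.0 * iso, iso)
        assert np.max(np.abs(dff)) < 1e-9
        assert a == pytest.approx(2.0)

    def test_zero_isosbestic_degrades_to_mean_subtraction(self):
        ca = np.sin(np.linspace(0, 20, 1000)) + 3.0
        dff, a, b, flags = ph.isosbestic_correct(ca, np.zeros(1000))
        assert "zero_variance_isosbestic" in flags
        np.testing.assert_allclose(dff, ca - ca.mean())

    @given(stnum.floats(min_value=-3, max_value=3))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_adding_isosbestic_multiples(self, k):
        rng = np.random.default_rng(7)
        iso = rng.normal(0, 1, 2000)
        signal = np.sin(np.linspace(0, 30, 2000))
        base, *_ = ph.isosbestic_correct(signal + 0.8 * iso, iso)
        shifted, *_ = ph.isosbestic_correct(signal + (0.8 + k) * iso, iso)
        np.testing.assert_allclose(base, shifted, atol=1e-8)

    def test_generator_artifact_removed(self, geometry):
        params = BehaviorGenParams(session_length_s=240.0, seed=2)
        track, events, truth = generate_behavior(params, geometry)
        pp = PhotometryGenParams(artifact_amp=1.5, seed=3)
        rec, clean = generate_photometry(track, events, pp, geometry, rng=np.random.default_rng(3))
        trace, _ = ph.process_recording(rec, detrend_window_s=600.0)
        art_uncorrected = _explained_var(rec.f_ca - rec.f_ca.mean(), rec.f_iso)
        art_corrected = _explained_var(trace.dff, rec.f_iso)
        assert art_corrected < 0.05 * art_uncorrected
        zc = (clean - clean.mean()) / clean.std()
        assert np.corrcoef(trace.zdff, zc)[0, 1] >= 0.9


def _explained_var(y, x):
    x = (x - x.mean()) / x.std()
    return float(np.dot(y - y.mean(), x) ** 2 / len(y) ** 2)


class TestZScore:
    def test_affine_invariance(self, rng):
        x = rng.normal(3, 2, 1000)
        np.testing.assert_allclose(ph.zscore_session(x), ph.zscore_session(5 * x - 7), atol=1e-12)

    def test_two_valued_trace(self):
        z = ph.zscore_session(np.array([0.0, 2.0] * 50))
        assert set(np.round(z, 12)) == {-1.0, 1.0}

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ph.zscore_session(np.full(10, 1.0))


class TestResample:
    def test_constant_and_ramp_exact(self):
        t = np.arange(0, 10, 1 / FS)
        pulses = np.arange(0.5, 9.5, 0.02)
        out, _ = ph.resample_to_frames(np.full_like(t, 4.0), t, pulses)
        np.testing.assert_allclose(out, 4.0)
        ramp = 3.0 * t
        out, _ = ph.resample_to_frames(ramp, t, pulses)
        np.testing.assert_allclose(out, 3.0 * pulses, atol=1e-9)

    def test_sinusoid_interpolation_error_small(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * 10.0 * t)
        pulses = np.arange(0.5, 9.5, 0.02)
        out, _ = ph.resample_to_frames(x, t, pulses)
        # < 2% of the signal's peak-to-peak amplitude
        assert np.max(np.abs(out - np.sin(2 * np.pi * 10.0 * pulses))) < 0.02 * np.ptp(x)

    def test_pipeline_order_pinned(self, rng):
        """z-score before resampling (the pipeline order) differs from
        resampling before z-scoring whenever occupancy is uneven."""
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * 0.3 * t) + rng.normal(0, 0.1, len(t))
        pulses = np.arange(4.0, 9.5, 0.02)  # frames cover only part of the trace
        z_then_r, _ = ph.resample_to_frames(ph.zscore_session(x), t, pulses)
        r_first, _ = ph.resample_to_frames(x, t, pulses)
        r_then_z = ph.zscore_session(r_first)
        assert not np.allclose(z_then_r, r_then_z, atol=1e-3)


class TestLuminanceAxis:
    def test_protocol_levels_map_exactly(self):
        np.testing.assert_allclose(
            ph.luminance_change(np.array([1.0, 3.0, 9.0, 27.0, 81.0])), [-2, -1, 0, 1, 2], atol=1e-12
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ph.luminance_change(0.0)


class TestOnOffResponse:
    def test_sustained_step(self):
        t = np.arange(0, 20, 1 / FS)
        z = np.where((t >= 5.0) & (t < 10.0), 1.0, 0.0)
        on, off = ph.on_off_response(z, t, 5.0, 5.0)
        assert on == pytest.approx(1.0, abs=0.02)
        assert off == pytest.approx(-1.0, abs=0.02)

    def test_flat_trace_zero(self):
        t = np.arange(0, 20, 1 / FS)
        on, off = ph.on_off_response(np.zeros_like(t), t, 5.0, 5.0)
        assert on == 0.0 and off == 0.0

    def test_truncated_margin_dropped(self):
        t = np.arange(0, 3, 1 / FS)
        assert ph.on_off_response(np.zeros_like(t), t, 0.5, 5.0) is None


class TestEventAligned:
    def test_identical_trials_zero_sem(self):
        frame_times = np.arange(0, 60, 0.02)
        z = np.sin(2 * np.pi * frame_times / 5.0)
        anchors = {"m0": np.array([10.0, 15.0, 20.0]), "m1": np.array([25.0, 30.0])}
        out = ph.event_aligned_average(z, frame_times, anchors, window_s=(-1.0, 1.0))
        np.testing.assert_allclose(out["sem"], 0.0, atol=1e-12)

    def test_anchored_peak_recovered(self, geometry):
        params = BehaviorGenParams(session_length_s=400.0, seed=5, trigger_probability=0.9, min_loom_interval_s=40.0)
        track, events, truth = generate_behavior(params, geometry)
        pp = PhotometryGenParams(artifact_amp=0.3, noise_sd=0.02, shelter_gain=0.0, distance_slope=0.0, seed=6)
        rec, clean = generate_photometry(
            track, events, pp, geometry, escape_onsets=truth.escape_onsets, rng=np.random.default_rng(6)
        )
        trace, z50 = ph.process_recording(rec)
        anchors = truth.escape_onsets
        assert len(anchors) >= 2
        out = ph.event_aligned_average(z50, rec.camera_pulse_times, anchors, window_s=(-2.0, 3.0))
        peak_lag = out["lags_s"][np.argmax(out["mean"])]
        # transient kernel peaks ~0.26 s after onset; allow 200 ms either side
        assert 0.0 < peak_lag < 0.6

    def test_shuffled_anchors_flat(self, geometry, rng):
        frame_times = np.arange(0, 200, 0.02)
        z = rng.normal(0, 1, len(frame_times))
        anchors = rng.uniform(10, 190, 40)
        out = ph.event_aligned_average(z, frame_times, anchors, window_s=(-1.0, 1.0))
        assert np.max(np.abs(out["mean"])) < 0.8


class TestDistanceProfile:
    def _session(self, geometry, pp_kwargs, seed=9):
        params = BehaviorGenParams(session_length_s=500.0, seed=seed, trigger_probability=0.0)
        track, events, truth = generate_behavior(params, geometry)
        pp = PhotometryGenParams(artifact_amp=0.2, noise_sd=0.02, seed=seed, **pp_kwargs)
        rec, clean = generate_photometry(track, events, pp, geometry, rng=np.random.default_rng(seed))
        trace, z50 = ph.process_recording(rec)
        kin = compute_kinematics(track, geometry)
        from escapekit.behavior import threat_zone_entries

        epochs = ph.approach_epochs(kin, threat_zone_entries(kin, geometry))
        return kin, z50, epochs

    def test_shelter_gain_dominates_shelter_bin(self, geometry):
        kin, z50, epochs = self._session(geometry, dict(shelter_gain=2.0, distance_slope=0.0))
        prof = ph.distance_binned_activity(z50, kin, epochs)
        shelter = prof.loc[prof["bin"] == "shelter", "mean_zdff"].iloc[0]
        arena = prof.loc[prof["bin"] != "shelter", "mean_zdff"].dropna()
        assert shelter > arena.max()

    def test_distance_slope_recovered(self, geometry):
        kin, z50, epochs = self._session(geometry, dict(shelter_gain=0.0, distance_slope=-0.03))
        prof = ph.distance_binned_activity(z50, kin, epochs)
        arena = prof[(prof["bin"] != "shelter")].dropna(subset=["mean_zdff"])
        slope = np.polyfit(arena["distance_cm"], arena["mean_zdff"], 1)[0]
        # z-scoring rescales; the sign and monotonicity of the gradient survive
        assert slope < 0
        assert arena["mean_zdff"].iloc[0] > arena["mean_zdff"].iloc[-1]


class TestCovariateRegression:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        out = ph.activity_covariate_regression(2.0 * x, {"distance": x})
        row = out.iloc[0]
        assert row["r_squared"] == pytest.approx(1.0)
        assert row["slope"] == pytest.approx(2.0)

    def test_null_covariate_ci_covers_zero(self):
        covered = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            y = r.normal(0, 1, 20)
            x = r.normal(0, 1, 20)
            out = ph.activity_covariate_regression(y, {"noise": x}).iloc[0]
            covered += out["p_value"] > 0.05
        assert covered >= 45

    def test_generator_slope_sign_recovered(self, geometry):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 60, 30)
        activity = -0.05 * d + rng.normal(0, 0.1, 30)
        out = ph.activity_covariate_regression(activity, {"distance": d}).iloc[0]
        assert out["slope"] < 0 and out["p_value"] < 0.05

    def test_rank_deficiency_rejected(self):
        with pytest.raises(ValueError):
            ph.activity_covariate_regression(np.arange(5.0), {"const": np.ones(5)})
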