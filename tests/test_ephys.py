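"""Spike rates, responsiveness rules, population curves, suppression."""

import numpy as np
import pandas as pd
import pytest

from escapekit import ephys as ep
from escapekit.core_io import SpikeUnit
from escapekit.synth import (
    EphysGenParams,
    UnitGenSpec,
    generate_spikes,
    headfixed_protocol,
    make_population,
)


def regular_train(rate_hz, t_stop, t_start=0.0):
    return np.arange(t_start, t_stop, 1.0 / rate_hz)


class TestSpikeRate:
    def test_no_spikes_zero_everywhere(self):
        grid = np.arange(0, 5, 0.02)
        np.testing.assert_allclose(ep.spike_rate(np.empty(0), grid), 0.0)

    def test_single_spike_occupies_trailing_window(self):
        grid = np.arange(0, 2, 0.02)
        rate = ep.spike_rate(np.array([1.0]), grid)
        hot = np.where(rate > 0)[0]
        np.testing.assert_allclose(rate[hot], 20.0)  # 1 spike / 50 ms
        # the spike contributes to grid points within 50 ms after it
        assert grid[hot[0]] >= 1.0 and grid[hot[-1]] < 1.0 + 0.05 + 1e-9

    def test_regular_train_steady_state(self):
        grid = np.arange(1.001, 9, 0.02)
        rate = ep.spike_rate(regular_train(100.0, 10.0), grid)
        np.testing.assert_allclose(rate, 100.0)

    def test_integrates_to_spike_count(self, rng):
        spikes = np.sort(rng.uniform(0.1, 9.9, 500))
        # grid step dividing the window: every spike is counted exactly
        # window/step times, so the rate integrates to the spike count
        grid = np.arange(0.025, 10.026, 0.025)
        total = np.sum(ep.spike_rate(spikes, grid)) * 0.025
        assert abs(total - 500) < 1.0


class TestUnitFilter:
    def make_unit(self, rate, uid=0, quality="single", layer_depth=800.0):
        return SpikeUnit(uid, regular_train(rate, 100.0), layer_depth, quality)

    def test_five_hz_threshold(self):
        quiet = [(0.0, 100.0)]
        units = [self.make_unit(4.9, 0), self.make_unit(5.1, 1)]
        kept = ep.filter_units_for_laser_analysis(units, quiet)
        assert [u.unit_id for u in kept] == [1]

    def test_multiunit_and_superficial_excluded(self):
        quiet = [(0.0, 100.0)]
        units = [
            self.make_unit(10.0, 0, quality="multi"),
            self.make_unit(10.0, 1, layer_depth=100.0),
            self.make_unit(10.0, 2),
        ]
        kept = ep.filter_units_for_laser_analysis(units, quiet)
        assert [u.unit_id for u in kept] == [2]

    def test_all_below_threshold_empty(self):
        quiet = [(0.0, 100.0)]
        assert ep.filter_units_for_laser_analysis([self.make_unit(1.0)], quiet) == []


class TestLoomResponsiveness:
    def unit_with_step(self, base_hz, evoked_hz, step_duration, onsets, t_stop=400.0):
        """Deterministic regular trains: baseline plus an evoked step."""
        spikes = [regular_train(base_hz, t_stop)]
        for o in onsets:
            spikes.append(o + 0.001 + np.arange(0, step_duration, 1.0 / evoked_hz))
        return SpikeUnit(0, np.sort(np.concatenate(spikes)), 800.0)

    def test_long_strong_step_detected(self):
        onsets = np.arange(10.0, 300.0, 10.0)
        u = self.unit_with_step(10.0, 60.0, 0.3, onsets)
        assert ep.classify_loom_responsive(u, onsets)

    def test_short_excursion_rejected(self):
        onsets = np.arange(10.0, 300.0, 10.0)
        u = self.unit_with_step(10.0, 60.0, 0.15, onsets)
        assert not ep.classify_loom_responsive(u, onsets)

    def test_stationary_unit_rarely_flagged(self, rng):
        onsets = np.arange(10.0, 260.0, 10.0)
        fp = 0
        for _ in range(40):
            spikes = np.sort(rng.uniform(0, 300, 3000))  # 10 Hz Poisson-ish
            fp += ep.classify_loom_responsive(SpikeUnit(0, spikes, 800.0), onsets)
        assert fp / 40 < 0.25


class TestWindowedResponses:
    def unit_with_gain(self, base_hz, delta_hz, onsets, duration):
        spikes = [regular_train(base_hz, 500.0)]
        if delta_hz > 0:
            for o in onsets:
                spikes.append(o + 0.001 + np.arange(0, duration, 1.0 / delta_hz))
            st = np.sort(np.concatenate(spikes))
        else:  # suppression: thin the baseline inside the window
            st = spikes[0]
            for o in onsets:
                inwin = (st >= o) & (st < o + duration)
                keep = np.ones(len(st), bool)
                idx = np.where(inwin)[0]
                keep[idx[:: max(int(round(1 / (1 + delta_hz / base_hz))), 2)]] = False
                st = st[keep]
        return SpikeUnit(0, st, 800.0)

    def test_sound_rule_is_one_sided(self):
        onsets = np.arange(20.0, 400.0, 10.0)
        suppressed = self.unit_with_gain(20.0, -10.0, onsets, 3.0)
        assert not ep.classify_windowed_response(suppressed, onsets, 3.0, two_sided=False)
        assert ep.classify_windowed_response(suppressed, onsets, 3.0, two_sided=True)

    def test_grating_rule_is_two_sided_for_enhancement_too(self):
        onsets = np.arange(20.0, 400.0, 10.0)
        enhanced = self.unit_with_gain(20.0, 15.0, onsets, 2.0)
        assert ep.classify_windowed_response(enhanced, onsets, 2.0, two_sided=True)

    def test_generator_sound_only_unit_classified(self):
        prot = headfixed_protocol(n_blocks=4, isi_s=6.0, n_sound=25, rng=np.random.default_rng(0))
        spec = UnitGenSpec(baseline_hz=10.0, unit_class="sound_only", sound_gain_hz=30.0, suppression=0.0)
        ds = generate_spikes(prot, EphysGenParams(units=[spec]), rng=np.random.default_rng(1))
        looms99 = prot[(prot.kind == "loom") & np.isclose(prot.contrast, 0.99) & ~prot.laser]["onset_s"].to_numpy()
        sounds = prot[prot.kind == "sound"]["onset_s"].to_numpy()
        prof = ep.profile_unit(ds.units[0], looms99, sound_onsets=sounds)
        assert prof.unit_class == "sound_only"


@pytest.fixture(scope="module")
def dataset():
    prot = headfixed_protocol(n_blocks=10, isi_s=8.0, n_sound=0, n_blank_laser=15, rng=np.random.default_rng(3))
    specs = [
        UnitGenSpec(baseline_hz=b, unit_class="visual_only", loom_gain_hz=g, suppression=0.3)
        for b, g in [(8.0, 30.0), (12.0, 40.0), (15.0, 25.0), (10.0, 35.0)]
    ]
    ds = generate_spikes(prot, EphysGenParams(units=specs), rng=np.random.default_rng(4))
    return ds, prot[prot.kind == "loom"].copy(), prot


class TestPopulationCurve:

    def test_reference_cell_normalizes_to_one(self, dataset):
        ds, looms, _ = dataset
        curve = ep.population_loom_curve(ds.units, looms)
        assert curve.control[np.isclose(curve.contrasts, 0.99)][0] == pytest.approx(1.0)

    def test_curve_increases_with_contrast(self, dataset):
        ds, looms, _ = dataset
        curve = ep.population_loom_curve(ds.units, looms)
        assert np.all(np.diff(curve.control) > -0.05)
        assert curve.control[0] < curve.control[-1]

    def test_missing_reference_contrast_rejected(self, dataset):
        ds, looms, _ = dataset
        with pytest.raises(ValueError):
            ep.population_loom_curve(ds.units, looms[~np.isclose(looms.contrast, 0.99)])

    def test_suppression_recovered(self, dataset):
        ds, looms, _ = dataset
        s = ep.population_laser_suppression(ds.units, looms)
        assert s == pytest.approx(0.3, abs=0.05)

    def test_no_suppression_null(self):
        prot = headfixed_protocol(n_blocks=10, isi_s=8.0, n_sound=0, n_blank_laser=0, rng=np.random.default_rng(5))
        specs = [UnitGenSpec(baseline_hz=12.0, unit_class="visual_only", suppression=0.0) for _ in range(4)]
        ds = generate_spikes(prot, EphysGenParams(units=specs), rng=np.random.default_rng(6))
        s = ep.population_laser_suppression(ds.units, prot[prot.kind == "loom"])
        assert abs(s) < 0.06

    def test_suppression_invariant_to_rate_rescaling(self, dataset):
        ds, looms, _ = dataset
        s1 = ep.population_laser_suppression(ds.units, looms)
        # doubling every unit's spikes (merging each unit with itself) leaves
        # the relative suppression unchanged
        doubled = [
            SpikeUnit(u.unit_id, np.sort(np.concatenate([u.spike_times, u.spike_times + 1e-4])), u.depth_um)
            for u in ds.units
        ]
        s2 = ep.population_laser_suppression(doubled, looms)
        assert s1 == pytest.approx(s2, abs=1e-3)


class TestSpontaneousSuppression:
    def _blank_trials(self, pre_hz, during_counts):
        """One unit with `pre_hz` baseline before each blank-laser onset and
        the given spike counts in each 1.5-s laser window (onsets 20 s apart)."""
        onsets = 20.0 * np.arange(1, len(during_counts) + 1)
        spikes = []
        for o, n in zip(onsets, during_counts):
            spikes.append(o - 0.5 + np.arange(int(pre_hz * 0.5)) / pre_hz)
            if n:
                spikes.append(o + 0.01 + np.arange(n) * (1.48 / n))
        return SpikeUnit(0, np.sort(np.concatenate(spikes)), 800.0), onsets

    def test_arithmetic_examples(self):
        # mean rate 10 -> 7.5 Hz during laser: suppression 0.25
        u, onsets = self._blank_trials(10.0, [11, 11, 12, 11])  # 11.25 avg over 1.5 s
        assert ep.unit_laser_suppression_spontaneous(u, onsets) == pytest.approx(0.25)
        # facilitation 10 -> 12 Hz: -0.2 (negative = rate increase)
        u, onsets = self._blank_trials(10.0, [18])
        assert ep.unit_laser_suppression_spontaneous(u, onsets) == pytest.approx(-0.2)

    def test_class_separation_recovered(self):
        prot = headfixed_protocol(n_blocks=2, isi_s=6.0, n_sound=10, n_blank_laser=30, rng=np.random.default_rng(7))
        specs = [
            UnitGenSpec(baseline_hz=15.0, unit_class="visual_only", suppression=0.36)
            for _ in range(10)
        ] + [UnitGenSpec(baseline_hz=15.0, unit_class="sound_only", suppression=0.0) for _ in range(10)]
        ds = generate_spikes(prot, EphysGenParams(units=specs), rng=np.random.default_rng(8))
        blanks = prot[prot.kind == "laser_blank"]["onset_s"].to_numpy()
        vis = np.median([ep.unit_laser_suppression_spontaneous(u, blanks) for u in ds.units[:10]])
        aud = np.median([ep.unit_laser_suppression_spontaneous(u, blanks) for u in ds.units[10:]])
        assert vis - aud == pytest.approx(0.36, abs=0.08)
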