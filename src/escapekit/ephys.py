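"""Spike-train quantification: rates, responsiveness classes, suppression.

Rates use a 50-ms causal average filter evaluated on a 50-Hz grid.  A unit is
loom-responsive if its trial-averaged rate after a 99%-contrast, no-laser
loom exceeds (baseline mean + 2 SD) continuously for >= 200 ms within the
first 500 ms; sound responsiveness is one-sided above baseline, grating and
blank-laser responsiveness are two-sided deviations.  Population suppression
is the relative rate reduction over the 3-s post-onset window at 99% contrast
with versus without optogenetic stimulation of the inhibitory afferents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from escapekit.core_io import SpikeDataset, SpikeUnit

RATE_WINDOW_S = 0.05
RATE_GRID_HZ = 50.0
BASELINE_WINDOW_S = 0.5
RESPONSE_WINDOW_S = 0.5
MIN_RESPONSIVE_DURATION_S = 0.2
POPULATION_WINDOW_S = 3.0
MIN_SPONTANEOUS_RATE_HZ = 5.0
BLANK_LASER_WINDOW_S = 1.5


@dataclass
class UnitResponseProfile:
    """Responsiveness summary for one unit."""

    unit_id: int
    baseline_rate: float
    loom_responsive: bool = False
    sound_responsive: bool = False
    grating_responsive: bool = False
    laser_modulated: bool = False
    suppression_spontaneous: float = np.nan
    layer: str = "intermediate"
    quality: str = "single"

    @property
    def visual(self) -> bool:
        return self.loom_responsive or self.grating_responsive

    @property
    def unit_class(self) -> str:
        """visual / non_visual on the visual axis; visual_only / sound_only
        for the modality-specific split."""
        if self.visual and not self.sound_responsive:
            return "visual_only"
        if self.sound_responsive and not self.visual:
            return "sound_only"
        if self.visual:
            return "visual"
        return "non_visual"


def spike_rate(
    spike_times: np.ndarray,
    t_grid: np.ndarray,
    window_s: float = RATE_WINDOW_S,
) -> np.ndarray:
    """Causal average-filter rate: spike count in the trailing ``window_s``
    at each grid time, divided by the window."""
    st = np.asarray(spike_times, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    hi = np.searchsorted(st, t, side="right")
    lo = np.searchsorted(st, t - window_s, side="right")
    return (hi - lo) / window_s


def mean_rate(spike_times: np.ndarray, t_start: float, t_stop: float) -> float:
    """Plain spike count / duration over [t_start, t_stop)."""
    st = np.asarray(spike_times, dtype=float)
    n = np.searchsorted(st, t_stop) - np.searchsorted(st, t_start)
    return float(n) / (t_stop - t_start)


def spontaneous_rate(unit: SpikeUnit, quiet_intervals: list[tuple[float, float]]) -> float:
    """Average rate over stimulus-free (inter-trial) intervals."""
    total_n = 0
    total_t = 0.0
    st = unit.spike_times
    for a, b in quiet_intervals:
        total_n += int(np.searchsorted(st, b) - np.searchsorted(st, a))
        total_t += b - a
    if total_t <= 0:
        return float("nan")
    return total_n / total_t


def filter_units_for_laser_analysis(
    units: list[SpikeUnit],
    quiet_intervals: list[tuple[float, float]],
    min_rate_hz: float = MIN_SPONTANEOUS_RATE_HZ,
    single_only: bool = True,
    layers: tuple[str, ...] = ("intermediate", "deep"),
) -> list[SpikeUnit]:
    """Units eligible for the spontaneous-suppression analysis: single units
    in the configured layers with spontaneous rate >= 5 Hz."""
    kept = [
        u
        for u in units
        if (not single_only or u.quality == "single")
        and u.layer in layers
        and spontaneous_rate(u, quiet_intervals) >= min_rate_hz
    ]
    return kept


# ---------------------------------------------------------------------------
# responsiveness rules
# ---------------------------------------------------------------------------


def _trial_averaged_rate(
    unit: SpikeUnit, onsets: np.ndarray, pre_s: float, post_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged causal rate on a 50-Hz peri-stimulus grid."""
    dt = 1.0 / RATE_GRID_HZ
    lags = np.arange(-pre_s + dt, post_s + dt / 2, dt)
    rates = [spike_rate(unit.spike_times, o + lags) for o in np.atleast_1d(onsets)]
    return lags, np.mean(rates, axis=0)


def classify_loom_responsive(
    unit: SpikeUnit,
    loom_onsets: np.ndarray,
    *,
    sd_floor: float = 1e-6,
) -> bool:
    """2-SD / 200-ms loom-responsiveness rule.

    The trial-averaged rate must exceed (baseline mean + 2 x baseline SD)
    continuously for at least 200 ms within the first 500 ms after onset.
    Baseline statistics are taken across the time bins of the trial-averaged
    rate in the 500 ms before onset.  Apply to 99%-contrast no-laser trials.
    """
    lags, rate = _trial_averaged_rate(unit, loom_onsets, BASELINE_WINDOW_S, RESPONSE_WINDOW_S)
    pre = rate[lags <= 0]
    post = rate[lags > 0]
    mu, sd = float(np.mean(pre)), float(np.std(pre))
    thresh = mu + 2.0 * max(sd, sd_floor)
    above = post > thresh
    need = int(round(MIN_RESPONSIVE_DURATION_S * RATE_GRID_HZ))
    run = 0
    for a in above:
        run = run + 1 if a else 0
        if run >= need:
            return True
    return False


def classify_windowed_response(
    unit: SpikeUnit,
    onsets: np.ndarray,
    response_window_s: float,
    *,
    two_sided: bool,
    sd_floor: float = 1e-6,
) -> bool:
    """Mean-response rule for sounds / gratings / blank-laser trials.

    The trial-averaged mean rate in the response window is compared with the
    baseline (500 ms pre-onset) mean +/- 2 SD across baseline time bins:
    one-sided above for sounds, two-sided for gratings and laser blanks.
    """
    onsets = np.atleast_1d(onsets)
    lags, rate = _trial_averaged_rate(unit, onsets, BASELINE_WINDOW_S, response_window_s)
    pre = rate[lags <= 0]
    post = rate[lags > 0]
    mu, sd = float(np.mean(pre)), float(np.std(pre))
    sd = max(sd, sd_floor)
    resp = float(np.mean(post))
    if two_sided:
        return bool(abs(resp - mu) > 2.0 * sd)
    return bool(resp - mu > 2.0 * sd)


def profile_unit(
    unit: SpikeUnit,
    loom99_onsets: np.ndarray,
    sound_onsets: np.ndarray | None = None,
    grating_onsets: np.ndarray | None = None,
    blank_laser_onsets: np.ndarray | None = None,
    quiet_intervals: list[tuple[float, float]] | None = None,
    sound_duration_s: float = 3.0,
    grating_duration_s: float = 2.0,
) -> UnitResponseProfile:
    """Apply every responsiveness rule to one unit."""
    base = (
        spontaneous_rate(unit, quiet_intervals)
        if quiet_intervals
        else mean_rate(unit.spike_times, 0.0, max(float(unit.spike_times[-1]), 1.0))
        if len(unit.spike_times)
        else 0.0
    )
    prof = UnitResponseProfile(
        unit_id=unit.unit_id, baseline_rate=base, layer=unit.layer, quality=unit.quality
    )
    prof.loom_responsive = classify_loom_responsive(unit, loom99_onsets)
    if sound_onsets is not None and len(sound_onsets):
        prof.sound_responsive = classify_windowed_response(
            unit, sound_onsets, sound_duration_s, two_sided=False
        )
    if grating_onsets is not None and len(grating_onsets):
        prof.grating_responsive = classify_windowed_response(
            unit, grating_onsets, grating_duration_s, two_sided=True
        )
    if blank_laser_onsets is not None and len(blank_laser_onsets):
        prof.laser_modulated = classify_windowed_response(
            unit, blank_laser_onsets, BLANK_LASER_WINDOW_S, two_sided=True
        )
        prof.suppression_spontaneous = unit_laser_suppression_spontaneous(
            unit, blank_laser_onsets
        )
    return prof


# ---------------------------------------------------------------------------
# population curves and suppression
# ---------------------------------------------------------------------------


@dataclass
class PopulationLoomCurve:
    """Contrast-response curve normalized to the 99% no-laser response."""

    contrasts: np.ndarray
    control: np.ndarray
    laser: np.ndarray
    pre_stimulus_reference: float


def population_loom_curve(
    units: list[SpikeUnit],
    loom_trials: pd.DataFrame,
    window_s: float = POPULATION_WINDOW_S,
) -> PopulationLoomCurve:
    """Mean population rate over the 3-s post-onset window per contrast and
    laser condition, normalized to the no-laser 99%-contrast response.

    ``loom_trials`` needs columns onset_s, contrast, laser.  All unit types
    (single and multi) are combined.
    """
    contrasts = np.sort(loom_trials["contrast"].unique())
    if not np.any(np.isclose(contrasts, 0.99)):
        raise ValueError("no 99%-contrast trials to normalize against")

    def _mean_pop_rate(sub: pd.DataFrame, a: float, b: float) -> float:
        vals = []
        for onset in sub["onset_s"]:
            for u in units:
                vals.append(mean_rate(u.spike_times, onset + a, onset + b))
        return float(np.mean(vals))

    ref_sub = loom_trials[np.isclose(loom_trials["contrast"], 0.99) & ~loom_trials["laser"]]
    if ref_sub.empty:
        raise ValueError("no 99%-contrast no-laser trials to normalize against")
    ref = _mean_pop_rate(ref_sub, 0.0, window_s)
    pre = _mean_pop_rate(loom_trials[~loom_trials["laser"]], -BASELINE_WINDOW_S, 0.0)

    control, laser = [], []
    for c in contrasts:
        for cond, acc in ((False, control), (True, laser)):
            sub = loom_trials[np.isclose(loom_trials["contrast"], c) & (loom_trials["laser"] == cond)]
            acc.append(_mean_pop_rate(sub, 0.0, window_s) / ref if len(sub) else np.nan)
    return PopulationLoomCurve(
        contrasts=contrasts,
        control=np.asarray(control),
        laser=np.asarray(laser),
        pre_stimulus_reference=pre / ref,
    )


def population_laser_suppression(
    units: list[SpikeUnit],
    loom_trials: pd.DataFrame,
    window_s: float = POPULATION_WINDOW_S,
    contrast: float = 0.99,
) -> float:
    """Relative rate reduction (1 - laser/control) over the 3-s window at the
    given contrast; positive values mean the stimulation decreased spiking."""
    sel = np.isclose(loom_trials["contrast"], contrast)
    ctrl = loom_trials[sel & ~loom_trials["laser"]]
    las = loom_trials[sel & loom_trials["laser"]]
    if ctrl.empty or las.empty:
        raise ValueError("need both laser and control trials at the reference contrast")

    def _pop(sub: pd.DataFrame) -> float:
        vals = [
            mean_rate(u.spike_times, onset, onset + window_s)
            for onset in sub["onset_s"]
            for u in units
        ]
        return float(np.mean(vals))

    control_rate = _pop(ctrl)
    if control_rate == 0:
        return float("nan")
    return 1.0 - _pop(las) / control_rate


def population_laser_suppression_by_layer(
    units: list[SpikeUnit], loom_trials: pd.DataFrame, **kw
) -> dict[str, float]:
    out = {}
    for layer in ("superficial", "intermediate", "deep"):
        sub = [u for u in units if u.layer == layer]
        if sub:
            out[layer] = population_laser_suppression(sub, loom_trials, **kw)
    return out


def unit_laser_suppression_spontaneous(
    unit: SpikeUnit,
    blank_laser_onsets: np.ndarray,
    during_s: float = BLANK_LASER_WINDOW_S,
    pre_s: float = BASELINE_WINDOW_S,
) -> float:
    """Per-unit spontaneous suppression: the average relative rate change,
    1 - <rate during first 1.5 s of laser> / <rate in the 500 ms pre>, with
    both rates averaged across blank-laser trials before taking the ratio
    (a per-trial ratio is unstable when the 500-ms baseline holds only a
    handful of spikes; averaging first gives an unbiased relative change).
    Negative values indicate facilitation.  A unit silent in every baseline
    window -> NaN."""
    onsets = np.atleast_1d(blank_laser_onsets)
    pre = np.mean([mean_rate(unit.spike_times, o - pre_s, o) for o in onsets])
    if pre == 0:
        return float("nan")
    during = np.mean([mean_rate(unit.spike_times, o, o + during_s) for o in onsets])
    return float(1.0 - during / pre)


def per_mouse_average(values: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Recording-level values -> one value per mouse (recordings averaged
    within mouse before cross-mouse statistics)."""
    per_rec = values.groupby(["mouse_id", "recording_id"])[value_col].mean().reset_index()
    return per_rec.groupby("mouse_id")[value_col].mean().reset_index()
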