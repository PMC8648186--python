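"""Isosbestic-corrected ΔF/F pipeline and downstream photometry analyses.

Pipeline order is fixed: running-median detrend of both channels ->
least-squares fit of the isosbestic channel to the calcium channel and
subtraction (motion/artifact correction) -> session z-score -> resampling to
the 50-Hz camera frames.  The isosbestic channel carries the shared,
calcium-independent components (bleaching residue, patch-cord motion), so
subtracting its fitted projection removes them from the calcium channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from escapekit.core_io import PhotometryRecording
from escapekit.kinematics import KinematicSeries

BASELINE_LUMINANCE = 9.0  # cd/m^2


@dataclass
class DffTrace:
    """Corrected fluorescence trace with processing provenance."""

    timestamps: np.ndarray
    dff: np.ndarray
    zdff: np.ndarray | None = None
    iso_slope: float = np.nan
    iso_intercept: float = np.nan
    detrend_window_s: float = np.nan
    flags: list[str] = field(default_factory=list)


def detrend_running_median(
    x: np.ndarray, sample_rate: float, window_s: float = 600.0
) -> tuple[np.ndarray, list[str]]:
    """Subtract a slow centred running median (default 10 min).

    Removes photobleaching and other slow drifts while leaving fast
    transients nearly untouched.  Sessions shorter than the window fall back
    to a single global median (flagged).
    """
    x = np.asarray(x, dtype=float)
    flags: list[str] = []
    n_win = int(round(window_s * sample_rate))
    if n_win >= len(x):
        flags.append("session_shorter_than_detrend_window")
        return x - np.median(x), flags
    if n_win % 2 == 0:
        n_win += 1
    med = (
        pd.Series(x).rolling(n_win, center=True, min_periods=1).median().to_numpy()
    )
    return x - med, flags


def isosbestic_correct(
    f_ca_detrended: np.ndarray, f_iso_detrended: np.ndarray
) -> tuple[np.ndarray, float, float, list[str]]:
    """Fit the isosbestic trace to the calcium trace (OLS, with intercept)
    and subtract, yielding the motion-corrected ΔF/F.

    Returns (dff, slope, intercept, flags).  A zero-variance isosbestic
    channel degrades gracefully to mean subtraction.
    """
    ca = np.asarray(f_ca_detrended, dtype=float)
    iso = np.asarray(f_iso_detrended, dtype=float)
    if ca.shape != iso.shape:
        raise ValueError("channels must have equal length")
    flags: list[str] = []
    if np.ptp(iso) < 1e-15 or np.std(iso) == 0:
        flags.append("zero_variance_isosbestic")
        return ca - np.mean(ca), 0.0, float(np.mean(ca)), flags
    slope, intercept = np.polyfit(iso, ca, 1)
    dff = ca - (slope * iso + intercept)
    return dff, float(slope), float(intercept), flags


def zscore_session(dff: np.ndarray) -> np.ndarray:
    """Session z-score: subtract the session mean, divide by the session SD."""
    dff = np.asarray(dff, dtype=float)
    sd = np.std(dff)
    if sd == 0:
        raise ValueError("zero-variance trace cannot be z-scored")
    return (dff - np.mean(dff)) / sd


def resample_to_frames(
    zdff: np.ndarray, timestamps: np.ndarray, camera_pulse_times: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Linearly interpolate the trace onto the camera frame times (50 Hz)."""
    t = np.asarray(timestamps, dtype=float)
    pulses = np.asarray(camera_pulse_times, dtype=float)
    flags: list[str] = []
    if pulses.min() < t.min() or pulses.max() > t.max():
        flags.append("camera_pulses_outside_trace_span_clipped")
    return np.interp(pulses, t, np.asarray(zdff, dtype=float)), flags


def process_recording(
    rec: PhotometryRecording, detrend_window_s: float = 600.0
) -> tuple[DffTrace, np.ndarray]:
    """Full chain on a recording; returns the 120-Hz trace object and the
    50-Hz frame-aligned z-scored ΔF/F."""
    fs = rec.sample_rate
    ca_d, fl1 = detrend_running_median(rec.f_ca, fs, detrend_window_s)
    iso_d, fl2 = detrend_running_median(rec.f_iso, fs, detrend_window_s)
    dff, slope, intercept, fl3 = isosbestic_correct(ca_d, iso_d)
    zdff = zscore_session(dff)
    frames, fl4 = resample_to_frames(zdff, rec.timestamps, rec.camera_pulse_times)
    trace = DffTrace(
        timestamps=rec.timestamps,
        dff=dff,
        zdff=zdff,
        iso_slope=slope,
        iso_intercept=intercept,
        detrend_window_s=detrend_window_s,
        flags=fl1 + fl2 + fl3 + fl4,
    )
    return trace, frames


# ---------------------------------------------------------------------------
# luminance axis
# ---------------------------------------------------------------------------


def luminance_change(i: float | np.ndarray, i_background: float = BASELINE_LUMINANCE):
    """Luminance-change axis: base-3 log of the stimulus/background ratio.

    The protocol's five logarithmically spaced levels {1, 3, 9, 27, 81}
    cd/m^2 map to {-2, -1, 0, +1, +2}.
    """
    i = np.asarray(i, dtype=float)
    if np.any(i <= 0):
        raise ValueError("luminance must be positive")
    return np.log(i / i_background) / np.log(3.0)


# ---------------------------------------------------------------------------
# event-locked responses
# ---------------------------------------------------------------------------


def on_off_response(
    zdff: np.ndarray,
    timestamps: np.ndarray,
    stimulus_onset: float,
    stimulus_duration: float,
    margin_s: float = 1.0,
) -> tuple[float, float] | None:
    """ON / OFF responses of one trial.

    ON = mean z-ΔF/F in the second after onset minus the second before;
    OFF is the analogue at stimulus offset.  Trials whose margins are
    truncated are dropped (returns None).
    """
    t = np.asarray(timestamps, dtype=float)
    offset = stimulus_onset + stimulus_duration
    if stimulus_onset - margin_s < t[0] or offset + margin_s > t[-1]:
        return None

    def _mean(a: float, b: float) -> float:
        lo, hi = np.searchsorted(t, [a, b])
        return float(np.mean(zdff[lo:hi]))

    on = _mean(stimulus_onset, stimulus_onset + margin_s) - _mean(
        stimulus_onset - margin_s, stimulus_onset
    )
    off = _mean(offset, offset + margin_s) - _mean(offset - margin_s, offset)
    return on, off


def event_aligned_average(
    zdff_50hz: np.ndarray,
    frame_times: np.ndarray,
    anchors_by_mouse: dict[str, np.ndarray] | np.ndarray,
    window_s: tuple[float, float] = (-2.0, 4.0),
    frame_rate: float = 50.0,
) -> dict:
    """Event-aligned average trace.

    Trials are averaged within each mouse first, then across mice (mean and
    SEM), matching the per-animal aggregation policy.  ``anchors_by_mouse``
    may be a plain array for single-mouse data.  Anchors whose windows are
    truncated are dropped.
    """
    if not isinstance(anchors_by_mouse, dict):
        anchors_by_mouse = {"mouse0": np.asarray(anchors_by_mouse, dtype=float)}
    n_pre = int(round(-window_s[0] * frame_rate))
    n_post = int(round(window_s[1] * frame_rate))
    lags = np.arange(-n_pre, n_post + 1) / frame_rate
    per_mouse = []
    for mouse, anchors in anchors_by_mouse.items():
        snips = []
        for a in np.atleast_1d(anchors):
            i = int(np.searchsorted(frame_times, a - 1e-9))
            if i - n_pre < 0 or i + n_post + 1 > len(zdff_50hz):
                continue
            snips.append(zdff_50hz[i - n_pre : i + n_post + 1])
        if snips:
            per_mouse.append(np.mean(snips, axis=0))
    if not per_mouse:
        raise ValueError("no anchor with a full window")
    stack = np.asarray(per_mouse)
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(stack)) if len(stack) > 1 else np.zeros_like(mean)
    return {"lags_s": lags, "mean": mean, "sem": sem, "n_mice": len(stack), "per_mouse": stack}


# ---------------------------------------------------------------------------
# approach-epoch analyses
# ---------------------------------------------------------------------------


def approach_epochs(
    kin: KinematicSeries, threat_zone_entry_frames: np.ndarray, span_s: float = 30.0
) -> list[tuple[int, int]]:
    """Index windows covering the ``span_s`` seconds before each threat-zone
    entry (shorter spans are used as available)."""
    t = kin.timestamps
    out = []
    for f in threat_zone_entry_frames:
        lo = int(np.searchsorted(t, t[f] - span_s))
        out.append((lo, int(f)))
    return out


def distance_binned_activity(
    zdff_50hz: np.ndarray,
    kin: KinematicSeries,
    epochs: list[tuple[int, int]],
    bin_cm: float = 5.0,
    d_max: float = 70.0,
) -> pd.DataFrame:
    """Mean z-ΔF/F per 5-cm shelter-distance bin over approach epochs.

    One aggregate shelter bin (d < 0) precedes the arena bins.  Epoch means
    are averaged (each epoch weighted equally), matching trial-then-mouse
    aggregation when called per mouse.
    """
    edges = np.arange(0.0, d_max + bin_cm, bin_cm)
    labels = ["shelter"] + [f"{edges[i]:g}-{edges[i+1]:g}" for i in range(len(edges) - 1)]
    centers = np.concatenate([[-2.5], (edges[:-1] + edges[1:]) / 2])
    sums = np.zeros((len(epochs), len(labels)))
    sums[:] = np.nan
    for k, (lo, hi) in enumerate(epochs):
        d = kin.shelter_distance[lo:hi]
        z = zdff_50hz[lo:hi]
        which = np.full(len(d), -1, dtype=int)
        which[d < 0] = 0
        arena = (d >= 0) & (d < d_max)
        which[arena] = 1 + np.minimum((d[arena] / bin_cm).astype(int), len(edges) - 2)
        for b in range(len(labels)):
            sel = which == b
            if sel.any():
                sums[k, b] = float(np.mean(z[sel]))
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(sums, axis=0)
    return pd.DataFrame(
        {"bin": labels, "distance_cm": centers, "mean_zdff": mean, "n_epochs": np.sum(~np.isnan(sums), axis=0)}
    )


def activity_covariate_regression(
    epoch_activity: np.ndarray, covariates: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-covariate OLS of epoch-averaged activity on one covariate.

    Returns slope, R² and p for each covariate (matching single-regressor
    linear-model summaries of epoch activity against distance, running speed
    or head direction).
    """
    y = np.asarray(epoch_activity, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least three epochs")
    rows = []
    for name, x in covariates.items():
        X = sm.add_constant(np.asarray(x, dtype=float))
        if np.linalg.matrix_rank(X) < 2:
            raise ValueError(f"covariate {name!r} is rank deficient")
        res = sm.OLS(y, X).fit()
        rows.append(
            {
                "covariate": name,
                "slope": float(res.params[1]),
                "r_squared": float(res.rsquared),
                "p_value": float(res.pvalues[1]),
            }
        )
    return pd.DataFrame(rows)
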