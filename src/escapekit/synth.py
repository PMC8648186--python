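"""Synthetic-session generators with ground-truth labels.

Every downstream stage of the pipeline is testable against sessions built
here: a bout-structured locomotor session in the escape arena with
logistic contrast-dependent escapes, two-channel photometry with a shared
motion artifact, inhomogeneous-Poisson spike trains with contrast-scaled
loom responses and multiplicative optogenetic suppression, and linear I-V
current tables.  Generators are deterministic given their seed and emit a
label for every generated event.

The locomotion model is deliberately simple — alternating rest/run bouts
with small smooth heading wiggle — chosen as the simplest process that
produces realistic approach and return epochs, not fitted to data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from escapekit.core_io import (
    ArenaGeometry,
    IVRecording,
    KeypointTrack,
    LoomSpec,
    PhotometryRecording,
    SessionEvents,
    SpikeDataset,
    SpikeUnit,
)

FRAME_RATE = 50.0

# keypoint rig: head and nose sit ahead of the body centre along the heading
HEAD_OFFSET_CM = 1.5
NOSE_OFFSET_CM = 4.5
EAR_OFFSET_CM = 1.0


def _unit(heading_deg: np.ndarray) -> np.ndarray:
    rad = np.radians(heading_deg)
    return np.column_stack([np.cos(rad), np.sin(rad)])


def track_from_path(
    t: np.ndarray,
    body_xy: np.ndarray,
    heading_deg: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> KeypointTrack:
    """Five-keypoint track from a body-centre path and heading series."""
    u = _unit(heading_deg)
    v = np.column_stack([-u[:, 1], u[:, 0]])  # left-hand transverse
    kps = {
        "body_center": body_xy,
        "head": body_xy + HEAD_OFFSET_CM * u,
        "nose": body_xy + NOSE_OFFSET_CM * u,
        "ear_left": body_xy + EAR_OFFSET_CM * u + EAR_OFFSET_CM * v,
        "ear_right": body_xy + EAR_OFFSET_CM * u - EAR_OFFSET_CM * v,
    }
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        kps = {k: xy + rng.normal(0, noise_sd, xy.shape) for k, xy in kps.items()}
    conf = {k: np.ones(len(t)) for k in kps}
    return KeypointTrack(t, kps, conf)


class _Walker:
    """Frame-by-frame trajectory builder in arena coordinates."""

    def __init__(
        self,
        geometry: ArenaGeometry,
        x0: float,
        y0: float,
        heading0: float = 0.0,
        fs: float = FRAME_RATE,
    ):
        self.geo = geometry
        self.fs = fs
        self.dt = 1.0 / fs
        self.x = [x0]
        self.y = [y0]
        self.h = [heading0]

    @property
    def t_now(self) -> float:
        return (len(self.x) - 1) * self.dt

    @property
    def pos(self) -> tuple[float, float]:
        return self.x[-1], self.y[-1]

    @property
    def d(self) -> float:
        return self.x[-1] - self.geo.shelter_depth

    def rest(self, duration_s: float) -> None:
        n = max(int(round(duration_s * self.fs)), 0)
        self.x.extend([self.x[-1]] * n)
        self.y.extend([self.y[-1]] * n)
        self.h.extend([self.h[-1]] * n)

    def walk(
        self,
        heading_deg: float,
        speed: float,
        duration_s: float,
        wiggle_amp: float = 0.0,
        wiggle_hz: float = 0.3,
        wiggle_phase: float = 0.0,
    ) -> None:
        """Straight walk along ``heading_deg`` with a small transverse
        sinusoidal wiggle; keypoint heading stays at the nominal direction."""
        n = max(int(round(duration_s * self.fs)), 1)
        rad = np.radians(heading_deg)
        ux, uy = np.cos(rad), np.sin(rad)
        steps = np.arange(1, n + 1) * self.dt
        xs = self.x[-1] + speed * steps * ux
        ys = self.y[-1] + speed * steps * uy
        if wiggle_amp > 0:
            tt = self.t_now + steps
            off = wiggle_amp * (
                np.sin(2 * np.pi * wiggle_hz * tt + wiggle_phase)
                - np.sin(2 * np.pi * wiggle_hz * (tt[0] - self.dt) + wiggle_phase)
            )
            xs = xs - off * uy
            ys = ys + off * ux
        ys = np.clip(ys, 1.5, self.geo.width - 1.5)
        xs = np.clip(xs, 1.0, self.geo.length - 1.0)
        self.x.extend(xs.tolist())
        self.y.extend(ys.tolist())
        self.h.extend([heading_deg] * n)

    def walk_to_x(self, x_target: float, speed: float, **kw) -> None:
        dist = x_target - self.x[-1]
        heading = 0.0 if dist >= 0 else 180.0
        self.walk(heading, speed, abs(dist) / speed, **kw)

    def turn_to(
        self,
        target_heading: float,
        deg_per_s: float = 480.0,
        drift_speed: float = 8.0,
        drift_heading: float = 180.0,
    ) -> float:
        """Rotate the heading at ``deg_per_s`` toward ``target_heading``
        (shortest path) while drifting slowly; returns turn duration."""
        start = self.h[-1]
        delta = (target_heading - start + 180.0) % 360.0 - 180.0
        n = max(int(round(abs(delta) / deg_per_s * self.fs)), 1)
        rad = np.radians(drift_heading)
        for k in range(1, n + 1):
            self.x.append(
                np.clip(self.x[-1] + drift_speed * self.dt * np.cos(rad), 1.0, self.geo.length - 1.0)
            )
            self.y.append(np.clip(self.y[-1] + drift_speed * self.dt * np.sin(rad), 1.5, self.geo.width - 1.5))
            self.h.append(start + delta * k / n)
        return n * self.dt

    def finish(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.arange(len(self.x)) / self.fs
        xy = np.column_stack([np.asarray(self.x), np.asarray(self.y)])
        heading = (np.asarray(self.h) + 180.0) % 360.0 - 180.0
        heading[heading == -180.0] = 180.0
        return t, xy, heading


# ---------------------------------------------------------------------------
# generator parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class BehaviorGenParams:
    """Generative parameters of the behavioral session.

    ``beta0``/``beta1`` parameterize the escape psychometric on contrast in
    percent: p(escape) = logistic(beta0 + beta1 * c_pct); the defaults place
    p(40%) = 0.5 and p(99%) ~ 0.95.  The escape turn is executed well above
    the 100 deg/s detection threshold so generated escapes are detectable.
    """

    beta0: float = -2.0
    beta1: float = 0.05
    contrast_levels: tuple[float, ...] = (0.2, 0.4, 0.6, 0.99)
    trigger_probability: float = 0.35  # looms per eligible threat-zone entry
    min_loom_interval_s: float = 120.0
    spontaneous_escape_rate: float = 0.1  # per unstimulated approach
    freeze_probability: float = 0.1  # per evoked non-escape trial
    bout_speed_cm_s: float = 12.0
    escape_peak_speed_cm_s: float = 55.0
    turn_speed_deg_s: float = 480.0
    session_length_s: float = 1800.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.trigger_probability, self.spontaneous_escape_rate, self.freeze_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.turn_speed_deg_s <= 100:
            raise ValueError("escape turn must exceed the 100 deg/s detection threshold")

    def p_escape(self, contrast: float) -> float:
        eta = self.beta0 + self.beta1 * contrast * 100.0
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class GroundTruth:
    """Labels for every generated behavioral event."""

    trials: pd.DataFrame
    spontaneous: pd.DataFrame
    returns: pd.DataFrame
    n_approaches_unstimulated: int
    escape_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# full behavioral session
# ---------------------------------------------------------------------------


def generate_behavior(
    params: BehaviorGenParams,
    geometry: ArenaGeometry | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[KeypointTrack, SessionEvents, GroundTruth]:
    """Bout-structured session: shelter rests alternate with excursions into
    the threat zone; looms are triggered on a fraction of eligible entries
    (facing the zone, minimum inter-stimulus interval) and the escape
    outcome is a Bernoulli draw from the logistic psychometric."""
    geometry = geometry or ArenaGeometry()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    loom = LoomSpec()
    w = _Walker(geometry, x0=5.0, y0=geometry.width / 2, heading0=0.0)
    trials: list[dict] = []
    spont: list[dict] = []
    returns: list[dict] = []
    n_app_unstim = 0
    last_loom_t = -np.inf
    stim_dur = loom.train_duration

    w.rest(rng.uniform(5, 10))
    while w.t_now < params.session_length_s:
        speed = float(np.clip(rng.normal(params.bout_speed_cm_s, 2.0), 6.0, 20.0))
        phase = rng.uniform(0, 2 * np.pi)
        # orient toward the threat zone, leave the shelter (heading 0)
        w.turn_to(0.0, 300.0, drift_speed=2.0, drift_heading=0.0)
        zone_x = geometry.shelter_depth + geometry.threat_zone[0]
        w.walk_to_x(zone_x + speed * 0.1, speed, wiggle_amp=0.5, wiggle_phase=phase)
        entry_t = w.t_now
        trigger = (
            rng.random() < params.trigger_probability
            and entry_t - last_loom_t >= params.min_loom_interval_s
        )
        if trigger:
            w.walk(0.0, speed, 0.2)  # manual trigger lag
            onset = w.t_now
            last_loom_t = onset
            contrast = float(rng.choice(params.contrast_levels))
            escaped = bool(rng.random() < params.p_escape(contrast))
            row = {
                "stimulus_onset": onset,
                "contrast": contrast,
                "eligible": True,
                "escaped": escaped,
                "froze": False,
                "escape_onset": np.nan,
                "shelter_arrival": np.nan,
                "peak_speed": np.nan,
            }
            if escaped:
                w.walk(0.0, speed, rng.uniform(0.25, 0.45))  # reaction time
                row["escape_onset"] = w.t_now
                w.turn_to(180.0, params.turn_speed_deg_s, drift_speed=8.0)
                run_dist = w.x[-1] - 5.0
                run_t = run_dist / params.escape_peak_speed_cm_s
                arrival = w.t_now + (w.d / run_dist) * run_t
                w.walk(180.0, params.escape_peak_speed_cm_s, run_t)
                row["shelter_arrival"] = arrival
                row["peak_speed"] = params.escape_peak_speed_cm_s
                w.rest(rng.uniform(8, 15))
            else:
                if rng.random() < params.freeze_probability:
                    w.walk(0.0, speed, 0.15)
                    w.rest(2.4)
                    row["froze"] = True
                    w.walk(0.0, 7.0, rng.uniform(0.5, 1.0), wiggle_amp=0.4, wiggle_phase=phase)
                else:
                    # keep ambling through the stimulus, then wander home
                    w.walk(0.0, 7.0, stim_dur + rng.uniform(0.5, 1.5), wiggle_amp=0.4, wiggle_phase=phase)
                w.turn_to(180.0, 300.0, drift_speed=4.0)
                w.walk_to_x(5.0, rng.uniform(8.0, 11.0), wiggle_amp=0.5, wiggle_phase=phase)
                w.rest(rng.uniform(8, 15))
            trials.append(row)
        else:
            n_app_unstim += 1
            d_target = rng.uniform(48.0, 66.0)
            w.walk_to_x(geometry.shelter_depth + d_target, speed, wiggle_amp=0.5, wiggle_phase=phase)
            if rng.random() < params.spontaneous_escape_rate:
                onset_t = w.t_now
                w.turn_to(180.0, params.turn_speed_deg_s, drift_speed=8.0)
                run_dist = w.x[-1] - 5.0
                run_speed = max(params.escape_peak_speed_cm_s, run_dist / 1.2)
                run_t = run_dist / run_speed
                arrival = w.t_now + (w.d / run_dist) * run_t
                w.walk(180.0, run_speed, run_t)
                spont.append({"escape_onset": onset_t, "shelter_arrival": arrival})
            else:
                w.turn_to(180.0, 300.0, drift_speed=4.0)
                ret_speed = rng.uniform(8.0, 11.0)
                arrival = w.t_now + w.d / ret_speed
                w.walk_to_x(5.0, ret_speed, wiggle_amp=0.5, wiggle_phase=phase)
                if arrival - last_loom_t > 10.0 + stim_dur:
                    returns.append({"shelter_arrival": arrival})
            w.rest(rng.uniform(8, 15))

    t, xy, heading = w.finish()
    track = track_from_path(t, xy, heading)
    ev_rows = [
        {"kind": "loom", "onset_s": r["stimulus_onset"], "duration_s": stim_dur, "contrast": r["contrast"]}
        for r in trials
    ]
    events = SessionEvents(pd.DataFrame(ev_rows, columns=["kind", "onset_s", "duration_s", "contrast"]))
    truth = GroundTruth(
        trials=pd.DataFrame(
            trials,
            columns=[
                "stimulus_onset",
                "contrast",
                "eligible",
                "escaped",
                "froze",
                "escape_onset",
                "shelter_arrival",
                "peak_speed",
            ],
        ),
        spontaneous=pd.DataFrame(spont, columns=["escape_onset", "shelter_arrival"]),
        returns=pd.DataFrame(returns, columns=["shelter_arrival"]),
        n_approaches_unstimulated=n_app_unstim,
        escape_onsets=np.array(
            [r["escape_onset"] for r in trials if r["escaped"]] + [s["escape_onset"] for s in spont]
        ),
    )
    return track, events, truth


# ---------------------------------------------------------------------------
# scripted single-trial scenarios (criteria-boundary battery)
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """One scripted mini-session with its ground-truth label."""

    kind: str  # evoked | unstimulated
    label: str  # escape | freeze | no_escape | spontaneous_escape | return
    eligible: bool | None
    track: KeypointTrack
    events: SessionEvents
    geometry: ArenaGeometry


def scripted_evoked_trial(
    d0: float,
    h0: float,
    outcome: str,
    *,
    turn_delay: float = 0.35,
    run_duration: float = 1.5,
    contrast: float = 0.6,
    geometry: ArenaGeometry | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Scenario:
    """A single stimulus trial: the mouse ambles along heading ``h0``, is at
    shelter distance ``d0`` at stimulus onset (t = 2 s), and then either
    escapes (turn + straight run crossing into the shelter ``run_duration``
    seconds after the turn ends), keeps ambling, or freezes."""
    geometry = geometry or ArenaGeometry()
    loom = LoomSpec()
    stim_dur = loom.train_duration
    onset = 2.0
    v_pre = 6.0
    # back-cast the start position so the mouse is at d0 exactly at onset
    rad = np.radians(h0)
    x_on = geometry.shelter_depth + d0
    y_on = geometry.width / 2
    w = _Walker(geometry, x_on - v_pre * onset * np.cos(rad), y_on - v_pre * onset * np.sin(rad), h0)
    w.walk(h0, v_pre, onset)

    eligible = bool(d0 >= 10.0 and abs(h0) < 60.0)
    label = "no_escape"
    if outcome == "escape":
        w.walk(h0, v_pre, turn_delay)
        escape_onset = w.t_now
        w.turn_to(180.0, 480.0, drift_speed=8.0)
        d_run = w.d
        run_speed = d_run / run_duration
        arrival = w.t_now + run_duration
        w.walk(180.0, run_speed, run_duration + min(4.0, w.x[-1] - 4.0) / run_speed)
        w.rest(max(0.0, onset + 6.5 - w.t_now))
        escaped = eligible and (arrival - onset < 5.0) and (arrival - escape_onset < 2.5)
        label = "escape" if escaped else "no_escape"
    elif outcome == "freeze":
        w.walk(h0, v_pre, 0.1)
        w.rest(2.4)
        w.walk(h0, v_pre, onset + 6.5 - w.t_now)
        label = "freeze"
    elif outcome == "amble":
        w.walk(h0, v_pre, onset + 6.5 - w.t_now)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")

    t, xy, heading = w.finish()
    track = track_from_path(t, xy, heading, noise_sd=noise_sd, rng=rng)
    events = SessionEvents(
        pd.DataFrame(
            [{"kind": "loom", "onset_s": onset, "duration_s": stim_dur, "contrast": contrast}]
        )
    )
    return Scenario("evoked", label, eligible, track, events, geometry)


def scripted_unstimulated_trial(
    kind: str,
    *,
    d_peak: float = 50.0,
    run_duration: float = 1.2,
    return_speed: float = 10.0,
    geometry: ArenaGeometry | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Scenario:
    """An unstimulated approach into the threat zone followed by either a
    fast spontaneous escape or a slow non-escape return."""
    geometry = geometry or ArenaGeometry()
    w = _Walker(geometry, geometry.shelter_depth + 25.0, geometry.width / 2, 0.0)
    w.rest(0.5)
    w.walk_to_x(geometry.shelter_depth + d_peak, 15.0)
    w.turn_to(180.0, 480.0, drift_speed=8.0)
    if kind == "spontaneous_escape":
        d_run = w.d
        run_speed = d_run / run_duration
        w.walk(180.0, run_speed, run_duration + 4.0 / run_speed)
    elif kind == "return":
        w.walk_to_x(geometry.shelter_depth - 4.0, return_speed)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    w.rest(1.5)
    t, xy, heading = w.finish()
    track = track_from_path(t, xy, heading, noise_sd=noise_sd, rng=rng)
    events = SessionEvents(pd.DataFrame(columns=["kind", "onset_s", "duration_s"]))
    return Scenario("unstimulated", kind, None, track, events, geometry)


def generate_trial_battery(
    n_trials: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
    geometry: ArenaGeometry | None = None,
) -> list[Scenario]:
    """Scripted trials spanning the criteria boundaries: start distances
    5-70 cm, headings 0-180 deg, shelter arrivals 2-6 s post-onset, plus
    freezing trials, spontaneous escapes and slow returns.

    Grid values keep a margin from the decision thresholds themselves (10 cm,
    60 deg, 2.5 s, 5 s) so that with moderate keypoint noise (0.3 cm) labels
    remain well defined.
    """
    geometry = geometry or ArenaGeometry()
    rng = np.random.default_rng(seed)
    specs: list[tuple] = []
    distances = [10.8, 14.0, 18.0, 24.0, 30.0, 36.0, 42.0, 48.0, 54.0, 60.0, 66.0, 69.0]
    amble_distances = [10.8, 14.0, 18.0, 24.0, 30.0, 36.0, 42.0, 48.0]
    headings = [0.0, 12.0, -18.0, 25.0, -32.0, 40.0, -47.0]
    run_durations = [1.0, 1.3, 1.6, 1.8, 2.0]
    turn_delays = [0.5, 0.9, 1.3, 1.7, 2.1]
    i = 0
    while len(specs) < int(0.45 * n_trials):
        d0 = distances[i % len(distances)]
        h0 = headings[(i // len(distances)) % len(headings)]
        rd = run_durations[i % len(run_durations)]
        td = turn_delays[(i + 1) % len(turn_delays)]
        specs.append(("evoked", dict(d0=d0, h0=h0, outcome="escape", run_duration=rd, turn_delay=td)))
        i += 1
    # late arrivals / long runs: shelter reached but outside the time rules
    i = 0
    while len(specs) < int(0.55 * n_trials):
        d0 = distances[(2 * i) % len(distances)]
        specs.append(
            ("evoked", dict(d0=d0, h0=headings[i % len(headings)], outcome="escape", run_duration=2.8 + 0.3 * (i % 4), turn_delay=2.0 + 0.25 * (i % 3)))
        )
        i += 1
    # ineligible: too close to the shelter
    for k, d0 in enumerate([5.0, 6.5, 8.0, 9.2]):
        for h0 in (0.0, 20.0, -35.0):
            specs.append(("evoked", dict(d0=d0, h0=h0, outcome="escape", run_duration=1.0, turn_delay=0.5)))
    # ineligible: facing away from the threat zone
    for h0 in (75.0, -80.0, 95.0, -110.0, 130.0, -150.0, 165.0, 180.0):
        specs.append(("evoked", dict(d0=30.0, h0=h0, outcome="amble")))
        specs.append(("evoked", dict(d0=18.0, h0=h0, outcome="escape", run_duration=1.2, turn_delay=0.5)))
    # plain non-escape ambles and freezes
    i = 0
    while len(specs) < int(0.80 * n_trials):
        if i % 3 == 2:
            specs.append(("evoked", dict(d0=distances[i % len(distances)], h0=headings[i % len(headings)], outcome="freeze")))
        else:
            specs.append(("evoked", dict(d0=amble_distances[(3 * i) % len(amble_distances)], h0=headings[(i + 2) % len(headings)], outcome="amble")))
        i += 1
    # unstimulated approaches
    i = 0
    while len(specs) < n_trials:
        if i % 2 == 0:
            specs.append(("unstim", dict(kind="spontaneous_escape", d_peak=44.0 + 4 * (i % 6), run_duration=0.9 + 0.25 * (i % 5))))
        else:
            specs.append(("unstim", dict(kind="return", d_peak=44.0 + 4 * (i % 6), return_speed=8.0 + (i % 4))))
        i += 1
    specs = specs[:n_trials]
    rng.shuffle(specs)
    out = []
    for sk, kw in specs:
        if sk == "evoked":
            out.append(scripted_evoked_trial(geometry=geometry, noise_sd=noise_sd, rng=rng, **kw))
        else:
            out.append(scripted_unstimulated_trial(geometry=geometry, noise_sd=noise_sd, rng=rng, **kw))
    return out


# ---------------------------------------------------------------------------
# psychometric trial outcomes
# ---------------------------------------------------------------------------


def simulate_escape_outcomes(
    beta0: float,
    beta1: float,
    contrasts_pct: tuple[float, ...],
    n_mice: int,
    n_trials_per_mouse: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Trial-level escape outcomes from the generative logistic
    p(escape) = logistic(beta0 + beta1 * contrast_pct), trials spread evenly
    over the contrast levels within each mouse."""
    rows = []
    for m in range(n_mice):
        cs = np.resize(np.asarray(contrasts_pct, dtype=float), n_trials_per_mouse)
        p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * cs)))
        esc = rng.random(n_trials_per_mouse) < p
        for c, e in zip(cs, esc):
            rows.append({"mouse_id": f"m{m}", "contrast_pct": c, "escaped": bool(e), "eligible": True, "usable": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------


@dataclass
class PhotometryGenParams:
    """Generative structure of the two-channel recording.

    f_ca  = bleach(t) * (baseline + clean + gain_ca  * artifact) + noise
    f_iso = bleach(t) * (baseline +         gain_iso * artifact) + noise

    with clean = transient kernel (x) state drivers.  The shared artifact
    emulates patch-cord motion; the isosbestic channel sees it but not the
    calcium signal.
    """

    sample_rate: float = 120.0
    bleach_tau_s: float = 2000.0
    baseline: float = 10.0
    artifact_amp: float = 1.0
    gain_ca: float = 1.0
    gain_iso: float = 1.0
    kernel_rise_s: float = 0.1
    kernel_decay_s: float = 1.0
    shelter_gain: float = 2.0
    distance_slope: float = -0.02  # per cm of shelter distance
    escape_gain: float = 3.0
    luminance_on_gain: float = 1.0
    luminance_off_gain: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.kernel_decay_s > self.kernel_rise_s > 0:
            raise ValueError("need decay > rise > 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


def _calcium_kernel(params: PhotometryGenParams, fs: float) -> np.ndarray:
    t = np.arange(0, 6 * params.kernel_decay_s, 1.0 / fs)
    k = np.exp(-t / params.kernel_decay_s) - np.exp(-t / params.kernel_rise_s)
    return k


def generate_photometry(
    track: KeypointTrack,
    events: SessionEvents,
    params: PhotometryGenParams,
    geometry: ArenaGeometry | None = None,
    escape_onsets: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PhotometryRecording, np.ndarray]:
    """Two-channel recording over the track's span, plus the noise-free
    calcium signal (the generator's ground truth) on the photometry grid."""
    geometry = geometry or ArenaGeometry()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    fs = params.sample_rate
    t = np.arange(track.timestamps[0], track.timestamps[-1], 1.0 / fs)
    d = np.interp(t, track.timestamps, track.keypoints["body_center"][:, 0]) - geometry.shelter_depth

    kernel = _calcium_kernel(params, fs)
    k_area = kernel.sum()
    k_peak = kernel.max()

    state = params.shelter_gain * (d < 0) + params.distance_slope * np.clip(d, 0, None)
    impulses = np.zeros_like(t)
    if escape_onsets is not None:
        for e in np.atleast_1d(escape_onsets):
            i = int(np.searchsorted(t, e))
            if 0 <= i < len(t):
                impulses[i] += params.escape_gain
    for _, ev in events.of_kind("luminance_step").iterrows():
        change = np.log(ev["luminance_cd_m2"] / 9.0) / np.log(3.0)
        i_on = int(np.searchsorted(t, ev["onset_s"]))
        i_off = int(np.searchsorted(t, ev["onset_s"] + ev["duration_s"]))
        if i_on < len(t):
            impulses[i_on] += params.luminance_on_gain * change
        if i_off < len(t):
            impulses[i_off] += -params.luminance_off_gain * change

    clean = (
        np.convolve(state, kernel / k_area)[: len(t)]
        + np.convolve(impulses, kernel / k_peak)[: len(t)]
    )
    artifact = gaussian_filter1d(rng.standard_normal(len(t)), sigma=0.25 * fs)
    sd = artifact.std()
    artifact = params.artifact_amp * (artifact / sd if sd > 0 else artifact)
    bleach = np.exp(-t / params.bleach_tau_s)
    f_ca = bleach * (params.baseline + clean + params.gain_ca * artifact) + rng.normal(
        0, params.noise_sd, len(t)
    )
    f_iso = bleach * (params.baseline + params.gain_iso * artifact) + rng.normal(
        0, params.noise_sd, len(t)
    )
    rec = PhotometryRecording(t, f_ca, f_iso, camera_pulse_times=track.timestamps)
    return rec, clean


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

UNIT_CLASSES = ("visual_only", "sound_only", "visual_sound", "unresponsive")


@dataclass
class UnitGenSpec:
    baseline_hz: float
    unit_class: str = "visual_only"
    loom_gain_hz: float = 30.0  # evoked rate at contrast 1.0
    sound_gain_hz: float = 15.0
    suppression: float = 0.3  # multiplicative (1 - s) during laser, visual classes
    depth_um: float = 800.0
    quality: str = "single"

    def __post_init__(self) -> None:
        if self.baseline_hz < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.suppression <= 1:
            raise ValueError("suppression must be in [0, 1]")

    @property
    def visual(self) -> bool:
        return self.unit_class in ("visual_only", "visual_sound")

    @property
    def sound(self) -> bool:
        return self.unit_class in ("sound_only", "visual_sound")


@dataclass
class EphysGenParams:
    units: list[UnitGenSpec]
    loom_response_window_s: float = 3.0
    sound_duration_s: float = 3.0
    laser_lead_s: float = 0.25
    laser_duration_s: float = 4.0
    seed: int = 0


def headfixed_protocol(
    n_blocks: int = 25,
    contrasts: tuple[float, ...] = (0.2, 0.4, 0.6, 0.99),
    isi_s: float = 30.0,
    n_sound: int = 20,
    n_blank_laser: int = 20,
    rng: np.random.Generator | None = None,
    t_start: float = 20.0,
) -> pd.DataFrame:
    """Head-fixed stimulus schedule: blocks of 8 looms (four contrasts, with
    and without laser, shuffled within block), then sound trials and blank
    laser trials.  Returns a trial table with onset_s, kind, contrast, laser."""
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    t = t_start
    for _ in range(n_blocks):
        condition = [(c, las) for c in contrasts for las in (False, True)]
        rng.shuffle(condition)
        for c, las in condition:
            rows.append({"onset_s": t, "kind": "loom", "contrast": c, "laser": las})
            t += isi_s
    for _ in range(n_sound):
        rows.append({"onset_s": t, "kind": "sound", "contrast": np.nan, "laser": False})
        t += 8.0
    for _ in range(n_blank_laser):
        rows.append({"onset_s": t, "kind": "laser_blank", "contrast": np.nan, "laser": True})
        t += 8.0
    return pd.DataFrame(rows)


def _piecewise_rate(spec: UnitGenSpec, trials: pd.DataFrame, params: EphysGenParams, t_stop: float):
    """Breakpoints and per-segment rates for one unit."""
    cuts = {0.0, t_stop}
    looms = trials[trials["kind"] == "loom"]
    sounds = trials[trials["kind"] == "sound"]
    blanks = trials[trials["kind"] == "laser_blank"]
    for o in looms["onset_s"]:
        cuts.update((o, o + params.loom_response_window_s))
    for o in looms.loc[looms["laser"], "onset_s"]:
        cuts.update((o - params.laser_lead_s, o - params.laser_lead_s + params.laser_duration_s))
    for o in sounds["onset_s"]:
        cuts.update((o, o + params.sound_duration_s))
    for o in blanks["onset_s"]:
        cuts.update((o, o + params.laser_duration_s))
    edges = np.array(sorted(c for c in cuts if 0.0 <= c <= t_stop))
    mids = (edges[:-1] + edges[1:]) / 2
    rate = np.full(len(mids), spec.baseline_hz)
    if spec.visual:
        for _, tr in looms.iterrows():
            sel = (mids > tr["onset_s"]) & (mids < tr["onset_s"] + params.loom_response_window_s)
            rate[sel] += spec.loom_gain_hz * tr["contrast"]
    if spec.sound:
        for o in sounds["onset_s"]:
            sel = (mids > o) & (mids < o + params.sound_duration_s)
            rate[sel] += spec.sound_gain_hz
    if spec.visual and spec.suppression > 0:
        laser_windows = [
            (o - params.laser_lead_s, o - params.laser_lead_s + params.laser_duration_s)
            for o in looms.loc[looms["laser"], "onset_s"]
        ] + [(o, o + params.laser_duration_s) for o in blanks["onset_s"]]
        for a, b in laser_windows:
            sel = (mids > a) & (mids < b)
            rate[sel] *= 1.0 - spec.suppression
    return edges, rate


def generate_spikes(
    trials: pd.DataFrame,
    params: EphysGenParams,
    t_stop: float | None = None,
    rng: np.random.Generator | None = None,
    recording_id: str = "rec0",
    mouse_id: str = "mouse0",
) -> SpikeDataset:
    """Inhomogeneous-Poisson spike trains per unit: contrast-scaled loom
    responses for visual classes, sound responses for auditory classes, and
    a multiplicative rate reduction (1 - s) of visual-class units while the
    laser is on."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if t_stop is None:
        t_stop = float(trials["onset_s"].max()) + 10.0
    units = []
    for uid, spec in enumerate(params.units):
        edges, rate = _piecewise_rate(spec, trials, params, t_stop)
        spikes = []
        for a, b, r in zip(edges[:-1], edges[1:], rate):
            if r <= 0:
                continue
            n = rng.poisson(r * (b - a))
            if n:
                spikes.append(rng.uniform(a, b, n))
        st = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        units.append(SpikeUnit(uid, st, depth_um=spec.depth_um, quality=spec.quality))
    return SpikeDataset(units, recording_id=recording_id, mouse_id=mouse_id)


def make_population(
    n_units: int,
    rng: np.random.Generator,
    class_mix: dict[str, float] | None = None,
    baseline_range: tuple[float, float] = (6.0, 20.0),
    suppression: float = 0.3,
    depth_range: tuple[float, float] = (500.0, 1600.0),
) -> list[UnitGenSpec]:
    """Random unit population with the given class mixture."""
    class_mix = class_mix or {"visual_only": 0.45, "sound_only": 0.2, "visual_sound": 0.15, "unresponsive": 0.2}
    classes = list(class_mix)
    probs = np.array([class_mix[c] for c in classes])
    probs = probs / probs.sum()
    specs = []
    for _ in range(n_units):
        cls = rng.choice(classes, p=probs)
        specs.append(
            UnitGenSpec(
                baseline_hz=float(rng.uniform(*baseline_range)),
                unit_class=str(cls),
                loom_gain_hz=float(rng.uniform(25.0, 45.0)),
                sound_gain_hz=float(rng.uniform(10.0, 25.0)),
                suppression=suppression,
                depth_um=float(rng.uniform(*depth_range)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# slice I-V
# ---------------------------------------------------------------------------


def generate_iv(
    g_true_ns: float,
    e_rev_true_mv: float,
    potentials_mv: np.ndarray,
    noise_sd_pa: float,
    rng: np.random.Generator,
    cell_id: str = "cell0",
    layer: str | None = "intermediate",
    mouse_id: str = "mouse0",
) -> IVRecording:
    """Linear synaptic I-V: I = g (V - E_rev) + noise (pA, with g in nS and
    V in mV)."""
    v = np.asarray(potentials_mv, dtype=float)
    i = g_true_ns * (v - e_rev_true_mv) + rng.normal(0, noise_sd_pa, len(v))
    return IVRecording(cell_id, v, i, layer=layer, mouse_id=mouse_id)


def generate_slice_population(
    p_connect: float,
    n_mice: int,
    cells_per_mouse: int,
    rng: np.random.Generator,
    g_mean_ns: float = 3.0,
    g_layer_slope_ns: float = 0.0,
    g_sd_ns: float = 1.0,
) -> pd.DataFrame:
    """Cell table for connectivity / conductance summaries: Bernoulli
    connectivity, conductances lognormal-ish around a layer-dependent mean."""
    layers = ("superficial", "intermediate", "deep")
    rows = []
    for m in range(n_mice):
        for c in range(cells_per_mouse):
            layer = layers[rng.integers(0, 3)]
            connected = bool(rng.random() < p_connect)
            g = max(rng.normal(g_mean_ns + g_layer_slope_ns * layers.index(layer), g_sd_ns), 0.05)
            rows.append(
                {
                    "mouse_id": f"m{m}",
                    "cell_id": f"m{m}c{c}",
                    "layer": layer,
                    "connected": connected,
                    "g_ns": g if connected else np.nan,
                }
            )
    return pd.DataFrame(rows)
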