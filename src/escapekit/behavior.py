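"""Behavioral event classification and escape psychometrics.

All classifiers are deterministic functions of a :class:`KinematicSeries`
plus the session event log, implementing the operational definitions used to
score shelter-directed escape:

- *successful escape*: shelter reached within 5 s of stimulus onset;
- *eligibility*: at onset the mouse is >= 10 cm from the shelter and facing
  the threat zone (|head direction| < 60 deg);
- *escape onset*: the last sample before the body rotation (angular velocity
  > 100 deg/s) that leads to shelter arrival, with arrival < 2.5 s later;
- *spontaneous escape*: the same fast-return criteria without any stimulus;
- *non-escape return*: shelter return with peak speed <= 40 cm/s in the last
  2 s and no stimulus;
- *freezing*: complete absence of motion for >= 2 s during the stimulus;
- *fast rotations*: >= 250 deg/s sustained >= 100 ms; *running bouts*: peak
  speed >= 35 cm/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from escapekit.core_io import ArenaGeometry, SessionEvents
from escapekit.kinematics import KinematicSeries, circular_diff_deg

# operational thresholds of the escape assay
ESCAPE_WINDOW_S = 5.0
RUN_WINDOW_S = 2.5
MIN_START_DISTANCE_CM = 10.0
MAX_START_HEADING_DEG = 60.0
TURN_THRESHOLD_DEG_S = 100.0
RETURN_SPEED_CEILING_CM_S = 40.0
RETURN_SPEED_WINDOW_S = 2.0
FREEZE_MIN_DURATION_S = 2.0
FREEZE_SPEED_FLOOR_CM_S = 1.0  # "absence of motion" floor; configurable
PEAK_SPEED_WINDOW_S = 3.75
ROTATION_THRESHOLD_DEG_S = 250.0
ROTATION_MIN_DURATION_S = 0.1
RUN_PEAK_SPEED_CM_S = 35.0
REST_SPEED_CM_S = 2.0  # below this the mouse counts as stopped
MAX_STOP_S = 0.5  # a stop longer than this breaks the turn->arrival linkage


@dataclass
class EscapeTrial:
    """Outcome of one stimulus presentation."""

    stimulus_onset: float
    kind: str = "loom"
    contrast: float = np.nan  # fraction for looms
    spl_db: float = np.nan
    eligible: bool = False
    escaped: bool = False
    escape_onset: float = np.nan
    shelter_arrival: float = np.nan
    peak_speed: float = np.nan
    froze: bool = False
    laser: bool = False
    laser_timing_class: str = "n/a"
    usable: bool = True
    mouse_id: str = "mouse0"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# primitive episode machinery
# ---------------------------------------------------------------------------


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges [s, e) of consecutive True samples."""
    if not mask.any():
        return []
    m = np.asarray(mask, dtype=bool)
    edges = np.diff(m.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(len(m))
    return list(zip(starts, ends))


def _crossings_with_hysteresis(
    d: np.ndarray, threshold: float, direction: str, hysteresis: float = 1.0
) -> np.ndarray:
    """Threshold crossings debounced by ``hysteresis`` cm: a new crossing is
    only counted after the signal has retreated past threshold -/+ hysteresis,
    so tracking noise at the boundary does not create double events."""
    idx = []
    armed = True
    for i, val in enumerate(d):
        if direction == "up":
            if armed and val >= threshold:
                if i > 0:
                    idx.append(i)
                armed = False
            elif not armed and val < threshold - hysteresis:
                armed = True
        else:
            if armed and val < threshold:
                if i > 0:
                    idx.append(i)
                armed = False
            elif not armed and val >= threshold + hysteresis:
                armed = True
    return np.asarray(idx, dtype=int)


def shelter_entries(kin: KinematicSeries) -> np.ndarray:
    """Frame indices where the body centre crosses into the shelter (d < 0),
    debounced with 1-cm hysteresis."""
    return _crossings_with_hysteresis(kin.shelter_distance, 0.0, "down")


def threat_zone_entries(kin: KinematicSeries, geometry: ArenaGeometry) -> np.ndarray:
    """Frame indices of threat-zone entries from the shelter direction,
    debounced with 1-cm hysteresis."""
    return _crossings_with_hysteresis(kin.shelter_distance, geometry.threat_zone[0], "up")


def _first_shelter_arrival(kin: KinematicSeries, after_idx: int, until_idx: int | None = None) -> int | None:
    d = kin.shelter_distance
    stop = len(d) if until_idx is None else until_idx
    inside = d[after_idx:stop] < 0
    hits = np.where(inside)[0]
    return None if len(hits) == 0 else after_idx + int(hits[0])


def find_escape_onset(
    kin: KinematicSeries,
    search_start_idx: int,
    arrival_idx: int,
    *,
    turn_threshold: float = TURN_THRESHOLD_DEG_S,
    rest_speed: float = REST_SPEED_CM_S,
    max_stop_s: float = MAX_STOP_S,
    min_net_turn_deg: float = 30.0,
) -> int | None:
    """Index of the last sample before the rotation episode leading to arrival.

    Scans rotation episodes (|angular velocity| > ``turn_threshold``) between
    ``search_start_idx`` and the shelter arrival.  An episode is *sustained*
    if its net heading change is at least ``min_net_turn_deg`` (jitter about
    a fixed heading produces brief super-threshold samples with near-zero net
    rotation and is rejected).  The *last* sustained episode whose path to
    arrival contains no stop longer than ``max_stop_s`` (speed <
    ``rest_speed``) is the rotation that launches the escape run: its
    preceding sample is the onset.  Earlier qualifying turns (for instance
    the turn that started the excursion) belong to prior locomotion, not to
    the escape itself.
    """
    av = np.abs(kin.angular_velocity)
    speed = kin.speed
    heading = kin.head_direction
    dt = kin.dt
    turning = av[search_start_idx:arrival_idx] > turn_threshold
    best: int | None = None
    for s, e in _runs_above(turning):
        ep_start = search_start_idx + s
        ep_end = search_start_idx + e
        net = abs(np.sum(circular_diff_deg(heading[max(ep_start - 1, 0) : ep_end + 1])))
        if net < min_net_turn_deg:
            continue
        # linkage: no stop > max_stop_s between the turn and arrival
        seg = speed[ep_start:arrival_idx]
        stopped = seg < rest_speed
        broken = any((e2 - s2) * dt > max_stop_s for s2, e2 in _runs_above(stopped))
        if not broken:
            best = max(ep_start - 1, 0)
    return best


# ---------------------------------------------------------------------------
# evoked escapes
# ---------------------------------------------------------------------------


def classify_evoked_escape(
    kin: KinematicSeries,
    stimulus: pd.Series | dict,
    geometry: ArenaGeometry,
    *,
    mouse_id: str = "mouse0",
    escape_window_s: float = ESCAPE_WINDOW_S,
    run_window_s: float = RUN_WINDOW_S,
) -> EscapeTrial:
    """Score one stimulus presentation as escape / non-escape.

    The trial is *eligible* iff at stimulus onset the mouse is at least 10 cm
    from the shelter and faces the threat zone at < 60 deg.  It *escaped* iff
    the shelter is reached within 5 s of onset and within 2.5 s of the escape
    onset (the last sample before the > 100 deg/s body rotation that leads to
    the arrival without an intervening stop).
    """
    onset = float(stimulus["onset_s"])
    trial = EscapeTrial(
        stimulus_onset=onset,
        kind=str(stimulus.get("kind", "loom")),
        contrast=float(stimulus.get("contrast", np.nan)),
        spl_db=float(stimulus.get("spl_db", np.nan)),
        mouse_id=mouse_id,
    )
    t = kin.timestamps
    onset_idx = int(np.searchsorted(t, onset - 1e-9))
    if onset_idx >= len(t):
        trial.usable = False
        return trial
    win_end_idx = int(np.searchsorted(t, onset + escape_window_s + 1.0))
    if not kin.valid[onset_idx:win_end_idx].all():
        trial.usable = False
        return trial

    d0 = kin.shelter_distance[onset_idx]
    h0 = abs(kin.head_direction[onset_idx])
    trial.eligible = bool(d0 >= MIN_START_DISTANCE_CM and h0 < MAX_START_HEADING_DEG)

    arrival_idx = _first_shelter_arrival(kin, onset_idx, win_end_idx)
    if arrival_idx is not None:
        trial.shelter_arrival = float(t[arrival_idx])
        onset_i = find_escape_onset(kin, onset_idx, arrival_idx)
        if onset_i is not None:
            trial.escape_onset = float(t[onset_i])
        trial.escaped = bool(
            trial.eligible
            and trial.shelter_arrival - onset < escape_window_s
            and onset_i is not None
            and trial.shelter_arrival - trial.escape_onset < run_window_s
        )
    if trial.escaped:
        trial.peak_speed = peak_escape_speed(kin, onset)
    return trial


def peak_escape_speed(
    kin: KinematicSeries, stimulus_onset: float, window_s: float = PEAK_SPEED_WINDOW_S
) -> float:
    """Maximum speed within ``window_s`` of stimulus onset (escape trials)."""
    t = kin.timestamps
    lo = int(np.searchsorted(t, stimulus_onset - 1e-9))
    hi = int(np.searchsorted(t, stimulus_onset + window_s + 1e-9))
    if hi <= lo:
        return float("nan")
    return float(np.max(kin.speed[lo:hi]))


def detect_freezing(
    kin: KinematicSeries,
    stimulus_onset: float,
    stimulus_duration: float,
    *,
    speed_floor: float = FREEZE_SPEED_FLOOR_CM_S,
    min_duration_s: float = FREEZE_MIN_DURATION_S,
    method: str = "displacement",
) -> bool:
    """Freezing: complete absence of motion for >= 2 s during the stimulus.

    ``method='speed'`` applies the literal rule (instantaneous speed below
    the motion floor throughout a 2-s run).  The default
    ``method='displacement'`` tests the equivalent condition on net movement
    — some 2-s window within the stimulus in which the animal never moves
    more than ``speed_floor * min_duration_s`` cm from the window's start —
    which is the same criterion for any animal that is actually motionless
    but is robust to keypoint noise inflating instantaneous speed.
    """
    t = kin.timestamps
    lo = int(np.searchsorted(t, stimulus_onset - 1e-9))
    hi = int(np.searchsorted(t, stimulus_onset + stimulus_duration + 1e-9))
    dt = kin.dt
    if method == "speed":
        still = kin.speed[lo:hi] < speed_floor
        return any((e - s) * dt >= min_duration_s for s, e in _runs_above(still))
    if method != "displacement":
        raise ValueError("method must be 'speed' or 'displacement'")
    n_win = int(round(min_duration_s / dt))
    pos = kin.position[lo:hi]
    tol = speed_floor * min_duration_s
    for s in range(0, len(pos) - n_win):
        window = pos[s : s + n_win + 1]
        if np.max(np.linalg.norm(window - window[0], axis=1)) < tol:
            return True
    return False


def classify_laser_timing(
    kin: KinematicSeries, stimulus_onset: float, laser_onset: float
) -> str:
    """Classify laser onset relative to escape initiation by cumulative turn.

    Cumulative |heading change| between stimulus and laser onset < 30 deg ->
    ``before_initiation``; > 60 deg -> ``after_initiation``; 30-60 deg ->
    ``unclassified``.  Trials < 10 cm from the shelter at laser onset are
    ``excluded``.
    """
    t = kin.timestamps
    lo = int(np.searchsorted(t, stimulus_onset - 1e-9))
    hi = int(np.searchsorted(t, laser_onset + 1e-9))
    if hi <= lo or hi > len(t):
        return "excluded"
    if kin.shelter_distance[min(hi, len(t) - 1)] < MIN_START_DISTANCE_CM:
        return "excluded"
    turned = float(np.sum(np.abs(circular_diff_deg(kin.head_direction[lo : hi + 1]))))
    if turned < 30.0:
        return "before_initiation"
    if turned > 60.0:
        return "after_initiation"
    return "unclassified"


# ---------------------------------------------------------------------------
# session-wide detectors
# ---------------------------------------------------------------------------


def _stimulus_free(events: SessionEvents, t_start: float, t_end: float) -> bool:
    """True if no loom/sound stimulus overlaps [t_start, t_end]."""
    stim = events.table[events.table["kind"].isin(["loom", "sound"])]
    if stim.empty:
        return True
    onset = stim["onset_s"].to_numpy()
    dur = np.nan_to_num(stim["duration_s"].to_numpy())
    return bool(np.all((onset + dur < t_start) | (onset > t_end)))


def detect_spontaneous_escapes(
    kin: KinematicSeries,
    events: SessionEvents,
    geometry: ArenaGeometry,
    *,
    lookback_s: float = 10.0,
) -> tuple[float, pd.DataFrame, int]:
    """Spontaneous-escape probability per threat-zone approach.

    An approach is a threat-zone entry from the shelter direction; approaches
    that trigger a stimulus are removed from the denominator (evoked and
    spontaneous probabilities are computed on disjoint event sets).  A
    spontaneous escape is a stimulus-free shelter return reaching the shelter
    < 2.5 s after its escape onset, starting >= 10 cm out.

    Returns (probability, escape table, n approaches).
    """
    t = kin.timestamps
    approaches = threat_zone_entries(kin, geometry)
    # approaches followed by a stimulus within the loom-trigger window are evoked
    spontaneous_approaches = [
        a for a in approaches if _stimulus_free(events, t[a] - 1.0, t[a] + 5.0)
    ]
    entries = shelter_entries(kin)
    rows = []
    for e_idx in entries:
        arrival = t[e_idx]
        if not _stimulus_free(events, arrival - lookback_s, arrival):
            continue
        search_start = int(np.searchsorted(t, arrival - lookback_s))
        onset_i = find_escape_onset(kin, search_start, e_idx)
        if onset_i is None:
            continue
        if arrival - t[onset_i] >= RUN_WINDOW_S:
            continue
        if kin.shelter_distance[onset_i] < MIN_START_DISTANCE_CM:
            continue
        rows.append(
            {"escape_onset": t[onset_i], "shelter_arrival": arrival, "frame": int(e_idx)}
        )
    table = pd.DataFrame(rows, columns=["escape_onset", "shelter_arrival", "frame"])
    n_app = len(spontaneous_approaches)
    prob = float(len(table)) / n_app if n_app else float("nan")
    return prob, table, n_app


def detect_non_escape_returns(
    kin: KinematicSeries, events: SessionEvents, *, lookback_s: float = 10.0
) -> pd.DataFrame:
    """Stimulus-free shelter returns that are not spontaneous escapes.

    Peak speed in the 2 s before arrival must not exceed 40 cm/s.
    """
    t = kin.timestamps
    rows = []
    for e_idx in shelter_entries(kin):
        arrival = t[e_idx]
        if not _stimulus_free(events, arrival - lookback_s, arrival):
            continue
        lo = int(np.searchsorted(t, arrival - RETURN_SPEED_WINDOW_S))
        vmax = float(np.max(kin.speed[lo : e_idx + 1])) if e_idx >= lo else 0.0
        if vmax > RETURN_SPEED_CEILING_CM_S:
            continue
        rows.append({"shelter_arrival": arrival, "frame": int(e_idx), "max_speed": vmax})
    return pd.DataFrame(rows, columns=["shelter_arrival", "frame", "max_speed"])


def detect_fast_rotations_and_runs(
    kin: KinematicSeries,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast body rotations (>= 250 deg/s for >= 100 ms) and running bouts
    (episodes with peak speed >= 35 cm/s), each tagged escape / non-escape by
    whether the shelter was reached < 2.5 s after the event onset."""
    t = kin.timestamps
    dt = kin.dt
    d = kin.shelter_distance

    def _reaches_shelter(start_idx: int) -> bool:
        hi = int(np.searchsorted(t, t[start_idx] + RUN_WINDOW_S))
        return bool(np.any(d[start_idx:hi] < 0))

    # a rotation of >= 250 deg/s sustained >= 100 ms is equivalent (for a
    # monotone turn) to a net heading change >= 25 deg over some 100-ms
    # window; the windowed form is insensitive to the smoothing filter's
    # shrinkage of super-threshold runs at episode edges
    k = max(int(round(ROTATION_MIN_DURATION_S / dt)), 1)
    cumturn = np.concatenate([[0.0], np.cumsum(circular_diff_deg(kin.head_direction))])
    net = np.abs(cumturn[k:] - cumturn[:-k])
    qualifies = net >= ROTATION_THRESHOLD_DEG_S * ROTATION_MIN_DURATION_S
    rot_rows = []
    for s, e in _runs_above(qualifies):
        rot_rows.append(
            {
                "onset": t[s],
                "duration": (e - s) * dt + ROTATION_MIN_DURATION_S,
                "escape": _reaches_shelter(s),
            }
        )
    run_rows = []
    for s, e in _runs_above(kin.speed > REST_SPEED_CM_S):
        vmax = float(np.max(kin.speed[s:e]))
        if vmax >= RUN_PEAK_SPEED_CM_S:
            run_rows.append(
                {"onset": t[s], "duration": (e - s) * dt, "max_speed": vmax, "escape": _reaches_shelter(s)}
            )
    rotations = pd.DataFrame(rot_rows, columns=["onset", "duration", "escape"])
    runs = pd.DataFrame(run_rows, columns=["onset", "duration", "max_speed", "escape"])
    return rotations, runs


def shelter_occupancy(kin: KinematicSeries) -> float:
    """Relative time in shelter: sum of in-shelter periods over total time."""
    return float(np.mean(kin.shelter_distance < 0))


def zone_occupancy(kin: KinematicSeries, interval: tuple[float, float]) -> float:
    """Fraction of time the shelter-distance coordinate is within [lo, hi)."""
    d = kin.shelter_distance
    return float(np.mean((d >= interval[0]) & (d < interval[1])))


def displacement_after_loom(
    kin: KinematicSeries, stimulus_onset: float, stimulus_duration: float
) -> float:
    """Path length from 500 ms after stimulus onset to the end of the stimulus
    (non-escape trials)."""
    t = kin.timestamps
    lo = int(np.searchsorted(t, stimulus_onset + 0.5))
    hi = int(np.searchsorted(t, stimulus_onset + stimulus_duration + 1e-9))
    if hi - lo < 2:
        return 0.0
    steps = np.linalg.norm(np.diff(kin.position[lo:hi], axis=0), axis=1)
    return float(np.sum(steps))


# ---------------------------------------------------------------------------
# summaries and psychometrics
# ---------------------------------------------------------------------------


def escape_probability(
    trials: pd.DataFrame, group_keys: list[str] = ("mouse_id", "contrast")
) -> pd.DataFrame:
    """Escape fraction per group: successful escapes / presentations.

    Only eligible, usable trials enter the denominator.  Empty cells are
    absent from the output (missing, not zero).
    """
    ok = trials[(trials["eligible"]) & (trials["usable"])]
    if ok.empty:
        return pd.DataFrame(columns=[*group_keys, "escape_probability", "n_trials"])
    grp = ok.groupby(list(group_keys), dropna=False)
    out = grp["escaped"].agg(["mean", "size"]).reset_index()
    return out.rename(columns={"mean": "escape_probability", "size": "n_trials"})


@dataclass
class PsychometricFit:
    """Logistic fit of escape outcome on stimulus contrast (in %)."""

    beta0: float
    beta1: float
    cov: np.ndarray
    n_trials: int
    separation: bool = False
    empirical: pd.DataFrame | None = None

    def predict(self, contrast_pct: np.ndarray) -> np.ndarray:
        eta = self.beta0 + self.beta1 * np.asarray(contrast_pct, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))

    def band(self, contrast_pct: np.ndarray, z: float = 1.96) -> tuple[np.ndarray, np.ndarray]:
        """95% confidence band from the fit's standard errors (delta method
        on the linear predictor)."""
        c = np.asarray(contrast_pct, dtype=float)
        X = np.column_stack([np.ones_like(c), c])
        eta = X @ np.array([self.beta0, self.beta1])
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, self.cov, X))
        lo = 1.0 / (1.0 + np.exp(-(eta - z * se)))
        hi = 1.0 / (1.0 + np.exp(-(eta + z * se)))
        return lo, hi


def fit_psychometric(trials: pd.DataFrame, contrast_col: str = "contrast_pct") -> PsychometricFit:
    """Pooled logistic regression of escape outcome on contrast (%) across mice.

    Complete separation (all-escape / all-fail at every level) is reported as
    a saturated fit with ``separation=True`` and the empirical per-contrast
    fractions attached.
    """
    df = trials.dropna(subset=[contrast_col])
    levels = df.groupby(contrast_col)["escaped"].mean()
    if len(levels) < 2:
        raise ValueError("need at least two contrast levels")
    empirical = levels.reset_index().rename(columns={"escaped": "escape_probability"})
    y = df["escaped"].astype(float).to_numpy()
    X = sm.add_constant(df[contrast_col].astype(float).to_numpy())
    separated = bool(np.all((levels == 0) | (levels == 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            beta0, beta1 = res.params
            cov = np.asarray(res.cov_params())
            if not np.all(np.isfinite(cov)) or np.any(np.abs(res.params) > 50):
                separated = True
        except Exception:
            separated = True
            beta0, beta1, cov = 0.0, 0.0, np.full((2, 2), np.nan)
    return PsychometricFit(
        beta0=float(beta0),
        beta1=float(beta1),
        cov=cov,
        n_trials=len(df),
        separation=separated,
        empirical=empirical,
    )


def fit_psychometric_per_mouse(
    trials: pd.DataFrame, contrast_col: str = "contrast_pct"
) -> dict[str, PsychometricFit]:
    out = {}
    for mouse, sub in trials.groupby("mouse_id"):
        if sub[contrast_col].nunique() >= 2:
            out[str(mouse)] = fit_psychometric(sub, contrast_col)
    return out


# ---------------------------------------------------------------------------
# experience phases
# ---------------------------------------------------------------------------

INTERMEDIATE_CONTRAST = (0.50, 0.60)  # fraction
HABITUATION_SPL_DB = 85.0


def label_experience_phase(
    trials: pd.DataFrame,
    modality: str = "loom",
    habituation_start_s: float | None = None,
) -> tuple[pd.Series, dict[str, float]]:
    """Phase label per trial: naive / experienced / habituating / habituated.

    Naive before the first stimulus; experienced after it; habituating once
    the habituation protocol starts (``habituation_start_s``, or the first
    trial if unknown); habituated from the trial after the first run of three
    consecutive non-escapes at intermediate contrast (50-60%; sounds: 85 dB).
    """
    df = trials.sort_values("stimulus_onset").reset_index()
    if df.empty:
        return pd.Series(dtype=object), {}
    first_stim = float(df["stimulus_onset"].iloc[0])
    if modality == "loom":
        qualifying = df["contrast"].between(*INTERMEDIATE_CONTRAST)
    else:
        qualifying = np.isclose(df["spl_db"], HABITUATION_SPL_DB, atol=2.5)
    habituated_from = np.inf
    run = 0
    for i in range(len(df)):
        if qualifying.iloc[i] and not df["escaped"].iloc[i]:
            run += 1
            if run >= 3:
                habituated_from = float(df["stimulus_onset"].iloc[i])
                break
        else:
            run = 0
    hab_start = habituation_start_s if habituation_start_s is not None else np.inf
    labels = []
    for _, row in df.iterrows():
        t0 = row["stimulus_onset"]
        if t0 > habituated_from:
            labels.append("habituated")
        elif t0 >= hab_start:
            labels.append("habituating")
        elif t0 > first_stim:
            labels.append("experienced")
        else:
            # the first stimulus is presented to a still-naive animal
            labels.append("naive")
    out = pd.Series(labels, index=df["index"], name="phase").sort_index()
    boundaries = {
        "first_stimulus_s": first_stim,
        "habituation_start_s": float(hab_start),
        "habituated_from_s": float(habituated_from),
    }
    return out, boundaries


def scenario_label(
    kin: KinematicSeries, events: SessionEvents, geometry: ArenaGeometry
) -> tuple[str, bool | None, str]:
    """Single comparable label for one mini-session.

    Stimulated sessions are scored as (``evoked``, eligibility, outcome)
    with outcome escape / freeze / no_escape (escape takes precedence);
    stimulus-free sessions as (``unstimulated``, None, spontaneous_escape /
    return / none).  Used to compare classifier output against generator
    ground truth, scenario by scenario.
    """
    stim = events.table[events.table["kind"].isin(["loom", "sound"])]
    if len(stim):
        first = stim.iloc[0]
        trial = classify_evoked_escape(kin, first, geometry)
        if trial.escaped:
            outcome = "escape"
        elif detect_freezing(kin, float(first["onset_s"]), float(first["duration_s"])):
            outcome = "freeze"
        else:
            outcome = "no_escape"
        return ("evoked", trial.eligible, outcome)
    _, spont, _ = detect_spontaneous_escapes(kin, events, geometry)
    if len(spont):
        return ("unstimulated", None, "spontaneous_escape")
    returns = detect_non_escape_returns(kin, events)
    return ("unstimulated", None, "return" if len(returns) else "none")


def phase_at_times(times: np.ndarray, boundaries: dict[str, float]) -> np.ndarray:
    """Phase label per time point from the boundaries of
    :func:`label_experience_phase`."""
    t = np.asarray(times, dtype=float)
    out = np.full(t.shape, "naive", dtype=object)
    out[t >= boundaries["first_stimulus_s"]] = "experienced"
    out[t >= boundaries["habituation_start_s"]] = "habituating"
    out[t > boundaries["habituated_from_s"]] = "habituated"
    return out
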