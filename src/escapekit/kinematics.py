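"""Smoothed kinematic series derived from keypoint tracks.

The behavioral classifiers consume four series computed here: body-center
position, shelter distance, instantaneous speed, head direction (0 deg =
facing the threat zone, +/-180 deg = facing the shelter), and angular
velocity of the head direction.  Position and heading are smoothed with a
100-ms running average *before* differentiation, so derivative estimates do
not amplify tracking noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from escapekit.core_io import ArenaGeometry, KeypointTrack, shelter_distance


@dataclass
class KinematicSeries:
    """Per-frame kinematics on the track's timebase.

    ``valid`` marks frames usable for event classification (False across
    tracking gaps longer than the interpolation limit).
    """

    timestamps: np.ndarray
    position: np.ndarray  # (n, 2) cm, smoothed body centre
    shelter_distance: np.ndarray  # cm
    speed: np.ndarray  # cm/s
    head_direction: np.ndarray  # deg, wrapped to (-180, 180]
    angular_velocity: np.ndarray  # deg/s
    valid: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.timestamps)))


def smooth_running_average(x: np.ndarray, window_s: float, frame_rate: float, *, causal: bool = False) -> np.ndarray:
    """Running-average filter over ``window_s`` seconds.

    Centered by default (symmetric window with shrinkage at the edges, so a
    constant input is reproduced exactly everywhere); set ``causal=True`` for
    a trailing window.  Works along the first axis.
    """
    n_win = int(round(window_s * frame_rate))
    if n_win < 1:
        raise ValueError("window shorter than one sample")
    if n_win == 1:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    csum = np.cumsum(x, axis=0)
    zero = np.zeros((1,) + x.shape[1:])
    csum = np.concatenate([zero, csum], axis=0)
    if causal:
        lo = np.maximum(np.arange(n) - n_win + 1, 0)
        hi = np.arange(n) + 1
    else:
        half_lo = (n_win - 1) // 2
        half_hi = n_win // 2
        lo = np.maximum(np.arange(n) - half_lo, 0)
        hi = np.minimum(np.arange(n) + half_hi + 1, n)
    counts = (hi - lo).reshape((-1,) + (1,) * (x.ndim - 1))
    return (csum[hi] - csum[lo]) / counts


def compute_speed(position: np.ndarray, timestamps: np.ndarray) -> np.ndarray:
    """Instantaneous speed: Euclidean step length over the frame interval.

    The first sample is duplicated so the output matches the input length.
    """
    pos = np.asarray(position, dtype=float)
    dt = np.diff(np.asarray(timestamps, dtype=float))
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    speed = step / dt
    return np.concatenate([speed[:1], speed]) if len(speed) else np.zeros(1)


def wrap_angle_deg(a: np.ndarray | float):
    """Wrap angles to (-180, 180]."""
    wrapped = -(np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0)
    return wrapped


def compute_head_direction(
    track: KeypointTrack, geometry: ArenaGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Head direction from the head->nose vector, in degrees.

    0 deg = facing the threat zone (+shelter-distance axis); +/-180 deg =
    facing the shelter.  Frames where nose and head coincide propagate the
    previous valid angle and are flagged (second return value).
    """
    for kp in ("nose", "head"):
        if kp not in track.keypoints:
            raise KeyError(f"keypoint {kp!r} missing from track")
    vec = track.keypoints["nose"] - track.keypoints["head"]
    norm = np.linalg.norm(vec, axis=1)
    degenerate = norm < 1e-12
    angle = np.degrees(np.arctan2(vec[:, 1], vec[:, 0]))
    angle = wrap_angle_deg(angle)
    if degenerate.any():
        idx = np.where(~degenerate)[0]
        if len(idx) == 0:
            angle[:] = 0.0
        else:
            # propagate previous valid angle (next valid one for a leading run)
            pos = np.searchsorted(idx, np.arange(len(angle)), side="right") - 1
            pos = np.clip(pos, 0, len(idx) - 1)
            angle = angle[idx[pos]]
    return angle, degenerate


def circular_diff_deg(angles: np.ndarray) -> np.ndarray:
    """Minimal signed angular steps between consecutive samples (deg)."""
    return wrap_angle_deg(np.diff(np.asarray(angles, dtype=float)))


def compute_angular_velocity(head_direction: np.ndarray, timestamps: np.ndarray) -> np.ndarray:
    """Discrete circular derivative of the heading, deg/s, length preserved."""
    dt = np.diff(np.asarray(timestamps, dtype=float))
    steps = circular_diff_deg(head_direction)
    av = steps / dt
    return np.concatenate([av[:1], av]) if len(av) else np.zeros(1)


def _interpolate_gaps(
    xy: np.ndarray, good: np.ndarray, timestamps: np.ndarray, max_gap_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate low-confidence runs up to ``max_gap_s``.

    Longer runs are still filled (so arrays stay finite) but returned as
    invalid so event classification can exclude them.
    """
    xy = xy.copy()
    n = len(xy)
    valid = np.ones(n, dtype=bool)
    if good.all():
        return xy, valid
    idx = np.arange(n)
    if not good.any():
        return xy, np.zeros(n, dtype=bool)
    for col in range(xy.shape[1]):
        xy[~good, col] = np.interp(idx[~good], idx[good], xy[good, col])
    # mark long gaps invalid
    bad = ~good
    starts = np.where(bad & ~np.roll(bad, 1))[0]
    if bad[0]:
        starts = np.unique(np.concatenate([[0], starts]))
    for s in starts:
        e = s
        while e < n and bad[e]:
            e += 1
        gap = timestamps[min(e, n - 1)] - timestamps[max(s - 1, 0)]
        if gap > max_gap_s:
            valid[s:e] = False
    return xy, valid


def compute_kinematics(
    track: KeypointTrack,
    geometry: ArenaGeometry,
    *,
    smoothing_window_s: float = 0.1,
    causal_smoothing: bool = False,
    low_confidence: float = 0.9,
    max_gap_s: float = 0.2,
) -> KinematicSeries:
    """Full kinematic chain: gap-fill -> smooth -> differentiate.

    Heading is smoothed on the unwrapped angle and re-wrapped, so the running
    average never averages across the +/-180 branch cut.
    """
    t = track.timestamps
    fr = track.frame_rate
    valid = np.ones(len(t), dtype=bool)

    body = track.keypoints["body_center"]
    good = track.confidence["body_center"] >= low_confidence
    body, v = _interpolate_gaps(body, good, t, max_gap_s)
    valid &= v
    body_s = smooth_running_average(body, smoothing_window_s, fr, causal=causal_smoothing)
    speed = compute_speed(body_s, t)

    if "nose" in track.keypoints and "head" in track.keypoints:
        heading_raw, degenerate = compute_head_direction(
            KeypointTrack(
                t,
                {
                    "nose": track.keypoints["nose"],
                    "head": track.keypoints["head"],
                },
                {
                    "nose": track.confidence["nose"],
                    "head": track.confidence["head"],
                },
            ),
            geometry,
        )
        conf_ok = (track.confidence["nose"] >= low_confidence) & (
            track.confidence["head"] >= low_confidence
        )
        unwrapped = np.degrees(np.unwrap(np.radians(heading_raw)))
        unwrapped, v = _interpolate_gaps(
            unwrapped[:, None], conf_ok & ~degenerate, t, max_gap_s
        )
        valid &= v
        heading_s = wrap_angle_deg(
            smooth_running_average(unwrapped[:, 0], smoothing_window_s, fr, causal=causal_smoothing)
        )
        ang_vel = compute_angular_velocity(heading_s, t)
    else:
        heading_s = np.zeros(len(t))
        ang_vel = np.zeros(len(t))
        valid &= False

    return KinematicSeries(
        timestamps=t,
        position=body_s,
        shelter_distance=shelter_distance(body_s, geometry),
        speed=speed,
        head_direction=heading_s,
        angular_velocity=ang_vel,
        valid=valid,
    )
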