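"""Domain types, coordinate conventions, and on-disk formats.

Coordinate convention
---------------------
All behavioral criteria are expressed in a 1-D *shelter distance* d along the
long axis of the arena: d = 0 at the shelter exit, positive toward the threat
zone, d in [-10, 0] inside the shelter.  2-D coordinates (x, y) are in cm with
the origin at the shelter-end corner of the arena, x along the long axis, so
d = x - shelter_depth.

Formats
-------
- Keypoint tracks: CSV in the DeepLabCut dialect (three header rows
  scorer / bodyparts / coords; x, y, likelihood per bodypart; first column is
  the frame index).
- Events: flat CSV with one row per stimulus / laser / luminance event.
- Photometry: HDF5 (datasets timestamps_s, f_ca, f_iso, camera_pulses_s) or
  an equivalent CSV pair.
- Spikes: .npy pair (spike times, cluster ids) plus a cluster-table CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

KEYPOINT_NAMES = ("body_center", "head", "nose", "ear_left", "ear_right")

#: nominal video frame rate (Hz)
FRAME_RATE = 50.0

EVENT_COLUMNS = [
    "kind",
    "onset_s",
    "duration_s",
    "contrast",
    "spl_db",
    "luminance_cd_m2",
    "laser_power_mw",
]

EVENT_KINDS = ("loom", "sound", "laser", "luminance_step")


@dataclass(frozen=True)
class ArenaGeometry:
    """Escape-arena geometry in cm.

    The default matches an 80 x 26 cm arena with a 10-cm-deep shelter at one
    end and a 30-cm threat zone starting 40 cm from the shelter exit.
    """

    length: float = 80.0
    width: float = 26.0
    shelter_depth: float = 10.0
    threat_zone: tuple[float, float] = (40.0, 70.0)

    def __post_init__(self) -> None:
        lo, hi = self.threat_zone
        if not (0 < self.shelter_depth < self.length):
            raise ValueError("shelter depth must lie inside the arena")
        if lo < 0 or hi > self.length - self.shelter_depth:
            raise ValueError("threat zone must lie inside the arena")
        if hi <= lo:
            raise ValueError("threat zone interval is empty")

    @property
    def shelter_interval(self) -> tuple[float, float]:
        """Shelter occupancy interval on the shelter-distance axis."""
        return (-self.shelter_depth, 0.0)

    @property
    def d_max(self) -> float:
        """Largest attainable shelter distance (far arena wall)."""
        return self.length - self.shelter_depth

    def x_to_shelter_distance(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(x) - self.shelter_depth if np.ndim(x) else x - self.shelter_depth

    def shelter_distance_to_x(self, d: np.ndarray | float):
        return np.asarray(d) + self.shelter_depth if np.ndim(d) else d + self.shelter_depth


@dataclass(frozen=True)
class LoomSpec:
    """Parameters of the expanding dark-spot (looming) stimulus.

    A train is ``repeats`` spots; each expands linearly from ``start_radius``
    to ``end_radius`` at ``expansion_rate``, holds for ``hold``, then an
    inter-spot interval of ``isi`` follows.  Contrast follows a negative
    Weber law against the background luminance.
    """

    expansion_rate: float = 55.0  # deg/s
    start_radius: float = 1.0  # deg
    end_radius: float = 20.8  # deg
    hold: float = 0.25  # s
    isi: float = 0.5  # s
    repeats: int = 3
    background_luminance: float = 9.0  # cd/m^2

    @property
    def expansion_duration(self) -> float:
        return (self.end_radius - self.start_radius) / self.expansion_rate

    @property
    def train_duration(self) -> float:
        """Onset of the first spot to offset of the last hold period."""
        single = self.expansion_duration + self.hold
        return self.repeats * single + (self.repeats - 1) * self.isi

    def spot_luminance(self, contrast: float) -> float:
        """Luminance of a spot with the given (positive) Weber contrast."""
        if not 0 < contrast <= 1:
            raise ValueError("contrast must be in (0, 1]")
        return self.background_luminance * (1.0 - contrast)


def weber_contrast(i: float | np.ndarray, i_background: float = 9.0):
    """Negative Weber contrast c = -(I - I_B)/I_B (darker spot => larger c)."""
    return -(np.asarray(i, dtype=float) - i_background) / i_background


@dataclass
class KeypointTrack:
    """Per-frame keypoint positions in arena cm with tracking confidences.

    ``keypoints[name]`` is an (n, 2) float array; ``confidence[name]`` is an
    (n,) array in [0, 1].  Missing keypoints simply have no entry.
    """

    timestamps: np.ndarray
    keypoints: dict[str, np.ndarray]
    confidence: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        if t.ndim != 1 or (len(t) > 1 and not np.all(np.diff(t) > 0)):
            raise ValueError("timestamps must be 1-D and strictly increasing")
        self.timestamps = t
        n = len(t)
        for name, xy in self.keypoints.items():
            xy = np.asarray(xy, dtype=float)
            if xy.shape != (n, 2):
                raise ValueError(f"keypoint {name!r} must have shape ({n}, 2)")
            self.keypoints[name] = xy
            c = np.asarray(self.confidence.get(name, np.ones(n)), dtype=float)
            if c.shape != (n,) or np.any((c < 0) | (c > 1)):
                raise ValueError(f"confidence for {name!r} must be (n,) in [0, 1]")
            self.confidence[name] = c

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def frame_rate(self) -> float:
        if len(self.timestamps) < 2:
            return FRAME_RATE
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    def missing_keypoints(self) -> list[str]:
        return [k for k in KEYPOINT_NAMES if k not in self.keypoints]


@dataclass
class SessionEvents:
    """Typed stimulus / laser / luminance event log.

    Backed by a DataFrame with columns ``kind, onset_s, duration_s, contrast,
    spl_db, luminance_cd_m2, laser_power_mw`` (NaN where not applicable).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in EVENT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[EVENT_COLUMNS].reset_index(drop=True)
        bad = set(df["kind"]) - set(EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds: {sorted(bad)}")
        if not df["onset_s"].is_monotonic_increasing:
            df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
        contrasts = df.loc[df["kind"] == "loom", "contrast"]
        if ((contrasts <= 0) | (contrasts > 1)).any():
            raise ValueError("loom contrast must be a fraction in (0, 1]")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.table[self.table["kind"] == kind].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "SessionEvents":
        return cls(pd.DataFrame(list(records)))


@dataclass
class PhotometryRecording:
    """Two-channel fiber-photometry recording with camera-sync pulses.

    ``f_ca`` is the calcium-dependent channel, ``f_iso`` the isosbestic
    (calcium-independent) channel, both sampled on ``timestamps`` (nominally
    120 Hz).  ``camera_pulse_times`` are the 50-Hz video frame triggers used
    for alignment.
    """

    timestamps: np.ndarray
    f_ca: np.ndarray
    f_iso: np.ndarray
    camera_pulse_times: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.f_ca = np.asarray(self.f_ca, dtype=float)
        self.f_iso = np.asarray(self.f_iso, dtype=float)
        self.camera_pulse_times = np.asarray(self.camera_pulse_times, dtype=float)
        if not (len(self.timestamps) == len(self.f_ca) == len(self.f_iso)):
            raise ValueError("photometry channels must have equal length")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass
class SpikeUnit:
    """A sorted unit: spike times plus probe-depth and quality metadata."""

    unit_id: int
    spike_times: np.ndarray
    depth_um: float
    quality: str = "single"  # single | multi
    layer: str | None = None

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        if st.ndim != 1 or (len(st) > 1 and np.any(np.diff(st) < 0)):
            raise ValueError("spike times must be 1-D and sorted ascending")
        if self.depth_um < 0:
            raise ValueError("depth must be >= 0")
        if self.quality not in ("single", "multi"):
            raise ValueError("quality must be 'single' or 'multi'")
        self.spike_times = st
        if self.layer is None:
            self.layer = layer_from_depth(self.depth_um)


#: depth boundaries (um from the collicular surface) used to assign layers
#: when no histological assignment is available; configurable per call.
DEFAULT_LAYER_BOUNDARIES = {"superficial": 400.0, "intermediate": 1100.0}


def layer_from_depth(
    depth_um: float, boundaries: dict[str, float] = DEFAULT_LAYER_BOUNDARIES
) -> str:
    if depth_um < boundaries["superficial"]:
        return "superficial"
    if depth_um <= boundaries["intermediate"]:
        return "intermediate"
    return "deep"


@dataclass
class SpikeDataset:
    """All sorted units of one recording."""

    units: list[SpikeUnit]
    recording_id: str = "rec0"
    mouse_id: str = "mouse0"

    def __len__(self) -> int:
        return len(self.units)

    def single_units(self) -> list[SpikeUnit]:
        return [u for u in self.units if u.quality == "single"]


@dataclass
class IVRecording:
    """Peak evoked currents per holding potential for one voltage-clamped cell."""

    cell_id: str
    holding_potentials_mv: np.ndarray
    peak_currents_pa: np.ndarray
    n_trials: np.ndarray | None = None
    layer: str | None = None
    mouse_id: str = "mouse0"

    def __post_init__(self) -> None:
        v = np.asarray(self.holding_potentials_mv, dtype=float)
        i = np.asarray(self.peak_currents_pa, dtype=float)
        if len(v) < 1:
            raise ValueError("need at least one holding potential")
        if v.shape != i.shape:
            raise ValueError("potentials and currents must align")
        if not np.all(np.isfinite(i)):
            raise ValueError("currents must be finite")
        self.holding_potentials_mv = v
        self.peak_currents_pa = i
        if self.n_trials is None:
            self.n_trials = np.ones(len(v), dtype=int)


# ---------------------------------------------------------------------------
# shelter-distance axis
# ---------------------------------------------------------------------------


def shelter_distance(
    track_or_xy: KeypointTrack | np.ndarray,
    geometry: ArenaGeometry,
    keypoint: str = "body_center",
) -> np.ndarray:
    """Signed distance from the shelter exit along the arena's long axis.

    0 at the shelter exit, negative inside the shelter (down to
    -shelter_depth), positive toward the threat zone.  Invariant to the
    transverse (y) coordinate.
    """
    if isinstance(track_or_xy, KeypointTrack):
        if keypoint not in track_or_xy.keypoints:
            raise KeyError(f"keypoint {keypoint!r} missing from track")
        x = track_or_xy.keypoints[keypoint][:, 0]
    else:
        xy = np.asarray(track_or_xy, dtype=float)
        x = xy[..., 0]
    return np.asarray(geometry.x_to_shelter_distance(x))


# ---------------------------------------------------------------------------
# time-base alignment
# ---------------------------------------------------------------------------


def map_times_to_frames(times: np.ndarray, pulse_times: np.ndarray) -> np.ndarray:
    """Map event times to nearest camera-frame indices (ties to the earlier
    frame, so causal analyses never see the future)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    pulses = np.asarray(pulse_times, dtype=float)
    idx = np.searchsorted(pulses, times)
    idx = np.clip(idx, 1, len(pulses) - 1)
    left, right = pulses[idx - 1], pulses[idx]
    # tie (exact midpoint) -> earlier frame
    choose_right = (times - left) > (right - times)
    frames = np.where(choose_right, idx, idx - 1)
    frames[times <= pulses[0]] = 0
    frames[times >= pulses[-1]] = len(pulses) - 1
    return frames


def align_timebases(
    events: SessionEvents, pulse_times: np.ndarray, tolerance_frames: int = 2
) -> SessionEvents:
    """Snap every event onset to the nearest camera frame time.

    Idempotent: onsets already on frame times are unchanged.  Raises if the
    pulse train is too short to cover the events beyond ``tolerance_frames``
    frame periods.
    """
    pulses = np.asarray(pulse_times, dtype=float)
    if len(pulses) < 2:
        raise ValueError("need at least two camera pulses to align")
    dt = float(np.median(np.diff(pulses)))
    onsets = events.table["onset_s"].to_numpy()
    if len(onsets) and (
        onsets.min() < pulses[0] - tolerance_frames * dt
        or onsets.max() > pulses[-1] + tolerance_frames * dt
    ):
        raise ValueError("event onsets fall outside the camera pulse train")
    frames = map_times_to_frames(onsets, pulses)
    aligned = events.table.copy()
    aligned["onset_s"] = pulses[frames]
    aligned["frame"] = frames
    return SessionEvents(aligned)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_keypoint_table(path: str | Path, track: KeypointTrack, scorer: str = "escapekit") -> None:
    """Write a track as a DeepLabCut-dialect CSV (scorer/bodyparts/coords headers)."""
    cols = {}
    for name in track.keypoints:
        xy = track.keypoints[name]
        cols[(scorer, name, "x")] = xy[:, 0]
        cols[(scorer, name, "y")] = xy[:, 1]
        cols[(scorer, name, "likelihood")] = track.confidence[name]
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["scorer", "bodyparts", "coords"])
    df.index.name = None
    df.to_csv(path)


def read_keypoint_table(
    path: str | Path,
    geometry: ArenaGeometry | None = None,
    frame_rate: float = FRAME_RATE,
    px_to_cm: float = 1.0,
    low_confidence: float = 0.9,
) -> tuple[KeypointTrack, dict]:
    """Read a DeepLabCut-dialect tracking CSV.

    Returns the track (coordinates scaled by ``px_to_cm`` into arena cm,
    frame index converted to seconds at ``frame_rate``) and a flags dict with
    ``missing`` keypoints and per-keypoint ``low_confidence`` boolean masks
    (confidence < ``low_confidence``).
    """
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    frames = df.index.to_numpy()
    if not np.all(np.diff(frames) > 0):
        raise ValueError("frame index must be strictly increasing")
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    keypoints: dict[str, np.ndarray] = {}
    confidence: dict[str, np.ndarray] = {}
    for name in bodyparts:
        sub = df.xs(name, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        for coord in ("x", "y", "likelihood"):
            if coord not in sub.columns:
                raise ValueError(f"bodypart {name!r} lacks a {coord!r} column")
        keypoints[name] = np.column_stack(
            [sub["x"].to_numpy(float) * px_to_cm, sub["y"].to_numpy(float) * px_to_cm]
        )
        confidence[name] = sub["likelihood"].to_numpy(float)
    track = KeypointTrack(frames / frame_rate, keypoints, confidence)
    flags = {
        "missing": track.missing_keypoints(),
        "low_confidence": {k: confidence[k] < low_confidence for k in confidence},
    }
    return track, flags


def write_events(path: str | Path, events: SessionEvents) -> None:
    events.table[EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path: str | Path) -> SessionEvents:
    return SessionEvents(pd.read_csv(path))


def write_photometry(path: str | Path, rec: PhotometryRecording) -> None:
    """Write a photometry recording to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("timestamps_s", data=rec.timestamps)
        f.create_dataset("f_ca", data=rec.f_ca)
        f.create_dataset("f_iso", data=rec.f_iso)
        f.create_dataset("camera_pulses_s", data=rec.camera_pulse_times)


def read_photometry(path: str | Path) -> PhotometryRecording:
    with h5py.File(path, "r") as f:
        return PhotometryRecording(
            f["timestamps_s"][:], f["f_ca"][:], f["f_iso"][:], f["camera_pulses_s"][:]
        )


def write_spikes(
    prefix: str | Path, dataset: SpikeDataset
) -> tuple[Path, Path, Path]:
    """Write spikes in the sorted-output dialect: .npy times + ids, cluster CSV."""
    prefix = Path(prefix)
    times = np.concatenate([u.spike_times for u in dataset.units]) if dataset.units else np.empty(0)
    ids = (
        np.concatenate([np.full(len(u.spike_times), u.unit_id) for u in dataset.units])
        if dataset.units
        else np.empty(0, dtype=int)
    )
    order = np.argsort(times, kind="stable")
    times_path = prefix.with_suffix(".times.npy")
    ids_path = prefix.with_suffix(".clusters.npy")
    np.save(times_path, times[order])
    np.save(ids_path, ids[order].astype(int))
    table = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in dataset.units],
            "depth_um": [u.depth_um for u in dataset.units],
            "quality": [u.quality for u in dataset.units],
        }
    )
    table_path = prefix.with_suffix(".cluster_table.csv")
    table.to_csv(table_path, index=False)
    return times_path, ids_path, table_path


def read_spikes(
    times_path: str | Path,
    ids_path: str | Path,
    table_path: str | Path,
    recording_id: str = "rec0",
    mouse_id: str = "mouse0",
) -> SpikeDataset:
    times = np.load(times_path)
    ids = np.load(ids_path)
    table = pd.read_csv(table_path)
    units = []
    for _, row in table.iterrows():
        st = np.sort(times[ids == row["unit_id"]])
        units.append(
            SpikeUnit(int(row["unit_id"]), st, float(row["depth_um"]), str(row["quality"]))
        )
    return SpikeDataset(units, recording_id=recording_id, mouse_id=mouse_id)


def write_iv_table(path: str | Path, recs: Sequence[IVRecording]) -> None:
    rows = []
    for rec in recs:
        for v, i, n in zip(rec.holding_potentials_mv, rec.peak_currents_pa, rec.n_trials):
            rows.append(
                {
                    "cell_id": rec.cell_id,
                    "mouse_id": rec.mouse_id,
                    "layer": rec.layer,
                    "holding_potential_mv": v,
                    "peak_current_pa": i,
                    "n_trials": int(n),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_iv_table(path: str | Path) -> list[IVRecording]:
    df = pd.read_csv(path)
    recs = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        layer = sub["layer"].iloc[0]
        recs.append(
            IVRecording(
                cell_id=str(cell_id),
                holding_potentials_mv=sub["holding_potential_mv"].to_numpy(),
                peak_currents_pa=sub["peak_current_pa"].to_numpy(),
                n_trials=sub["n_trials"].to_numpy(),
                layer=None if pd.isna(layer) else str(layer),
                mouse_id=str(sub["mouse_id"].iloc[0]),
            )
        )
    return recs
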