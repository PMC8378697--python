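"""Session ingest and clock synchronization.

Each sensor stream (eye tracker at 30 Hz, inertial head sensor at 400 Hz,
GPS watch at 1 Hz) records on its own clock. Synchronization events
observed in two streams at the beginning and end of a session give pairs
(t_reference, t_stream) from which an affine clock map
``t_reference = offset + scale * t_stream`` is estimated; every stream is
then offset, scaled, and resampled by linear interpolation onto a common
uniform 30 Hz timeline in the eye tracker's (reference) clock.

Missing samples are never interpolated across gaps longer than ``max_gap``
(default 0.5 s); such runs stay missing and are excluded from downstream
statistics.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from gazekit.camera import CameraModel, CalibrationPointPair

DEFAULT_MAX_GAP_S = 0.5
REFERENCE_RATE_HZ = 30.0

NOMINAL_RATES = {"eye_px": 30.0, "head_deg": 400.0, "gps": 1.0}


@dataclass
class RawStream:
    """One stream in its own clock; values are columns (n_samples, n_cols)."""

    stream_id: str
    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate: float = 0.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.timestamps.size:
            self.values = self.values.T
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError(f"{self.stream_id}: timestamps not strictly increasing")
        if not self.nominal_rate:
            self.nominal_rate = NOMINAL_RATES.get(self.stream_id, 0.0)


@dataclass
class SyncEventPair:
    """One synchronization event seen in the reference and a stream clock."""

    event_label: str
    t_reference: float
    t_stream: float


def estimate_clock_map(pairs: list[SyncEventPair]) -> tuple[float, float]:
    """Affine clock map from sync events: t_reference = offset + scale * t_stream.

    Two pairs are interpolated exactly; more are fit by least squares.
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 sync event pairs to estimate a clock map")
    ts = np.array([p.t_stream for p in pairs], dtype=float)
    tr = np.array([p.t_reference for p in pairs], dtype=float)
    if np.ptp(ts) == 0 or len(np.unique(ts)) < 2:
        raise ValueError("degenerate fit: duplicate t_stream values")
    # closed-form least squares about the centroid: well-conditioned for
    # absolute (e.g. POSIX) clocks and exact for identity/offset-only maps
    ts_c, tr_c = ts - ts.mean(), tr - tr.mean()
    scale = float(np.dot(ts_c, tr_c) / np.dot(ts_c, ts_c))
    offset = float(tr.mean() - scale * ts.mean())
    return offset, scale


def apply_clock_map(t_stream: np.ndarray, clock_map: tuple[float, float]) -> np.ndarray:
    offset, scale = clock_map
    return offset + scale * np.asarray(t_stream, dtype=float)


def resample_to_timeline(
    stream: RawStream,
    clock_map: tuple[float, float],
    timeline: np.ndarray,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> np.ndarray:
    """Linearly resample a stream onto the reference timeline.

    Upsamples the 1 Hz GPS and decimates the 400 Hz head series alike by
    plain linear interpolation. Timeline points outside the stream's mapped
    extent are missing (NaN), as are points falling inside a dropout gap
    longer than ``max_gap_s``.
    """
    t_ref = apply_clock_map(stream.timestamps, clock_map)
    timeline = np.asarray(timeline, dtype=float)
    out = np.full((timeline.size, stream.values.shape[1]), np.nan)
    for col in range(stream.values.shape[1]):
        v = stream.values[:, col]
        ok = ~np.isnan(v)
        if ok.sum() == 0:
            continue
        tv, vv = t_ref[ok], v[ok]
        if timeline[-1] < tv[0] or timeline[0] > tv[-1]:
            raise ValueError(
                f"{stream.stream_id}: no overlap between stream and timeline"
            )
        y = np.interp(timeline, tv, vv, left=np.nan, right=np.nan)
        # blank out points inside dropout gaps: spacing beyond both the
        # absolute threshold and 1.5x the stream's own nominal interval
        gap_thresh = max(max_gap_s, 1.5 * float(np.median(np.diff(tv))))
        gaps = np.flatnonzero(np.diff(tv) > gap_thresh)
        for g in gaps:
            inside = (timeline > tv[g]) & (timeline < tv[g + 1])
            y[inside] = np.nan
        out[:, col] = y
    return out


@dataclass
class AlignedSession:
    """All streams on one uniform 30 Hz reference timeline."""

    timeline: np.ndarray
    eye_px: np.ndarray  # (n, 2) pixel coordinates, NaN = missing
    head_deg: np.ndarray | None  # (n,) degrees, None if stream absent
    gps_latlon: np.ndarray | None  # (n, 2) WGS84 degrees, None if absent
    task_windows: list[tuple[str, float, float]] = field(default_factory=list)
    camera: CameraModel | None = None
    calibration_pairs: list[CalibrationPointPair] = field(default_factory=list)

    @property
    def has_head(self) -> bool:
        return self.head_deg is not None

    @property
    def has_gps(self) -> bool:
        return self.gps_latlon is not None

    def __post_init__(self) -> None:
        n = self.timeline.size
        for name in ("eye_px", "head_deg", "gps_latlon"):
            arr = getattr(self, name)
            if arr is not None and arr.shape[0] != n:
                raise ValueError(f"{name} length differs from timeline")
        t0, t1 = self.timeline[0], self.timeline[-1]
        # tolerate one sample interval of slack at the edges
        tol = float(np.median(np.diff(self.timeline))) if n >= 2 else 1e-6
        for label, a, b in self.task_windows:
            if a >= b:
                raise ValueError(f"task window {label!r} has t_start >= t_end")
            if a < t0 - tol or b > t1 + tol:
                raise ValueError(f"task window {label!r} extends past the timeline")


def _parse_iso(stamp: str) -> float:
    s = stamp.strip().replace("Z", "+00:00")
    dt = datetime.fromisoformat(s)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def read_gpx(path: str | Path) -> RawStream:
    """Read a GPX 1.1 track into a RawStream (timestamps = POSIX seconds)."""
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed GPX file {path}: {exc}") from exc
    times, lats, lons = [], [], []
    for el in root.iter():
        if el.tag.endswith("trkpt"):
            t_el = next((c for c in el if c.tag.endswith("time")), None)
            if t_el is None or t_el.text is None:
                raise ValueError(f"GPX trkpt without <time> in {path}")
            times.append(_parse_iso(t_el.text))
            lats.append(float(el.attrib["lat"]))
            lons.append(float(el.attrib["lon"]))
    if not times:
        raise ValueError(f"no track points found in {path}")
    return RawStream("gps", np.array(times), np.column_stack([lats, lons]))


def read_track_csv(path: str | Path) -> RawStream:
    df = pd.read_csv(path)
    return RawStream("gps", df["t"].to_numpy(), df[["lat", "lon"]].to_numpy())


def _read_sync(path: Path) -> dict[str, list[SyncEventPair]]:
    if not path.exists():
        raise FileNotFoundError(f"missing sync file: {path}")
    raw = json.loads(path.read_text())
    return {
        stream: [
            SyncEventPair(p["label"], p["t_reference"], p["t_stream"])
            for p in pairs
        ]
        for stream, pairs in raw["streams"].items()
    }


def load_session(
    bundle_dir: str | Path,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    rate_hz: float = REFERENCE_RATE_HZ,
) -> AlignedSession:
    """Load a raw session bundle and align all streams at 30 Hz.

    Requires ``eye_px.csv``, ``sync.json``, and ``tasks.json``; the head
    and GPS streams are optional (eye-only sessions carry no head sensor)
    and are marked absent, never zero-filled. ``camera.json`` and
    ``calibration_points.csv`` are attached when present.
    """
    bundle = Path(bundle_dir)
    eye_csv = bundle / "eye_px.csv"
    if not eye_csv.exists():
        raise FileNotFoundError(f"missing eye stream: {eye_csv}")
    eye_df = pd.read_csv(eye_csv)
    eye_stream = RawStream(
        "eye_px", eye_df["t"].to_numpy(), eye_df[["x_px", "y_px"]].to_numpy()
    )

    sync = _read_sync(bundle / "sync.json")
    eye_map = (
        estimate_clock_map(sync["eye"]) if "eye" in sync else (0.0, 1.0)
    )

    t_eye_ref = apply_clock_map(eye_stream.timestamps, eye_map)
    n = int(np.floor((t_eye_ref[-1] - t_eye_ref[0]) * rate_hz + 1e-6)) + 1
    timeline = t_eye_ref[0] + np.arange(n) / rate_hz

    eye_px = resample_to_timeline(eye_stream, eye_map, timeline, max_gap_s)

    head_deg = None
    head_csv = bundle / "head_deg.csv"
    if head_csv.exists():
        head_df = pd.read_csv(head_csv)
        head_stream = RawStream(
            "head_deg", head_df["t"].to_numpy(), head_df["yaw_deg"].to_numpy()
        )
        head_map = estimate_clock_map(sync["head"])
        head_deg = resample_to_timeline(head_stream, head_map, timeline, max_gap_s)[
            :, 0
        ]

    gps_latlon = None
    gpx_path, csv_path = bundle / "track.gpx", bundle / "track.csv"
    if gpx_path.exists() or csv_path.exists():
        gps_stream = read_gpx(gpx_path) if gpx_path.exists() else read_track_csv(
            csv_path
        )
        gps_map = estimate_clock_map(sync["gps"])
        gps_latlon = resample_to_timeline(gps_stream, gps_map, timeline, max_gap_s)

    tasks_path = bundle / "tasks.json"
    if not tasks_path.exists():
        raise FileNotFoundError(f"missing task windows: {tasks_path}")
    task_windows = [
        (d["task"], float(d["t_start"]), float(d["t_end"]))
        for d in json.loads(tasks_path.read_text())
    ]

    camera = None
    if (bundle / "camera.json").exists():
        camera = CameraModel.load(bundle / "camera.json")

    cal_pairs: list[CalibrationPointPair] = []
    cal_csv = bundle / "calibration_points.csv"
    if cal_csv.exists():
        cal_df = pd.read_csv(cal_csv)
        cal_pairs = [
            CalibrationPointPair(
                (r.target_x_px, r.target_y_px), (r.gaze_x_px, r.gaze_y_px)
            )
            for r in cal_df.itertuples()
        ]

    return AlignedSession(
        timeline=timeline,
        eye_px=eye_px,
        head_deg=head_deg,
        gps_latlon=gps_latlon,
        task_windows=task_windows,
        camera=camera,
        calibration_pairs=cal_pairs,
    )
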