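"""Synthetic session generator with known ground truth.

Emulates the study conditions of a two-task outdoor protocol — a *walking*
task along a campus path and a *search-and-retrieval* task in a cluttered
courtyard — so that every downstream stage (ingest, synchronization,
undistortion, gaze composition, peak detection, locomotion) can be tested
without the original participant recordings.

The generative model:

* Gaze-in-body targets are drawn zero-mean Gaussian with SD equal to the
  task's spread target (walking ~19.5 deg, searching ~28.5 deg); shift
  intervals are a refractory dwell plus an exponential tail with overall
  rate ``shift_rate``.
* Each target of eccentricity A is decomposed into a head part
  ``A * head_contribution_fn(A)`` and an eye part ``A - head``; the eye is
  clipped to the oculomotor range (+-55 deg) with the residual reassigned
  to the head.  The eye jumps to its component at shift onset (saccadic)
  while the head approaches its own with first-order lag dynamics
  (default tau = 0.15 s), so gaze settles onto the target as the head
  arrives.
* GPS positions advance along a task-specific waypoint polyline at a
  per-second truncated-Gaussian speed; the searching polyline is a
  circuitous multi-waypoint loop with 2-10 s dwell pauses at waypoints,
  the walking polyline the study's three-leg path (26 m E, 150 m N,
  135 m E).
* Each stream is written in its own clock, ``t_stream = (t_true + offset)
  * (1 + drift)``, with synchronization events at session start and end;
  eye positions are rendered to fisheye pixels through the forward
  distortion model.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Callable

import numpy as np

from gazekit.camera import CameraModel, degrees_to_pixels, distort_points
from gazekit.kinematics import OCULOMOTOR_RANGE_DEG
from gazekit.locomotion import EARTH_RADIUS_M, GpsTrack
from gazekit.series import RotationSeries, make_timeline

#: reference geographic origin for synthetic tracks (Riverside, CA campus)
DEFAULT_ORIGIN_LATLON = (33.9737, -117.3281)

#: GPX timestamps are rendered relative to this epoch
GPX_EPOCH = datetime(2021, 3, 1, 8, 0, 0, tzinfo=timezone.utc)

#: the walking task's three-leg campus path: 26 m E, 150 m N, 135 m E (311 m)
WALKING_WAYPOINTS = ((0.0, 0.0), (26.0, 0.0), (26.0, 150.0), (161.0, 150.0))

#: circuitous courtyard loop for the searching task (~380 m traveled,
#: net displacement ~114 m)
SEARCHING_WAYPOINTS = (
    (0.0, 0.0),
    (40.0, 5.0),
    (5.0, 25.0),
    (45.0, 20.0),
    (10.0, 40.0),
    (50.0, 45.0),
    (20.0, 60.0),
    (60.0, 65.0),
    (30.0, 80.0),
    (70.0, 90.0),
)


def linear_head_contribution(base: float, slope: float) -> Callable[[float], float]:
    """Head-recruitment policy: fraction = clip(base + slope * A, 0, 1).

    Monotone non-decreasing in amplitude, mirroring the laboratory finding
    that the head increasingly contributes to larger gaze shifts.
    """

    def fn(amplitude_deg: float) -> float:
        return float(np.clip(base + slope * amplitude_deg, 0.0, 1.0))

    return fn


@dataclass
class SimulationConfig:
    """All knobs of one synthetic session (one participant, one task)."""

    task_label: str = "walking"
    gaze_spread_target: float = 19.5
    head_contribution_fn: Callable[[float], float] = field(
        default_factory=lambda: linear_head_contribution(0.40, 0.0035)
    )
    shift_rate: float = 0.5
    min_dwell_s: float = 1.0
    session_duration: float = 270.0
    eye_limit: float = OCULOMOTOR_RANGE_DEG
    head_lag_tau: float = 0.15
    mean_speed: float = 1.17
    speed_sd: float = 0.15
    path_waypoints: tuple = WALKING_WAYPOINTS
    dwell_range_s: tuple[float, float] | None = None
    stream_rates: dict = field(
        default_factory=lambda: {"eye": 30.0, "head": 400.0, "gps": 1.0}
    )
    clock_offsets: dict = field(
        default_factory=lambda: {"eye": 0.0, "head": 13.7, "gps": -4.2}
    )
    clock_drifts: dict = field(
        default_factory=lambda: {"eye": 0.0, "head": 2e-5, "gps": 1e-5}
    )
    noise_sd: float = 1.0
    gps_noise_sd_m: float = 0.5
    gps_noise_ar: float = 0.999
    calibration_error_deg: float = 2.73
    origin_latlon: tuple[float, float] = DEFAULT_ORIGIN_LATLON
    rng_seed: int = 0

    def validate(self) -> None:
        if self.task_label not in ("walking", "searching"):
            raise ValueError("task_label must be 'walking' or 'searching'")
        if self.shift_rate * self.session_duration < 10:
            raise ValueError("need shift_rate * session_duration >= 10")
        if self.min_dwell_s >= 1.0 / self.shift_rate:
            raise ValueError("min_dwell_s must be below the mean shift interval")
        if self.mean_speed <= 0:
            raise ValueError("mean_speed must be positive")
        if len(self.path_waypoints) < 2:
            raise ValueError("need at least 2 waypoints")
        wp = np.asarray(self.path_waypoints, dtype=float)
        if (np.hypot(*np.diff(wp, axis=0).T) == 0).any():
            raise ValueError("coincident consecutive waypoints")
        # monotone [0, 1] head-recruitment policy, probed on a grid
        grid = np.linspace(0.0, 180.0, 361)
        vals = np.array([self.head_contribution_fn(a) for a in grid])
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("head_contribution_fn must map into [0, 1]")
        if (np.diff(vals) < -1e-12).any():
            raise ValueError("head_contribution_fn must be non-decreasing")


def walking_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-condition defaults for the walking task: narrow gaze spread,
    brisk steady speed, near-straight path, lower head recruitment."""
    cfg = SimulationConfig(
        task_label="walking",
        gaze_spread_target=19.5,
        head_contribution_fn=linear_head_contribution(0.40, 0.0035),
        session_duration=270.0,
        mean_speed=1.17,
        speed_sd=0.15,
        path_waypoints=WALKING_WAYPOINTS,
        dwell_range_s=None,
        rng_seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def searching_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-condition defaults for the search-and-retrieval task: wide gaze
    spread, slow stop-and-go locomotion on a circuitous loop, higher head
    recruitment at every amplitude."""
    cfg = SimulationConfig(
        task_label="searching",
        gaze_spread_target=28.5,
        head_contribution_fn=linear_head_contribution(0.50, 0.0030),
        session_duration=730.0,
        mean_speed=0.75,
        speed_sd=0.35,
        path_waypoints=SEARCHING_WAYPOINTS,
        dwell_range_s=(2.0, 10.0),
        calibration_error_deg=3.50,
        rng_seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def cohort_configs(
    n_participants: int,
    seed: int = 0,
    spread_scale_sd: float = 0.15,
    recruit_shift_sd: float = 0.05,
    speed_scale_sd: float = 0.08,
) -> list[tuple[str, SimulationConfig, SimulationConfig]]:
    """Paired walking/searching configurations for a synthetic cohort.

    Individual differences are modelled as participant-level random effects
    shared across tasks: a multiplicative gaze-spread factor, an additive
    shift of the head-recruitment baseline, and a multiplicative walking
    speed factor. Without them every simulated participant would be
    exchangeable and random-intercept models would sit on the zero-variance
    boundary, which real cohorts never do.
    """
    rng = np.random.default_rng(seed)

    def _jitter(waypoints: tuple, sd_m: float = 3.0) -> tuple:
        # each participant walks their own line: interior waypoints move,
        # endpoints stay (the route's start and goal are fixed)
        wp = np.asarray(waypoints, dtype=float)
        wp[1:-1] += rng.normal(0.0, sd_m, size=wp[1:-1].shape)
        return tuple(map(tuple, wp))

    out = []
    for p in range(n_participants):
        pid = f"p{p:02d}"
        spread_f = max(0.5, rng.normal(1.0, spread_scale_sd))
        recruit = float(np.clip(rng.normal(0.0, recruit_shift_sd), -0.2, 0.2))
        speed_f = max(0.5, rng.normal(1.0, speed_scale_sd))
        cal_err = float(rng.uniform(1.7, 4.6))
        walk = walking_config(
            seed=int(rng.integers(0, 2**31 - 1)),
            gaze_spread_target=19.5 * spread_f,
            head_contribution_fn=linear_head_contribution(0.40 + recruit, 0.0035),
            mean_speed=1.17 * speed_f,
            path_waypoints=_jitter(WALKING_WAYPOINTS),
            calibration_error_deg=cal_err,
        )
        search = searching_config(
            seed=int(rng.integers(0, 2**31 - 1)),
            gaze_spread_target=28.5 * spread_f,
            head_contribution_fn=linear_head_contribution(0.50 + recruit, 0.0030),
            mean_speed=0.75 * speed_f,
            path_waypoints=_jitter(SEARCHING_WAYPOINTS),
            calibration_error_deg=cal_err,
        )
        out.append((pid, walk, search))
    return out


@dataclass
class GroundTruth:
    """Noise-free truth for recovery tests; eye + head = gaze sample-wise."""

    true_gaze_series: RotationSeries | None = None
    true_eye_series: RotationSeries | None = None
    true_head_series: RotationSeries | None = None
    true_shift_log: list = field(default_factory=list)
    true_path_length: float | None = None
    true_straightness: float | None = None

    def spreads(self) -> dict:
        out = {}
        for name, s in [
            ("gaze", self.true_gaze_series),
            ("eye", self.true_eye_series),
            ("head", self.true_head_series),
        ]:
            if s is not None:
                out[name] = float(np.std(s.angle, ddof=1))
        return out


# ---------------------------------------------------------------------------
# gaze streams
# ---------------------------------------------------------------------------


def _decompose_target(
    gaze_target: float, fn: Callable[[float], float], eye_limit: float
) -> tuple[float, float]:
    """Split a gaze-in-body target into (eye, head) endpoint components.

    head = g * fn(|g|); eye = g - head, clipped to the oculomotor range
    with the residual reassigned to the head (shifts beyond the range
    require the head).
    """
    amp = abs(gaze_target)
    head = gaze_target * fn(amp)
    eye = gaze_target - head
    if abs(eye) > eye_limit:
        eye = math.copysign(eye_limit, eye)
        head = gaze_target - eye
    return eye, head


def simulate_gaze_streams(
    config: SimulationConfig,
) -> tuple[RotationSeries, RotationSeries, GroundTruth]:
    """Generate noisy eye and head series plus noise-free ground truth.

    Returns 30 Hz eye-in-head and head-in-body series with additive
    Gaussian measurement noise (``noise_sd``), and a :class:`GroundTruth`
    holding the pre-noise series and the shift log
    (time, eccentricity, eye part, head part).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    rate = config.stream_rates["eye"]
    timeline = make_timeline(config.session_duration, rate)
    n = timeline.size

    # Shift onsets: a refractory dwell plus an exponential tail, so that the
    # mean interval is 1/shift_rate but no dwell is shorter than min_dwell_s
    # (gaze holds each target long enough for the lagged head to settle).
    exp_mean = 1.0 / config.shift_rate - config.min_dwell_s
    t = 0.0
    onsets = [0.0]
    while True:
        t += config.min_dwell_s + rng.exponential(exp_mean)
        if t >= config.session_duration:
            break
        onsets.append(t)
    targets = rng.normal(0.0, config.gaze_spread_target, size=len(onsets))

    infeasible = [
        g
        for g in targets
        if abs(g) > config.eye_limit and config.head_contribution_fn(abs(g)) == 0.0
    ]
    if infeasible:
        raise ValueError(
            "infeasible decomposition: gaze target beyond the oculomotor "
            "range with a zero-head recruitment policy"
        )

    shift_log = []
    eye_t = np.empty(len(onsets))
    head_t = np.empty(len(onsets))
    for k, (t_on, g) in enumerate(zip(onsets, targets)):
        e, h = _decompose_target(g, config.head_contribution_fn, config.eye_limit)
        eye_t[k], head_t[k] = e, h
        shift_log.append(
            {"time": float(t_on), "amplitude": abs(float(g)),
             "eye": abs(float(e)), "head": abs(float(h))}
        )

    # sample-wise active components (piecewise constant between shifts)
    idx = np.searchsorted(np.asarray(onsets), timeline, side="right") - 1
    eye_target_s = eye_t[idx]
    head_target_s = head_t[idx]

    # the eye jumps to its endpoint component at shift onset (saccadic);
    # the head follows first-order lag dynamics toward its component, so
    # gaze = eye + head approaches the target as the head settles
    dt = 1.0 / rate
    alpha = 1.0 - math.exp(-dt / config.head_lag_tau)
    head = np.empty(n)
    head[0] = head_target_s[0]
    for i in range(1, n):
        head[i] = head[i - 1] + alpha * (head_target_s[i] - head[i - 1])
    eye = eye_target_s.astype(float)
    gaze = eye + head

    truth = GroundTruth(
        true_gaze_series=RotationSeries(timeline, gaze, "gaze"),
        true_eye_series=RotationSeries(timeline, eye, "eye"),
        true_head_series=RotationSeries(timeline, head, "head"),
        true_shift_log=shift_log,
    )
    eye_noisy = eye + rng.normal(0.0, config.noise_sd, size=n)
    head_noisy = head + rng.normal(0.0, config.noise_sd, size=n)
    return (
        RotationSeries(timeline, eye_noisy, "eye"),
        RotationSeries(timeline, head_noisy, "head"),
        truth,
    )


# ---------------------------------------------------------------------------
# GPS track
# ---------------------------------------------------------------------------


def _polyline_arclength(waypoints: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(waypoints, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at_arclength(waypoints: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    s = min(max(s, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(cum) - 2)
    seg_len = cum[i + 1] - cum[i]
    frac = 0.0 if seg_len == 0 else (s - cum[i]) / seg_len
    return waypoints[i] + frac * (waypoints[i + 1] - waypoints[i])


def simulate_gps_track(
    config: SimulationConfig,
) -> tuple[GpsTrack, float, float]:
    """Simulate the 1 Hz GPS track; returns (track, path_length, straightness).

    Position advances along the waypoint polyline at a per-second speed
    drawn Normal(mean_speed, speed_sd) truncated at zero; searching
    configurations pause 2-10 s at each interior waypoint (target
    retrieval). GPS error is a slowly drifting AR(1) bias, not white
    jitter, mimicking smoothed consumer-watch output. Ground truth is the
    distance actually traveled along the polyline and its straightness
    ratio (traveled / net displacement).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 1)  # decouple from gaze draw
    wp = np.asarray(config.path_waypoints, dtype=float)
    cum = _polyline_arclength(wp)
    total = cum[-1]

    n_sec = int(round(config.session_duration)) + 1
    s = 0.0
    dwell_left = 0.0
    next_wp = 1  # index of next waypoint that triggers a dwell
    positions = np.empty((n_sec, 2))
    positions[0] = wp[0]
    for i in range(1, n_sec):
        if dwell_left > 0:
            dwell_left -= 1.0
        else:
            v = max(0.0, rng.normal(config.mean_speed, config.speed_sd))
            s = min(s + v, total)
            # dwell when a waypoint is reached (searching only)
            while (
                config.dwell_range_s is not None
                and next_wp < len(cum)
                and s >= cum[next_wp]
            ):
                s = cum[next_wp]
                dwell_left = rng.uniform(*config.dwell_range_s)
                next_wp += 1
        positions[i] = _point_at_arclength(wp, cum, s)

    true_path_length = float(s)
    net = float(np.hypot(*(positions[-1] - positions[0])))
    if net < 1e-9:
        raise ValueError("zero net displacement: straightness undefined")
    true_straightness = true_path_length / net

    # slowly drifting AR(1) positional bias, per axis
    phi, sd = config.gps_noise_ar, config.gps_noise_sd_m
    if sd > 0:
        innov_sd = sd * math.sqrt(1.0 - phi * phi)
        noise = np.empty((n_sec, 2))
        noise[0] = rng.normal(0.0, sd, size=2)
        eps = rng.normal(0.0, innov_sd, size=(n_sec - 1, 2))
        for i in range(1, n_sec):
            noise[i] = phi * noise[i - 1] + eps[i - 1]
        positions = positions + noise

    lat0, lon0 = config.origin_latlon
    lat = lat0 + np.degrees(positions[:, 1] / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(
        positions[:, 0] / (EARTH_RADIUS_M * math.cos(math.radians(lat0)))
    )
    track = GpsTrack(
        timeline=np.arange(n_sec, dtype=float), latitude=lat, longitude=lon
    )
    return track, true_path_length, true_straightness


# ---------------------------------------------------------------------------
# raw-bundle rendering
# ---------------------------------------------------------------------------


def _to_stream_clock(t_true: np.ndarray, config: SimulationConfig, stream: str):
    return (t_true + config.clock_offsets[stream]) * (1.0 + config.clock_drifts[stream])


def _write_csv(path: Path, header: list[str], rows) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def _write_gpx(path: Path, t_stream: np.ndarray, lat: np.ndarray, lon: np.ndarray):
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<gpx version="1.1" creator="gazekit" '
        'xmlns="http://www.topografix.com/GPX/1/1">',
        " <trk><trkseg>",
    ]
    for t, la, lo in zip(t_stream, lat, lon):
        stamp = (GPX_EPOCH + timedelta(seconds=float(t))).strftime(
            "%Y-%m-%dT%H:%M:%S.%f"
        )[:-3] + "Z"
        lines.append(
            f'  <trkpt lat="{la:.8f}" lon="{lo:.8f}"><time>{stamp}</time></trkpt>'
        )
    lines += [" </trkseg></trk>", "</gpx>", ""]
    path.write_text("\n".join(lines))


def render_raw_session(
    eye: RotationSeries,
    head: RotationSeries,
    gps: GpsTrack,
    camera: CameraModel,
    config: SimulationConfig,
    out_dir: str | Path,
    truth: GroundTruth | None = None,
) -> Path:
    """Write the raw per-session file bundle the ingest module reads.

    Eye degrees pass through the FORWARD fisheye distortion to pixels (the
    inverse of the pipeline's undistortion); each stream's timestamps are
    re-expressed in its own clock; the head series is resampled to 400 Hz;
    sync-event pairs are written for session start and end; calibration
    validation point pairs carry the configured injected angular error.
    Samples outside the camera FOV are written as empty cells (missing).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed + 2)

    # --- eye pixels, eye clock ---------------------------------------------
    half_fov = camera.horizontal_fov_deg / 2.0
    px = distort_points(degrees_to_pixels(eye.angle, camera), camera)
    in_fov = np.abs(eye.angle) < half_fov
    t_eye = _to_stream_clock(eye.timeline, config, "eye")
    rows = [
        (f"{t:.6f}", f"{x:.3f}", f"{y:.3f}") if ok else (f"{t:.6f}", "", "")
        for t, (x, y), ok in zip(t_eye, px, in_fov)
    ]
    _write_csv(out / "eye_px.csv", ["t", "x_px", "y_px"], rows)

    # --- head at 400 Hz, head clock ----------------------------------------
    head_rate = config.stream_rates["head"]
    t400 = make_timeline(config.session_duration, head_rate)
    yaw400 = np.interp(t400, head.timeline, head.angle)
    t_head = _to_stream_clock(t400, config, "head")
    _write_csv(
        out / "head_deg.csv",
        ["t", "yaw_deg"],
        [(f"{t:.6f}", f"{y:.4f}") for t, y in zip(t_head, yaw400)],
    )

    # --- GPS, gps clock ----------------------------------------------------
    t_gps = _to_stream_clock(gps.timeline, config, "gps")
    _write_gpx(out / "track.gpx", t_gps, gps.latitude, gps.longitude)

    # --- sync events (true session start / end observed in each clock) ----
    # GPS timestamps are absolute UTC (as in GPX), so its sync events are
    # POSIX seconds; eye and head clocks are relative device clocks.
    t_events = np.array([0.0, config.session_duration])
    t_ref = _to_stream_clock(t_events, config, "eye")
    epoch = GPX_EPOCH.timestamp()
    stream_event_times = {
        stream: _to_stream_clock(t_events, config, stream)
        + (epoch if stream == "gps" else 0.0)
        for stream in ("eye", "head", "gps")
    }
    sync = {
        "reference": "eye",
        "streams": {
            stream: [
                {
                    "label": lbl,
                    "t_reference": float(tr),
                    "t_stream": float(ts),
                }
                for lbl, tr, ts in zip(
                    ["session_start", "session_end"], t_ref, times
                )
            ]
            for stream, times in stream_event_times.items()
        },
    }
    (out / "sync.json").write_text(json.dumps(sync, indent=1))

    # --- task window (reference clock) -------------------------------------
    tasks = [
        {
            "task": config.task_label,
            "t_start": float(t_ref[0]),
            "t_end": float(t_ref[1]),
        }
    ]
    (out / "tasks.json").write_text(json.dumps(tasks, indent=1))

    camera.save(out / "camera.json")

    # --- calibration validation pairs: 5 looks with injected error ---------
    target_angles = np.array(
        [(0.0, 0.0), (-20.0, 0.0), (20.0, 0.0), (0.0, -12.0), (0.0, 12.0)]
    )
    cal_rows = []
    for hx, vy in target_angles:
        direction = rng.uniform(0.0, 2 * math.pi)
        gx = hx + config.calibration_error_deg * math.cos(direction)
        gy = vy + config.calibration_error_deg * math.sin(direction)
        tpx = distort_points(
            degrees_to_pixels(np.array([hx]), camera, vertical_deg=vy), camera
        )[0]
        gpx_ = distort_points(
            degrees_to_pixels(np.array([gx]), camera, vertical_deg=gy), camera
        )[0]
        cal_rows.append(
            (f"{tpx[0]:.3f}", f"{tpx[1]:.3f}", f"{gpx_[0]:.3f}", f"{gpx_[1]:.3f}")
        )
    _write_csv(
        out / "calibration_points.csv",
        ["target_x_px", "target_y_px", "gaze_x_px", "gaze_y_px"],
        cal_rows,
    )

    if truth is not None:
        gt = {
            "task": config.task_label,
            "spreads": truth.spreads(),
            "shift_log": truth.true_shift_log,
            "path_length_m": truth.true_path_length,
            "straightness": truth.true_straightness,
            "gaze_spread_target": config.gaze_spread_target,
            "mean_speed": config.mean_speed,
            "rng_seed": config.rng_seed,
        }
        (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    return out


def simulate_session(
    config: SimulationConfig,
    out_dir: str | Path,
    camera: CameraModel | None = None,
) -> tuple[Path, GroundTruth]:
    """Simulate one session end to end and write its raw bundle."""
    camera = camera or CameraModel(distortion=(-0.05, 0.01))
    eye, head, truth = simulate_gaze_streams(config)
    gps, length, straight = simulate_gps_track(config)
    truth.true_path_length = length
    truth.true_straightness = straight
    out = render_raw_session(eye, head, gps, camera, config, out_dir, truth)
    return out, truth
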