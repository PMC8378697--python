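"""End-to-end processing of one aligned session into its measures.

Ties the modules together: pixels -> degrees for the eye, gaze-in-body
composition, spread per effector, gaze-shift peaks with binned head
contributions, locomotion measures from the GPS track, and calibration
screening. The analysis drivers and the acceptance script both run
sessions through this path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gazekit.camera import (
    calibration_error,
    pixels_to_degrees,
    screen_calibration,
    undistort_points,
)
from gazekit.io_sync import AlignedSession
from gazekit.kinematics import (
    EccentricityBinning,
    bin_head_contributions,
    compose_gaze,
    detect_gaze_peaks,
    spread,
)
from gazekit.locomotion import GpsTrack, LocomotionMeasures, locomotion_measures
from gazekit.series import RotationSeries


@dataclass
class SessionMeasures:
    """Per-participant, per-task summary of one session."""

    participant_id: str
    task: str
    spreads: dict = field(default_factory=dict)  # effector -> degrees
    locomotion: LocomotionMeasures | None = None
    contribution_bins: pd.DataFrame | None = None
    peaks: list = field(default_factory=list)
    n_peaks: int = 0
    calibration_error_deg: float | None = None
    include: bool = True


def eye_series_from_pixels(session: AlignedSession) -> RotationSeries:
    """Undistort the eye pixel stream and convert to degrees of rotation."""
    if session.camera is None:
        raise ValueError("session has no camera model; cannot convert pixels")
    und = undistort_points(session.eye_px, session.camera)
    deg = np.asarray(
        [pixels_to_degrees(p, session.camera) if not np.isnan(p).any() else np.nan
         for p in np.atleast_2d(und)]
    )
    return RotationSeries(session.timeline, deg, "eye")


def process_session(
    session: AlignedSession,
    participant_id: str = "p0",
    min_separation_s: float = 10 / 30.0,
    binning: EccentricityBinning | None = None,
) -> list[SessionMeasures]:
    """Compute all measures for every task window of one session."""
    eye = eye_series_from_pixels(session)
    head = gaze = None
    if session.has_head:
        head = RotationSeries(session.timeline, session.head_deg, "head")
        gaze = compose_gaze(eye, head)

    track = None
    if session.has_gps:
        ok = ~np.isnan(session.gps_latlon).any(axis=1)
        track = GpsTrack(
            timeline=session.timeline[ok],
            latitude=session.gps_latlon[ok, 0],
            longitude=session.gps_latlon[ok, 1],
        )

    cal_err = None
    if session.calibration_pairs and session.camera is not None:
        cal_err, _ = calibration_error(session.calibration_pairs, session.camera)

    results = []
    for task, t0, t1 in session.task_windows:
        m = SessionMeasures(participant_id=participant_id, task=task)
        m.calibration_error_deg = cal_err
        if cal_err is not None:
            m.include = screen_calibration(cal_err)
        m.spreads["eye"] = spread(eye, (t0, t1))
        if head is not None:
            m.spreads["head"] = spread(head, (t0, t1))
            m.spreads["gaze"] = spread(gaze, (t0, t1))
            peaks = detect_gaze_peaks(
                gaze.window(t0, t1),
                eye.window(t0, t1),
                head.window(t0, t1),
                min_separation_s=min_separation_s,
            )
            m.peaks = peaks
            m.n_peaks = len(peaks)
            m.contribution_bins = bin_head_contributions(peaks, binning)
        if track is not None:
            m.locomotion = locomotion_measures(track, (t0, t1))
        results.append(m)
    return results


def measures_to_table(all_measures: list[SessionMeasures]) -> pd.DataFrame:
    """Long-format measure table: one row per participant x task x measure."""
    rows = []
    for m in all_measures:
        base = {"participant": m.participant_id, "task": m.task}
        for eff, val in m.spreads.items():
            rows.append({**base, "effector": eff, "measure": "spread", "value": val})
        if m.locomotion is not None:
            for name in (
                "path_length_m",
                "mean_speed_ms",
                "speed_sd_ms",
                "straightness_ratio",
                "task_time_s",
            ):
                rows.append(
                    {
                        **base,
                        "effector": None,
                        "measure": name,
                        "value": getattr(m.locomotion, name),
                    }
                )
    df = pd.DataFrame(rows)
    if df.duplicated(["participant", "task", "effector", "measure"]).any():
        raise ValueError("duplicate participant x task x measure keys")
    return df


def contributions_to_table(all_measures: list[SessionMeasures]) -> pd.DataFrame:
    """Per-participant per-task per-bin mean head contributions."""
    rows = []
    for m in all_measures:
        if m.contribution_bins is None:
            continue
        for b, r in m.contribution_bins.iterrows():
            rows.append(
                {
                    "participant": m.participant_id,
                    "task": m.task,
                    "bin": int(b),
                    "value": r["mean_contribution"],
                    "n_peaks": int(r["n_peaks"]),
                }
            )
    return pd.DataFrame(rows)
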