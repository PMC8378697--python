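"""Gaze-in-body kinematics: composition, spread, and gaze-shift peaks.

Gaze-in-body is the sample-wise sum of eye-in-head and head-in-body
horizontal rotation. Visual-exploration *spread* is the standard deviation
of a rotation series over a task. Gaze shifts are the local extrema of the
gaze-in-body series — minima are shifts to the left of the body, maxima are
shifts to the right — and each peak's *head contribution* is the percentage
of its eccentricity accounted for by head rather than eye rotation,
aggregated per participant in eight 10-degree eccentricity bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gazekit.series import RotationSeries, same_timeline

#: biomechanical limit of horizontal eye-in-head rotation, degrees
OCULOMOTOR_RANGE_DEG = 55.0

#: minimum separation between recorded peaks: 10 frames at 30 Hz
DEFAULT_MIN_SEPARATION_S = 10 / 30.0


def compose_gaze(eye: RotationSeries, head: RotationSeries) -> RotationSeries:
    """Gaze-in-body = eye-in-head + head-in-body, sample-wise.

    Missing (NaN) in either input propagates to the sum. Sign convention:
    negative rotations are to the left, 0 is body center, positive right.
    """
    if not same_timeline(eye, head):
        raise ValueError("eye and head series must share one timeline")
    return RotationSeries(eye.timeline.copy(), eye.angle + head.angle, "gaze")


def spread(
    series: RotationSeries,
    window: tuple[float, float] | None = None,
) -> float:
    """Spread of visual exploration: sample SD (ddof=1) of rotation.

    Missing samples are excluded; a window (t_start, t_end) restricts the
    computation to one task.
    """
    sub = series if window is None else series.window(*window)
    vals = sub.angle[~np.isnan(sub.angle)]
    if vals.size < 2:
        raise ValueError("spread requires >= 2 non-missing samples in window")
    return float(np.std(vals, ddof=1))


@dataclass
class GazeShiftPeak:
    """One detected extremum of the gaze-in-body series.

    Components are magnitudes (absolute degrees) of the same-signed eye and
    head rotations at the peak sample; they sum to the eccentricity.
    """

    t_peak: float
    direction: str  # "left" (minimum) or "right" (maximum)
    gaze_eccentricity: float
    eye_component: float
    head_component: float

    @property
    def head_contribution(self) -> float:
        return head_contribution(self.eye_component, self.head_component)


def head_contribution(eye_deg: float, head_deg: float) -> float:
    """Percentage of a gaze shift accomplished by the head.

    100 * |head| / (|eye| + |head|). Eye and head must rotate in the same
    direction (opposite-signed pairs are excluded upstream); e.g. eyes 20
    degrees left plus head 20 degrees left gives a combined eccentricity of
    40 degrees with a 50% head contribution.
    """
    e, h = abs(float(eye_deg)), abs(float(head_deg))
    if e + h == 0:
        raise ValueError("zero-eccentricity shift has no defined contribution")
    if np.sign(eye_deg) * np.sign(head_deg) < 0:
        raise ValueError("eye and head components must share a direction")
    return 100.0 * h / (e + h)


def _strict_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima; plateaus use the center
    sample. NaN samples never qualify and break plateau runs."""
    n = x.size
    maxima: list[int] = []
    minima: list[int] = []
    i = 1
    while i < n - 1:
        if np.isnan(x[i]):
            i += 1
            continue
        # plateau run [i, j]
        j = i
        while j + 1 < n - 1 and x[j + 1] == x[i]:
            j += 1
        left, right = x[i - 1], x[j + 1]
        if not (np.isnan(left) or np.isnan(right)):
            center = (i + j) // 2
            if left < x[i] and right < x[i]:
                maxima.append(center)
            elif left > x[i] and right > x[i]:
                minima.append(center)
        i = j + 1
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def detect_gaze_peaks(
    gaze: RotationSeries,
    eye: RotationSeries,
    head: RotationSeries,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    min_prominence: float = 0.0,
) -> list[GazeShiftPeak]:
    """Detect gaze-shift peaks in the gaze-in-body series.

    Local maxima are shifts to the right of the body, local minima shifts to
    the left. A peak is recorded only when eyes and head are rotated in the
    same (nonzero) direction at the peak sample. Peaks closer together than
    ``min_separation_s`` (default 10 frames = 333 ms at 30 Hz) conflict; the
    conflict is resolved greedily in favor of the larger eccentricity.

    ``min_prominence`` optionally drops extrema whose |gaze| falls below the
    threshold; 0 (default) disables it.
    """
    if not (same_timeline(gaze, eye) and same_timeline(gaze, head)):
        raise ValueError("gaze, eye, and head series must share one timeline")
    x = gaze.angle
    maxima, minima = _strict_extrema(x)

    candidates: list[GazeShiftPeak] = []
    for idx, direction in [(i, "right") for i in maxima] + [
        (i, "left") for i in minima
    ]:
        e, h = eye.angle[idx], head.angle[idx]
        if np.isnan(e) or np.isnan(h):
            continue
        if np.sign(e) == 0 or np.sign(e) != np.sign(h):
            continue
        ecc = abs(x[idx])
        if ecc <= min_prominence or ecc == 0:
            continue
        candidates.append(
            GazeShiftPeak(
                t_peak=float(gaze.timeline[idx]),
                direction=direction,
                gaze_eccentricity=float(ecc),
                eye_component=float(abs(e)),
                head_component=float(abs(h)),
            )
        )

    # greedy separation: keep larger-eccentricity peaks, drop conflicters
    kept: list[GazeShiftPeak] = []
    for pk in sorted(candidates, key=lambda p: -p.gaze_eccentricity):
        if all(abs(pk.t_peak - q.t_peak) >= min_separation_s for q in kept):
            kept.append(pk)
    kept.sort(key=lambda p: p.t_peak)
    return kept


@dataclass
class EccentricityBinning:
    """Eight half-open 10-degree eccentricity bins: [10,20), ..., [80, inf).

    Each bin is labelled by its lower bound; peaks below 10 degrees fall in
    no bin and are excluded from the contribution analysis.
    """

    lower_bounds: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80)

    @property
    def labels(self) -> list[int]:
        return [int(b) for b in self.lower_bounds]

    def assign(self, eccentricity: float) -> int | None:
        """Bin label for an eccentricity, or None if below the first bin."""
        if eccentricity < self.lower_bounds[0]:
            return None
        edges = list(self.lower_bounds) + [np.inf]
        for lo, hi in zip(edges[:-1], edges[1:]):
            if lo <= eccentricity < hi:
                return int(lo)
        return None  # pragma: no cover


def bin_head_contributions(
    peaks: list[GazeShiftPeak],
    binning: EccentricityBinning | None = None,
) -> pd.DataFrame:
    """Mean head contribution per eccentricity bin for one participant-task.

    Returns a DataFrame indexed by bin label with columns
    ``mean_contribution`` (percent) and ``n_peaks``; bins with no peaks are
    absent from the index (never imputed as zero).
    """
    binning = binning or EccentricityBinning()
    rows = []
    for pk in peaks:
        label = binning.assign(pk.gaze_eccentricity)
        if label is None:
            continue
        rows.append({"bin": label, "contribution": pk.head_contribution})
    if not rows:
        return pd.DataFrame(
            columns=["mean_contribution", "n_peaks"],
            index=pd.Index([], name="bin"),
        )
    df = pd.DataFrame(rows)
    out = df.groupby("bin")["contribution"].agg(["mean", "count"])
    out.columns = ["mean_contribution", "n_peaks"]
    return out


def peaks_to_frame(
    peaks: list[GazeShiftPeak], binning: EccentricityBinning | None = None
) -> pd.DataFrame:
    """Tabulate peaks (peaks.csv schema): t_peak, direction, eccentricity,
    components, contribution, bin label (NaN below 10 degrees)."""
    binning = binning or EccentricityBinning()
    return pd.DataFrame(
        {
            "t_peak": [p.t_peak for p in peaks],
            "direction": [p.direction for p in peaks],
            "eccentricity_deg": [p.gaze_eccentricity for p in peaks],
            "eye_deg": [p.eye_component for p in peaks],
            "head_deg": [p.head_component for p in peaks],
            "contribution_pct": [p.head_contribution for p in peaks],
            "bin_label": [
                b if (b := binning.assign(p.gaze_eccentricity)) is not None else np.nan
                for p in peaks
            ],
        }
    )
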