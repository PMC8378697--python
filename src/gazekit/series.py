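"""Uniformly sampled horizontal rotation time series.

Angles are signed degrees: negative = left of body center, 0 = center,
positive = right. Missing samples (tracker dropouts, out-of-FOV looks) are
encoded as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EFFECTORS = ("eye", "head", "gaze")


@dataclass
class RotationSeries:
    """One effector's horizontal rotation sampled on a uniform timeline.

    Parameters
    ----------
    timeline : array of float
        Sample times in seconds, uniformly spaced (nominally 30 Hz).
    angle : array of float
        Signed horizontal rotation in degrees; NaN marks missing samples.
    effector : {"eye", "head", "gaze"}
        Which rotation this series measures: eye-in-head, head-in-body,
        or their sum, gaze-in-body.
    """

    timeline: np.ndarray
    angle: np.ndarray
    effector: str = "gaze"

    def __post_init__(self) -> None:
        self.timeline = np.asarray(self.timeline, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.timeline.shape != self.angle.shape:
            raise ValueError(
                f"timeline and angle shapes differ: "
                f"{self.timeline.shape} vs {self.angle.shape}"
            )
        if self.effector not in EFFECTORS:
            raise ValueError(f"effector must be one of {EFFECTORS}")
        if self.timeline.size >= 2 and not np.all(np.diff(self.timeline) > 0):
            raise ValueError("timeline must be strictly increasing")

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing samples."""
        return np.isnan(self.angle)

    @property
    def rate(self) -> float:
        """Nominal sampling rate in Hz."""
        if self.timeline.size < 2:
            raise ValueError("rate undefined for series with < 2 samples")
        return 1.0 / float(np.median(np.diff(self.timeline)))

    def __len__(self) -> int:
        return self.timeline.size

    def window(self, t_start: float, t_end: float) -> "RotationSeries":
        """Sub-series with timeline in [t_start, t_end]."""
        m = (self.timeline >= t_start) & (self.timeline <= t_end)
        return RotationSeries(self.timeline[m], self.angle[m], self.effector)


def same_timeline(a: RotationSeries, b: RotationSeries, atol: float = 1e-9) -> bool:
    return a.timeline.shape == b.timeline.shape and np.allclose(
        a.timeline, b.timeline, atol=atol
    )


def make_timeline(duration: float, rate: float = 30.0, t0: float = 0.0) -> np.ndarray:
    """Uniform timeline covering [t0, t0 + duration] at `rate` Hz."""
    n = int(round(duration * rate)) + 1
    return t0 + np.arange(n) / rate
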