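"""Fisheye camera model: pixels <-> degrees of visual angle.

The scene ("field of view") camera of a head-mounted eye tracker carries a
wide-angle fisheye lens, so raw gaze estimates in pixel coordinates must be
corrected for lens distortion before they can be converted to degrees of
eye-in-head rotation.

Model family: equidistant fisheye with even-order polynomial distortion.
The ideal (distortion-free) projection is angle-proportional,

    r_px = f * theta,     f = image_width_px / horizontal_fov_rad,

which makes the pixel-to-degree conversion linear in displacement from the
principal point: degrees = delta_x_px * horizontal_fov_deg / image_width_px.
Distortion acts on the field angle,

    theta_d = theta * (1 + k1*theta**2 + k2*theta**4),

and undistortion inverts this by Newton iteration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_MAX_NEWTON_ITER = 50
# quadratic convergence makes the tighter tolerance ~1 extra iteration;
# 1e-12 rad keeps the pixel round-trip error below 1e-6 px at the image edge
_NEWTON_TOL_RAD = 1e-12


@dataclass
class CameraModel:
    """Equidistant-fisheye scene camera.

    Parameters
    ----------
    image_width_px, image_height_px : int
        Sensor size in pixels.
    horizontal_fov_deg : float
        Horizontal field of view; the study camera's value is 111 degrees.
    principal_point_px : (float, float)
        Optical center in pixel coordinates; defaults to the image center.
    distortion : (k1, k2)
        Even-order polynomial distortion coefficients on the field angle.
    """

    image_width_px: int = 640
    image_height_px: int = 480
    horizontal_fov_deg: float = 111.0
    principal_point_px: tuple[float, float] | None = None
    distortion: tuple[float, ...] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.horizontal_fov_deg < 180.0:
            raise ValueError("horizontal_fov_deg must be in (0, 180)")
        if self.principal_point_px is None:
            self.principal_point_px = (
                self.image_width_px / 2.0,
                self.image_height_px / 2.0,
            )
        cx, cy = self.principal_point_px
        if not (0 <= cx <= self.image_width_px and 0 <= cy <= self.image_height_px):
            raise ValueError("principal point must lie inside the image")

    @property
    def focal_px_per_rad(self) -> float:
        return self.image_width_px / math.radians(self.horizontal_fov_deg)

    @property
    def deg_per_px(self) -> float:
        return self.horizontal_fov_deg / self.image_width_px

    # -- JSON round trip (camera.json schema) -------------------------------

    def to_dict(self) -> dict:
        return {
            "image_width_px": self.image_width_px,
            "image_height_px": self.image_height_px,
            "horizontal_fov_deg": self.horizontal_fov_deg,
            "principal_point_px": list(self.principal_point_px),
            "distortion": list(self.distortion),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            image_width_px=int(d["image_width_px"]),
            image_height_px=int(d["image_height_px"]),
            horizontal_fov_deg=float(d["horizontal_fov_deg"]),
            principal_point_px=tuple(d["principal_point_px"]),
            distortion=tuple(d.get("distortion", (0.0, 0.0))),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CameraModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CalibrationPointPair:
    """A validation look: true target vs. estimated gaze, both in pixels."""

    target_px: tuple[float, float]
    gaze_px: tuple[float, float]


def _poly_theta(theta: np.ndarray, coeffs: tuple[float, ...]) -> np.ndarray:
    """theta_d = theta * (1 + k1 theta^2 + k2 theta^4 + ...)."""
    out = np.ones_like(theta)
    t2 = theta * theta
    p = t2.copy()
    for k in coeffs:
        out = out + k * p
        p = p * t2
    return theta * out


def _poly_theta_deriv(theta: np.ndarray, coeffs: tuple[float, ...]) -> np.ndarray:
    out = np.ones_like(theta)
    t2 = theta * theta
    p = t2.copy()
    for i, k in enumerate(coeffs):
        out = out + (2 * i + 3) * k * p
        p = p * t2
    return out


def distort_points(points_px: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Forward fisheye distortion of ideal-projection pixel points.

    The generator's forward model: takes points under the ideal equidistant
    projection and returns where the physical lens images them.
    """
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    cx, cy = camera.principal_point_px
    f = camera.focal_px_per_rad
    d = pts - [cx, cy]
    r = np.hypot(d[:, 0], d[:, 1])
    theta = r / f
    theta_d = _poly_theta(theta, camera.distortion)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, (f * theta_d) / np.where(r > 0, r, 1.0), 1.0)
    out = np.column_stack([cx + d[:, 0] * scale, cy + d[:, 1] * scale])
    return out.reshape(np.asarray(points_px, dtype=float).shape)


def undistort_points(points_px: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Invert the fisheye distortion; non-converged points become NaN.

    Solves theta from theta_d = theta(1 + k1 theta^2 + k2 theta^4) by Newton
    iteration to 1e-8 rad; the principal point maps to itself. Points whose
    iteration does not converge within 50 steps are returned as NaN
    (missing), not raised.
    """
    orig_shape = np.asarray(points_px, dtype=float).shape
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    cx, cy = camera.principal_point_px
    f = camera.focal_px_per_rad
    d = pts - [cx, cy]
    r_d = np.hypot(d[:, 0], d[:, 1])
    theta_d = r_d / f

    theta = theta_d.copy()
    converged = np.zeros_like(theta, dtype=bool)
    for _ in range(_MAX_NEWTON_ITER):
        resid = _poly_theta(theta, camera.distortion) - theta_d
        converged = np.abs(resid) < _NEWTON_TOL_RAD
        if converged.all():
            break
        step = resid / _poly_theta_deriv(theta, camera.distortion)
        theta = np.where(converged, theta, theta - step)
    resid = _poly_theta(theta, camera.distortion) - theta_d
    converged = np.abs(resid) < _NEWTON_TOL_RAD

    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r_d > 0, (f * theta) / np.where(r_d > 0, r_d, 1.0), 1.0)
    out = np.column_stack([cx + d[:, 0] * scale, cy + d[:, 1] * scale])
    out[~converged] = np.nan
    return out.reshape(orig_shape)


def pixels_to_degrees(points_px: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Horizontal visual angle of undistorted pixel points, in degrees.

    Uses the ideal equidistant relation: degrees is linear in horizontal
    displacement from the principal point, with slope
    horizontal_fov_deg / image_width_px. Negative = left.
    """
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    cx, _ = camera.principal_point_px
    deg = (pts[:, 0] - cx) * camera.deg_per_px
    if np.asarray(points_px).ndim == 1:
        return float(deg[0])
    return deg


def degrees_to_pixels(
    angle_deg: np.ndarray, camera: CameraModel, vertical_deg: np.ndarray | float = 0.0
) -> np.ndarray:
    """Ideal-projection pixel coordinates of a horizontal (and optional
    vertical) visual angle; inverse of :func:`pixels_to_degrees`."""
    a = np.atleast_1d(np.asarray(angle_deg, dtype=float))
    v = np.broadcast_to(np.asarray(vertical_deg, dtype=float), a.shape)
    cx, cy = camera.principal_point_px
    return np.column_stack([cx + a / camera.deg_per_px, cy + v / camera.deg_per_px])


def point_angles_deg(points_px: np.ndarray, camera: CameraModel) -> np.ndarray:
    """(horizontal, vertical) visual angles of undistorted pixel points."""
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    cx, cy = camera.principal_point_px
    return np.column_stack(
        [(pts[:, 0] - cx) * camera.deg_per_px, (pts[:, 1] - cy) * camera.deg_per_px]
    )


def calibration_error(
    pairs: list[CalibrationPointPair], camera: CameraModel
) -> tuple[float, np.ndarray]:
    """Mean 2-D angular separation between target and gaze validation looks.

    Each pair is undistorted, converted to (horizontal, vertical) degrees,
    and the Euclidean angular distance taken; returns (mean, per-pair).
    Screening threshold: errors above 5 degrees exclude a participant.
    """
    if not pairs:
        raise ValueError("calibration_error requires at least one point pair")
    targets = np.array([p.target_px for p in pairs], dtype=float)
    gazes = np.array([p.gaze_px for p in pairs], dtype=float)
    t_ang = point_angles_deg(undistort_points(targets, camera), camera)
    g_ang = point_angles_deg(undistort_points(gazes, camera), camera)
    per_pair = np.hypot(*(t_ang - g_ang).T)
    return float(np.mean(per_pair)), per_pair


def screen_calibration(error_deg: float, threshold_deg: float = 5.0) -> bool:
    """Quality screen: True = include; exclude iff error > threshold
    (strict inequality, so an error of exactly 5 degrees is retained)."""
    if error_deg < 0:
        raise ValueError("calibration error cannot be negative")
    return error_deg <= threshold_deg
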