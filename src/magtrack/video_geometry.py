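"""Dual-angle video-oculography geometry.

Two cameras view the eye with their optical axes separated by a fixed angle
``alpha`` (40 degrees by default) and equidistant from the eye.  Each
camera's infrared LED produces a corneal reflection (CR) on the corneal
radius parallel to that camera's axis, so the signed horizontal distance
``delta = pupil - CR`` in each image isolates eye rotation from translation.

With ``theta_1`` and ``theta_2`` the angles from each camera axis to the
pupil axis (``theta_1 + theta_2 = alpha``) and ``R_p`` the distance from the
pupil plane to the center of corneal curvature:

    delta_1 = R_p * sin(theta_1),    delta_2 = R_p * sin(theta_2)

Taking the ratio eliminates ``R_p``, giving angular eye position from image
measurements alone:

    theta_2 = atan2(delta_2 * sin(alpha), delta_1 + delta_2 * cos(alpha))

The atan2 form is algebraically equal to the quotient formula
``atan(sin(alpha) / (delta_1/delta_2 + cos(alpha)))`` wherever
``delta_2 > 0`` but remains well-defined at ``delta_2 = 0`` and for signed
deltas.  Reported eye position uses the symmetric-zero convention: 0 deg is
the bisector of the two camera axes, so ``eye = theta_2 - alpha/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EyeTrace

__all__ = [
    "CameraRig",
    "PupilFrameSeries",
    "angle_from_deltas",
    "forward_deltas",
    "eye_position_from_frames",
]


@dataclass
class CameraRig:
    """Fixed dual-camera geometry.

    ``inter_camera_angle_deg``: angle between the two camera axes.
    ``camera_distance_mm``: lens-to-axis-intersection distance A.
    ``pixel_scale_mm_per_px``: image magnification at the eye.
    ``frame_rate_hz``: video acquisition rate.
    ``nasal_camera``: which camera (1 or 2) sits on the nasal side; flips the
    sign of the reported angle so that positive is always the configured
    nasal->temporal (rightward) direction.
    """

    inter_camera_angle_deg: float = 40.0
    camera_distance_mm: float = 50.0
    pixel_scale_mm_per_px: float = 0.005
    frame_rate_hz: float = 30.0
    nasal_camera: int = 2

    def __post_init__(self):
        if not 0.0 < self.inter_camera_angle_deg < 90.0:
            raise ValueError("inter-camera angle must lie in (0, 90) degrees")
        if self.camera_distance_mm <= 0:
            raise ValueError("camera distance must be positive")
        if self.pixel_scale_mm_per_px <= 0:
            raise ValueError("pixel scale must be positive")
        if self.nasal_camera not in (1, 2):
            raise ValueError("nasal_camera must be 1 or 2")

    @property
    def sign(self) -> float:
        """+1 when camera 2 is nasal (eye = theta2 - alpha/2 increases nasal-ward)."""
        return 1.0 if self.nasal_camera == 2 else -1.0


@dataclass
class PupilFrameSeries:
    """Per-frame pupil and reference-CR pixel landmarks for both cameras.

    ``pupil_px`` and ``cr_px`` have shape (n_frames, 2 cameras, 2) holding
    (x, y) pixel coordinates; ``valid`` flags frames whose landmarks are
    usable.  Signed horizontal deltas are derived, never stored.
    """

    time_s: np.ndarray
    pupil_px: np.ndarray
    cr_px: np.ndarray
    pixel_scale_mm_per_px: float
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pupil_px = np.asarray(self.pupil_px, dtype=float)
        self.cr_px = np.asarray(self.cr_px, dtype=float)
        n = self.time_s.size
        for name, arr in (("pupil_px", self.pupil_px), ("cr_px", self.cr_px)):
            if arr.shape != (n, 2, 2):
                raise ValueError(f"{name} must have shape (n_frames, 2, 2)")
        if self.pixel_scale_mm_per_px <= 0:
            raise ValueError("pixel scale must be positive")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (n,):
                raise ValueError("valid must be one flag per frame")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def delta_px(self) -> np.ndarray:
        """Signed horizontal pupil-CR distance (px), shape (n, 2)."""
        return self.pupil_px[:, :, 0] - self.cr_px[:, :, 0]

    @property
    def delta_mm(self) -> np.ndarray:
        """Signed horizontal pupil-CR distance (mm), shape (n, 2)."""
        return self.delta_px * self.pixel_scale_mm_per_px


def angle_from_deltas(delta1_mm, delta2_mm, rig: CameraRig | None = None) -> np.ndarray:
    """Eye-axis angle theta_2 (deg) from the two signed pupil-CR distances.

    theta_2 = atan2(delta_2*sin(alpha), delta_1 + delta_2*cos(alpha)).
    Independent of R_p: scaling both deltas by any positive constant leaves
    the output unchanged.  Raises if both deltas are zero (the pupil axis
    is then undefined).
    """
    if rig is None:
        rig = CameraRig()
    d1 = np.asarray(delta1_mm, dtype=float)
    d2 = np.asarray(delta2_mm, dtype=float)
    if np.any((d1 == 0.0) & (d2 == 0.0)):
        raise ValueError("both deltas zero: eye angle undefined")
    alpha = np.deg2rad(rig.inter_camera_angle_deg)
    return np.rad2deg(np.arctan2(d2 * np.sin(alpha), d1 + d2 * np.cos(alpha)))


def forward_deltas(theta2_deg, r_p_mm, rig: CameraRig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Forward projection: (delta_1, delta_2) in mm for eye-axis angle theta_2.

    delta_1 = R_p*sin(alpha - theta_2), delta_2 = R_p*sin(theta_2); exact
    inverse of :func:`angle_from_deltas` up to floating point.
    """
    if rig is None:
        rig = CameraRig()
    th2 = np.deg2rad(np.asarray(theta2_deg, dtype=float))
    alpha = np.deg2rad(rig.inter_camera_angle_deg)
    return r_p_mm * np.sin(alpha - th2), r_p_mm * np.sin(th2)


def eye_position_from_frames(frames: PupilFrameSeries, rig: CameraRig | None = None) -> EyeTrace:
    """Per-frame angular eye position from landmark series.

    Applies :func:`angle_from_deltas` to each valid frame and maps to the
    symmetric-zero convention (eye = theta_2 - alpha/2, signed per
    ``rig.nasal_camera``).  Invalid frames yield NaN gaps.
    """
    if rig is None:
        rig = CameraRig()
    if not frames.valid.any():
        raise ValueError("no valid frames")
    dmm = frames.delta_mm
    pos = np.full(len(frames), np.nan)
    v = frames.valid & ~((dmm[:, 0] == 0) & (dmm[:, 1] == 0))
    theta2 = angle_from_deltas(dmm[v, 0], dmm[v, 1], rig)
    pos[v] = rig.sign * (theta2 - rig.inter_camera_angle_deg / 2.0)
    dt = np.diff(frames.time_s)
    rate = 1.0 / np.median(dt) if dt.size else rig.frame_rate_hz
    return EyeTrace(time_s=frames.time_s.copy(), position_deg=pos, sample_rate_hz=rate)
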