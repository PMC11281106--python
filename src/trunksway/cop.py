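"""Rotation-vector stream -> centered COP-projection trace in millimetres.

Quaternions are decomposed into intrinsic z-y'-x'' Euler angles; pitch
(rotation about the mediolateral axis) maps to anterior-posterior
displacement and roll (about the anteroposterior axis) to mediolateral
displacement via a lever arm: ``cop = lever_mm * tan(angle)``. Angles are
median-centered first so the reference posture sits at the origin. Samples
outside the admissible sway ellipse (AP radius 25 mm, ML radius 18 mm by
default) are excised.

All mm-scale outputs are conditional on the lever arm; the default 500 mm is
a plausible sternum-to-seat moment arm and is always config-visible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

DEFAULT_LEVER_MM = 500.0
GIMBAL_LOCK_MARGIN_DEG = 0.1


class EmptyTraceError(ValueError):
    """Every sample was removed."""


@dataclass(frozen=True)
class EulerAngles:
    """Euler-angle series in degrees, with gimbal-lock flags.

    pitch: about the mediolateral axis, + = forward lean;
    roll: about the anteroposterior axis, + = right lean;
    yaw: unused downstream but kept for completeness.
    """

    pitch: np.ndarray
    roll: np.ndarray
    yaw: np.ndarray
    flagged: np.ndarray  # True where |pitch| is within 0.1 deg of gimbal lock

    @property
    def n_samples(self) -> int:
        return int(np.asarray(self.pitch).shape[0])


@dataclass(frozen=True)
class CopTrace:
    """Paired AP/ML displacement series in mm at a fixed rate.

    ``sample_index`` carries each sample's index on the original uniform
    session timeline, so that window bookkeeping survives excisions.
    """

    cop_ap: np.ndarray  # mm, anterior-posterior (COPx)
    cop_ml: np.ndarray  # mm, medial-lateral (COPy)
    rate_hz: float
    lever_mm: float
    sample_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        ap = np.asarray(self.cop_ap, dtype=float)
        ml = np.asarray(self.cop_ml, dtype=float)
        if ap.shape != ml.shape:
            raise ValueError("cop_ap and cop_ml must have equal length")
        object.__setattr__(self, "cop_ap", ap)
        object.__setattr__(self, "cop_ml", ml)
        if self.sample_index is None:
            object.__setattr__(self, "sample_index", np.arange(ap.size))
        else:
            object.__setattr__(
                self, "sample_index", np.asarray(self.sample_index, dtype=np.int64)
            )

    @property
    def n_samples(self) -> int:
        return int(self.cop_ap.size)

    def slice_by_index(self, start: int, stop: int) -> "CopTrace":
        """Samples whose original timeline index lies in [start, stop)."""
        m = (self.sample_index >= start) & (self.sample_index < stop)
        return dataclasses.replace(
            self,
            cop_ap=self.cop_ap[m],
            cop_ml=self.cop_ml[m],
            sample_index=self.sample_index[m],
        )


@dataclass(frozen=True)
class EllipseBounds:
    """Admissible sway ellipse semi-axes in mm."""

    ap_radius: float = 25.0
    ml_radius: float = 18.0

    def __post_init__(self) -> None:
        if self.ap_radius <= 0 or self.ml_radius <= 0:
            raise ValueError("ellipse radii must be positive")


def quaternion_to_euler(quat_wxyz: np.ndarray) -> EulerAngles:
    """Intrinsic z-y'-x'' (yaw-pitch-roll) decomposition in degrees.

    Input rows are (qw, qx, qy, qz); near-unit quaternions are renormalized.
    Samples with |pitch| within 0.1 degrees of gimbal lock are flagged for
    downstream exclusion rather than raising.
    """
    q = np.atleast_2d(np.asarray(quat_wxyz, dtype=float))
    norms = np.linalg.norm(q, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValueError("quaternions are not close to unit norm")
    q = q / norms[:, None]
    rot = Rotation.from_quat(q[:, [1, 2, 3, 0]])  # to scalar-last
    yaw, pitch, roll = rot.as_euler("ZYX", degrees=True).T
    flagged = np.abs(np.abs(pitch) - 90.0) < GIMBAL_LOCK_MARGIN_DEG
    return EulerAngles(pitch=pitch, roll=roll, yaw=yaw, flagged=flagged)


def center_angles(angles: EulerAngles) -> EulerAngles:
    """Subtract the median of each Euler angle (reference posture -> origin)."""
    if angles.n_samples == 0:
        raise ValueError("empty angle series")
    return EulerAngles(
        pitch=angles.pitch - np.median(angles.pitch),
        roll=angles.roll - np.median(angles.roll),
        yaw=angles.yaw - np.median(angles.yaw),
        flagged=angles.flagged,
    )


def angles_to_displacement(
    angles: EulerAngles,
    lever_mm: float = DEFAULT_LEVER_MM,
    rate_hz: float = 100.0,
    sample_index: np.ndarray | None = None,
) -> CopTrace:
    """Project centered angles onto the horizontal plane:
    ``cop_ap = lever * tan(pitch)``, ``cop_ml = lever * tan(roll)``.

    Linear in the lever arm, and ~linear in the angle for small sway.
    """
    if lever_mm <= 0:
        raise ValueError("lever_mm must be positive")
    if np.any(np.abs(angles.pitch) >= 90) or np.any(np.abs(angles.roll) >= 90):
        raise ValueError("angles at or beyond 90 degrees cannot be projected")
    return CopTrace(
        cop_ap=lever_mm * np.tan(np.deg2rad(angles.pitch)),
        cop_ml=lever_mm * np.tan(np.deg2rad(angles.roll)),
        rate_hz=rate_hz,
        lever_mm=lever_mm,
        sample_index=sample_index,
    )


def ellipse_clip(
    trace: CopTrace, bounds: EllipseBounds = EllipseBounds()
) -> tuple[CopTrace, float]:
    """Keep samples inside (or on) the admissible ellipse; excise the rest.

    Returns the clipped trace and the removed fraction. Excision (not
    interpolation) keeps only admissible sway but breaks time continuity — a
    known caveat for the fractal measures downstream.
    """
    r = (trace.cop_ap / bounds.ap_radius) ** 2 + (trace.cop_ml / bounds.ml_radius) ** 2
    keep = r <= 1.0 + 1e-12  # boundary inclusive
    if not keep.any():
        raise EmptyTraceError("all samples fall outside the ellipse")
    clipped = dataclasses.replace(
        trace,
        cop_ap=trace.cop_ap[keep],
        cop_ml=trace.cop_ml[keep],
        sample_index=trace.sample_index[keep],
    )
    return clipped, float(1.0 - keep.mean())
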