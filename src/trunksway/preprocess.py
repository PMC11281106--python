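"""Accelerometer/rotation-vector preprocessing, activity removal, and
15-minute window segmentation.

The accelerometer pipeline runs, in order: 10 Hz low-pass -> gravity removal
-> mean detrending -> 150-sample moving average. Non-seated intervals
(walking, postural transitions) are detected where the acceleration magnitude
exceeds a threshold of 2 m/s^2, derived two independent ways: from reference
walking accelerations at C7 (|a| = sqrt(1.02^2 + 1.15^2 + 1.41^2) ~ 2.08) and
from the MET regression MET = 5.289*mag - 8.5548 evaluated at 3 METs
(mag = 2.18, ~2 after rounding). Detected intervals are removed from the
rotation-vector stream by identical sample indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .ingest import UniformStream


class SessionTooShortError(ValueError):
    """Fewer than three full windows in the session."""


@dataclass(frozen=True)
class ThresholdSpec:
    """Activity-threshold derivation constants (axis accelerations in m/s^2,
    MET regression slope in (m/s^2)/MET and intercept in m/s^2)."""

    walk_ax: float = 1.02
    walk_ay: float = 1.15
    walk_az: float = 1.41
    met_value: float = 3.0
    met_slope: float = 5.289
    met_intercept: float = 8.5548
    threshold: float = 2.0

    def kinematic_magnitude(self) -> float:
        return acceleration_magnitude(self.walk_ax, self.walk_ay, self.walk_az)

    def met_magnitude(self) -> float:
        return threshold_from_met(self.met_value, self.met_slope, self.met_intercept)


@dataclass
class LabeledWindow:
    """One 15-minute analysis window (half-open sample interval)."""

    label: str  # AM1.., Lunch, PM1..
    start_index: int
    end_index: int
    retained_mask: np.ndarray | None = None  # per-sample seated mask

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    @property
    def retained_fraction(self) -> float:
        if self.retained_mask is None:
            return 1.0
        return float(np.mean(self.retained_mask))

    @property
    def period(self) -> str:
        """AM / PM / Lunch aggregation bucket."""
        if self.label.startswith("AM"):
            return "AM"
        if self.label.startswith("PM"):
            return "PM"
        return "Lunch"


def _sos_lowpass(cutoff_hz: float, rate_hz: float, order: int) -> np.ndarray:
    if cutoff_hz >= rate_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist {rate_hz / 2} Hz"
        )
    return signal.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")


def lowpass_acc(
    stream: UniformStream, cutoff_hz: float = 10.0, order: int = 4
) -> UniformStream:
    """Zero-phase Butterworth low-pass (applied forward-backward) per channel.

    DC passes with unit gain; content above the cutoff is attenuated without
    introducing phase lag.
    """
    sos = _sos_lowpass(cutoff_hz, stream.rate_hz, order)
    out = signal.sosfiltfilt(sos, stream.values, axis=0)
    return stream.with_values(out)


def remove_gravity(
    stream: UniformStream, gravity_cutoff_hz: float = 0.3, order: int = 2
) -> UniformStream:
    """Subtract a slowly-varying gravity estimate per axis.

    Gravity is estimated as the sub-``gravity_cutoff_hz`` component of each
    axis (zero-phase low-pass), which tracks slow posture drift; a static
    recording maps to ~0 on all axes.
    """
    sos = _sos_lowpass(gravity_cutoff_hz, stream.rate_hz, order)
    grav = signal.sosfiltfilt(sos, stream.values, axis=0)
    return stream.with_values(stream.values - grav)


def detrend_mean(series: np.ndarray) -> np.ndarray:
    """Subtract the signal mean from each sample."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    return series - series.mean(axis=0)


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use shrinking (clipped) windows.

    Even window lengths are incremented to the next odd value so the window
    stays centered (no phase lag); output length equals input length.
    Works on 1-D series or (n, c) arrays columnwise.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        window += 1
    x = np.asarray(series, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    n = x.shape[0]
    half = window // 2
    csum = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return out[:, 0] if one_d else out


def acceleration_magnitude(x, y, z):
    """Euclidean norm of the three acceleration axes (m/s^2)."""
    return np.sqrt(np.square(x) + np.square(y) + np.square(z))


def threshold_from_met(
    met: float, slope: float = 5.289, intercept: float = 8.5548
) -> float:
    """Invert the MET regression: magnitude = (MET + intercept) / slope."""
    if slope == 0:
        raise ValueError("slope must be nonzero")
    return (met + intercept) / slope


def preprocess_accelerometer(
    stream: UniformStream,
    lowpass_cutoff_hz: float = 10.0,
    gravity_cutoff_hz: float = 0.3,
    smooth_samples: int = 150,
) -> UniformStream:
    """Full accelerometer chain: low-pass, gravity removal, mean detrend,
    moving-average smoothing. The order is part of the contract."""
    s = lowpass_acc(stream, lowpass_cutoff_hz)
    s = remove_gravity(s, gravity_cutoff_hz)
    s = s.with_values(detrend_mean(s.values))
    return s.with_values(moving_average(s.values, smooth_samples))


def smooth_rotation_vector(stream: UniformStream, smooth_samples: int = 5) -> UniformStream:
    """Moving-average smoothing of the quaternion components (then
    renormalized to unit quaternions)."""
    vals = moving_average(stream.values, smooth_samples)
    norms = np.linalg.norm(vals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return stream.with_values(vals / norms)


def detect_nonseated(
    mag: np.ndarray,
    threshold: float = 2.0,
    rate_hz: float = 100.0,
    guard_seconds: float = 0.5,
) -> list[tuple[int, int]]:
    """Half-open index intervals where the magnitude exceeds the threshold.

    Each maximal above-threshold run is dilated by ``guard_seconds`` on both
    sides (postural transitions bleed beyond the strict excursion);
    overlapping dilated runs merge. The complement is the retained seated
    signal.
    """
    mag = np.asarray(mag, dtype=float)
    if mag.size == 0:
        raise ValueError("empty magnitude series")
    above = mag > threshold
    if not above.any():
        return []
    guard = int(round(guard_seconds * rate_hz))
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        s = max(0, int(s) - guard)
        e = min(mag.size, int(e) + guard)
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def retained_mask(n_samples: int, intervals: list[tuple[int, int]]) -> np.ndarray:
    """Boolean seated mask: True outside all removal intervals."""
    mask = np.ones(n_samples, dtype=bool)
    for s, e in intervals:
        mask[s:e] = False
    return mask


def segment_windows(
    n_samples: int, rate_hz: float, window_minutes: float = 15.0
) -> list[LabeledWindow]:
    """Tile the session into consecutive full windows and label them.

    The central window (index ``n_windows // 2``) and its two neighbours are
    labelled ``Lunch``; earlier windows are ``AM1..AMk`` (AM1 earliest) and
    later ones ``PM1..PMm`` (PM1 first after lunch). A trailing partial
    window is discarded. Requires at least three full windows.
    """
    win = int(round(window_minutes * 60 * rate_hz))
    n_windows = n_samples // win
    if n_windows < 3:
        raise SessionTooShortError(
            f"session has {n_windows} full windows; at least 3 required"
        )
    center = n_windows // 2
    lunch = {center - 1, center, center + 1} & set(range(n_windows))
    windows = []
    for i in range(n_windows):
        if i in lunch:
            label = "Lunch"
        elif i < center:
            label = f"AM{i + 1}"
        else:
            label = f"PM{i - max(lunch)}"
        windows.append(LabeledWindow(label, i * win, (i + 1) * win))
    return windows
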