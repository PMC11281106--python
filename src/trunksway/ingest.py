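"""Raw sensor-stream ingestion, common-interval cropping, and uniform resampling.

Chest-worn smartphone sensors start and stop at slightly different times and
deliver irregularly spaced samples (battery throttling). Before any signal
processing, all streams are cropped to the interval every sensor covers and
linearly resampled onto a shared constant-rate time axis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

NS_PER_S = 1_000_000_000

#: canonical channel ordering per sensor kind, matching the CSV dialect
SENSOR_CHANNELS: dict[str, tuple[str, ...]] = {
    "accelerometer": ("x", "y", "z"),
    "gyroscope": ("x", "y", "z"),
    "magnetometer": ("x", "y", "z"),
    "rotation_vector": ("qw", "qx", "qy", "qz"),
}


class NonOverlapError(ValueError):
    """Streams share no common time interval."""


class InsufficientDataError(ValueError):
    """Too few samples for the requested operation."""


@dataclass(frozen=True)
class SensorStream:
    """One sensor's timestamped multichannel series.

    Timestamps are integer nanoseconds (Android sensor convention) and must be
    strictly increasing; duplicate timestamps should be removed with
    :meth:`from_raw` (first occurrence wins).
    """

    sensor_kind: str
    timestamps_ns: np.ndarray  # int64, strictly increasing
    channels: tuple[str, ...]
    values: np.ndarray  # (n_samples, n_channels) float64
    nominal_rate_hz: float

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps_ns, dtype=np.int64)
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        if vals.shape[0] != ts.shape[0]:
            raise ValueError(
                f"values rows ({vals.shape[0]}) != timestamps ({ts.shape[0]})"
            )
        if vals.shape[1] != len(self.channels):
            raise ValueError("values columns do not match channel names")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps_ns", ts)
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_raw(
        cls,
        sensor_kind: str,
        timestamps_ns: np.ndarray,
        values: np.ndarray,
        nominal_rate_hz: float,
    ) -> "SensorStream":
        """Build a stream from possibly dirty raw data.

        Keeps the first occurrence of duplicated timestamps and sorts by time.
        """
        ts = np.asarray(timestamps_ns, dtype=np.int64)
        vals = np.atleast_2d(np.asarray(values, dtype=float))
        order = np.argsort(ts, kind="stable")
        ts, vals = ts[order], vals[order]
        keep = np.concatenate([[True], np.diff(ts) > 0])
        channels = SENSOR_CHANNELS.get(sensor_kind)
        if channels is None:
            channels = tuple(f"c{i}" for i in range(vals.shape[1]))
        return cls(sensor_kind, ts[keep], channels, vals[keep], nominal_rate_hz)

    @property
    def n_samples(self) -> int:
        return int(self.timestamps_ns.shape[0])

    @property
    def times_s(self) -> np.ndarray:
        return self.timestamps_ns.astype(float) / NS_PER_S

    @property
    def start_ns(self) -> int:
        return int(self.timestamps_ns[0])

    @property
    def stop_ns(self) -> int:
        return int(self.timestamps_ns[-1])


@dataclass(frozen=True)
class UniformStream(SensorStream):
    """A sensor stream on a constant-interval time axis."""

    rate_hz: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    def with_values(self, values: np.ndarray) -> "UniformStream":
        """Return a copy carrying new channel values on the same time axis."""
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))


def crop_to_common_interval(streams: list[SensorStream]) -> list[SensorStream]:
    """Crop every stream to [max(start), min(stop)] across streams.

    The analysis interval starts at the initial timestamp of the last sensor
    to begin acquisition and ends at the final timestamp of the first sensor
    to stop. Samples outside are dropped; within-stream order is preserved.
    """
    if not streams:
        raise ValueError("need at least one stream")
    for s in streams:
        if s.n_samples == 0:
            raise InsufficientDataError(f"{s.sensor_kind}: empty stream")
    start = max(s.start_ns for s in streams)
    stop = min(s.stop_ns for s in streams)
    if start > stop:
        raise NonOverlapError(
            f"streams do not overlap: max start {start} > min stop {stop}"
        )
    out = []
    for s in streams:
        mask = (s.timestamps_ns >= start) & (s.timestamps_ns <= stop)
        out.append(
            dataclasses.replace(
                s, timestamps_ns=s.timestamps_ns[mask], values=s.values[mask]
            )
        )
    return out


def resample_uniform(stream: SensorStream, rate_hz: float) -> UniformStream:
    """Linearly interpolate each channel onto a constant 1/rate time axis.

    The new axis starts at the stream's first timestamp and never extends past
    its last (no extrapolation). Rotation-vector channels are renormalized to
    unit quaternions after componentwise interpolation; sway angles are small,
    so renormalized linear interpolation is indistinguishable from slerp.
    """
    if stream.n_samples < 2:
        raise InsufficientDataError("resampling requires at least 2 samples")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    step_ns = NS_PER_S / rate_hz
    span = stream.stop_ns - stream.start_ns
    n_out = int(np.floor(span / step_ns)) + 1
    # integer-indexed axis avoids cumulative float drift over multi-hour runs
    new_ts = stream.start_ns + np.round(np.arange(n_out) * step_ns).astype(np.int64)
    new_ts = new_ts[new_ts <= stream.stop_ns]
    t_old = stream.timestamps_ns.astype(float)
    t_new = new_ts.astype(float)
    vals = np.empty((t_new.size, len(stream.channels)))
    for j in range(len(stream.channels)):
        vals[:, j] = np.interp(t_new, t_old, stream.values[:, j])
    if stream.sensor_kind == "rotation_vector":
        norms = np.linalg.norm(vals, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        vals = vals / norms
    return UniformStream(
        sensor_kind=stream.sensor_kind,
        timestamps_ns=new_ts,
        channels=stream.channels,
        values=vals,
        nominal_rate_hz=stream.nominal_rate_hz,
        rate_hz=rate_hz,
    )


def read_sensor_csv(path: str | Path, sensor_kind: str, nominal_rate_hz: float) -> SensorStream:
    """Read one sensor's CSV (``t_ns,<ch1>,<ch2>,...``; UTF-8, '.' decimals)."""
    df = pd.read_csv(path)
    if df.columns[0] != "t_ns":
        raise ValueError(f"{path}: first column must be 't_ns'")
    stream = SensorStream.from_raw(
        sensor_kind,
        df["t_ns"].to_numpy(np.int64),
        df.iloc[:, 1:].to_numpy(float),
        nominal_rate_hz,
    )
    expected = SENSOR_CHANNELS.get(sensor_kind)
    if expected is not None and tuple(df.columns[1:]) != expected:
        raise ValueError(
            f"{path}: expected channels {expected}, found {tuple(df.columns[1:])}"
        )
    return stream


def write_sensor_csv(stream: SensorStream, path: str | Path) -> None:
    """Write a stream in the same CSV dialect ``read_sensor_csv`` accepts."""
    df = pd.DataFrame(stream.values, columns=list(stream.channels))
    df.insert(0, "t_ns", stream.timestamps_ns)
    df.to_csv(path, index=False)
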