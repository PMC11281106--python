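"""Linear variability measures of the COP trace.

Per-direction statistical and temporal features (max, min, mean, SD,
variance, RMS, IQR, zero-lag autocorrelation, travelled signal distance) and
joint postural-sway metrics (sway area, ranges, path, RMS distance, mean
sway velocity) with the conventional definitions:

    sway area           0.5 * |sum_n (X_{n+1} Y_n - X_n Y_{n+1})|   (shoelace)
    sway range          sqrt(range(X)^2 + range(Y)^2)
    sway path           sum_n sqrt(dX_n^2 + dY_n^2)
    sway distance RMS   sqrt(mean(X^2 + Y^2))
    mean sway velocity  (fs / N) * sway path

The literal signed, un-halved sway-area sum is available via
``sway_area_raw=True`` (it is double the enclosed area and carries an
orientation sign).
"""

from __future__ import annotations

import numpy as np

from .cop import CopTrace


class InsufficientDataError(ValueError):
    pass


def statistical_features(series: np.ndarray) -> dict[str, float]:
    """Statistical-domain features of one direction's series.

    SD and variance use the sample (N-1) denominator; quartiles use linear
    interpolation.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 4:
        raise InsufficientDataError("need at least 4 samples")
    q1, q3 = np.percentile(y, [25, 75])
    return {
        "maximum": float(y.max()),
        "minimum": float(y.min()),
        "mean": float(y.mean()),
        "sd": float(y.std(ddof=1)),
        "variance": float(y.var(ddof=1)),
        "rms": float(np.sqrt(np.mean(y**2))),
        "iqr": float(q3 - q1),
    }


def autocorr_zero_lag(series: np.ndarray) -> float:
    """Zero-lag self-correlation: sum of squares (equals N * RMS^2)."""
    y = np.asarray(series, dtype=float)
    return float(np.sum(y**2))


def signal_distance(series: np.ndarray) -> float:
    """Travelled distance of the time series: sum_n sqrt(1 + dy_n^2)."""
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise InsufficientDataError("need at least 2 samples")
    return float(np.sum(np.sqrt(1.0 + np.diff(y) ** 2)))


def sway_metrics(trace: CopTrace, sway_area_raw: bool = False) -> dict[str, float]:
    """Joint sway metrics of the paired AP/ML trace (units mm, mm^2, mm/s)."""
    x = trace.cop_ap
    y = trace.cop_ml
    n = x.size
    if n < 3:
        raise InsufficientDataError("need at least 3 samples")
    cross = x[1:] * y[:-1] - x[:-1] * y[1:]
    shoelace = float(np.sum(cross))
    area = shoelace if sway_area_raw else 0.5 * abs(shoelace)
    rng_ap = float(x.max() - x.min())
    rng_ml = float(y.max() - y.min())
    path = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
    return {
        "sway_area": area,
        "sway_range": float(np.hypot(rng_ap, rng_ml)),
        "sway_range_ap": rng_ap,
        "sway_range_ml": rng_ml,
        "sway_path": path,
        "sway_distance_rms": float(np.sqrt(np.mean(x**2 + y**2))),
        "mean_sway_velocity": trace.rate_hz / n * path,
    }


def linear_feature_rows(trace: CopTrace, sway_area_raw: bool = False) -> list[dict]:
    """Tidy rows (direction, feature, value) for one window's trace."""
    rows: list[dict] = []
    for direction, series in (("AP", trace.cop_ap), ("ML", trace.cop_ml)):
        feats = statistical_features(series)
        feats["autocorrelation"] = autocorr_zero_lag(series)
        feats["signal_distance"] = signal_distance(series)
        rows.extend(
            {"direction": direction, "feature": k, "value": v}
            for k, v in feats.items()
        )
    rows.extend(
        {"direction": "joint", "feature": k, "value": v}
        for k, v in sway_metrics(trace, sway_area_raw).items()
    )
    return rows
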