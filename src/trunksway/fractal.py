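"""Multifractal detrended fluctuation analysis, the singularity spectrum,
and sample entropy.

MFDFA (Kantelhardt's formulation): the profile (cumulative sum of the
mean-subtracted series) is split into non-overlapping segments of length
``s`` taken from both ends, each segment is detrended with a polynomial fit,
and the order-``q`` fluctuation function

    F_q(s) = { mean_v [ F^2(v, s) ]^{q/2} }^{1/q}        (q != 0)
    F_0(s) = exp( 0.5 * mean_v ln F^2(v, s) )            (q  = 0)

scales as ``s^{H(q)}``; the generalized Hurst exponents H(q) are least-
squares slopes of log F_q against log s. The singularity spectrum follows by
Legendre transform: ``alpha = H(q) + q dH/dq``, ``f(alpha) = q (alpha -
H(q)) + 1``; its widths (total / left / right of the maximum) quantify the
degree of multifractality.

Sample entropy (Richman & Moorman): the negative log of the conditional
probability that templates matching within tolerance ``r`` (Chebyshev
distance, self-matches excluded) at length ``m`` also match at ``m+1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


class UndefinedEntropyError(ValueError):
    """No template matches at one of the two lengths; SampEn is undefined."""


@dataclass(frozen=True)
class MfdfaParams:
    """MFDFA configuration.

    Defaults follow the analysis protocol: q from -5 to 5 in 0.5 steps,
    scales from 5 samples to N/8 with 30 linearly spaced values, first-order
    (linear) segment detrending, and integration of the input into its
    profile.
    """

    q_grid: tuple[float, ...] = tuple(np.arange(-5.0, 5.01, 0.5))
    scale_min: int = 5
    scale_max: int | None = None  # None -> N // 8
    n_scales: int = 30
    detrend_order: int = 1
    integrate_input: bool = True

    def __post_init__(self) -> None:
        if self.scale_min < self.detrend_order + 2:
            raise ValueError("scale_min must be at least detrend_order + 2")
        if 0.0 not in [round(q, 9) for q in self.q_grid]:
            raise ValueError("q_grid must contain 0")


@dataclass(frozen=True)
class MfdfaResult:
    q_grid: np.ndarray
    scales: np.ndarray
    fq: np.ndarray  # (n_q, n_scales) fluctuation functions
    hq: np.ndarray  # generalized Hurst exponents H(q)
    fit_r2: np.ndarray

    def h_at(self, q: float) -> float:
        idx = np.argmin(np.abs(self.q_grid - q))
        if abs(self.q_grid[idx] - q) > 1e-9:
            raise KeyError(f"q={q} not on the q grid")
        return float(self.hq[idx])


@dataclass(frozen=True)
class MultifractalSpectrum:
    alpha: np.ndarray
    f_alpha: np.ndarray
    alpha0: float  # singularity strength at the spectrum maximum
    total_width: float
    positive_width: float  # alpha0 - min alpha (q > 0 branch)
    negative_width: float  # max alpha - alpha0 (q < 0 branch)
    degenerate: bool = False

    @property
    def spectrum_maximum(self) -> float:
        return self.alpha0


def _scales_for(n: int, params: MfdfaParams) -> np.ndarray:
    smax = params.scale_max if params.scale_max is not None else n // 8
    smax = min(smax, n // 4)
    if smax <= params.scale_min:
        raise ValueError("series too short for the requested scale range")
    scales = np.unique(
        np.round(np.linspace(params.scale_min, smax, params.n_scales)).astype(int)
    )
    return scales


def mfdfa(series: np.ndarray, params: MfdfaParams | None = None) -> MfdfaResult:
    """Run MFDFA on one series and return F_q(s) and H(q)."""
    params = params or MfdfaParams()
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = x.size
    if n < 8 * params.scale_min:
        raise ValueError(f"series too short: {n} < {8 * params.scale_min}")
    if params.integrate_input:
        profile = np.cumsum(x - x.mean())
    else:
        profile = x
    scales = _scales_for(n, params)
    q = np.asarray(params.q_grid, dtype=float)
    fq = np.empty((q.size, scales.size))
    for si, s in enumerate(scales):
        nseg = n // s
        # forward and backward segmentations
        segs = np.concatenate(
            [
                profile[: nseg * s].reshape(nseg, s),
                profile[n - nseg * s :].reshape(nseg, s),
            ]
        )
        t = np.arange(s, dtype=float)
        V = np.vander(t, params.detrend_order + 1)
        coef, *_ = np.linalg.lstsq(V, segs.T, rcond=None)
        resid = segs.T - V @ coef
        f2 = np.mean(resid**2, axis=0)
        f2 = np.maximum(f2, 1e-300)
        for qi, qv in enumerate(q):
            if abs(qv) < 1e-12:
                fq[qi, si] = np.exp(0.5 * np.mean(np.log(f2)))
            else:
                fq[qi, si] = np.mean(f2 ** (qv / 2.0)) ** (1.0 / qv)
    log_s = np.log(scales.astype(float))
    log_f = np.log(fq)
    hq = np.empty(q.size)
    r2 = np.empty(q.size)
    for qi in range(q.size):
        slope, intercept = np.polyfit(log_s, log_f[qi], 1)
        pred = slope * log_s + intercept
        ss_res = np.sum((log_f[qi] - pred) ** 2)
        ss_tot = np.sum((log_f[qi] - log_f[qi].mean()) ** 2)
        hq[qi] = slope
        r2[qi] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MfdfaResult(q_grid=q, scales=scales, fq=fq, hq=hq, fit_r2=r2)


def hq_by_scale_count(
    series: np.ndarray,
    params: MfdfaParams | None = None,
    counts: tuple[int, ...] = (5, 10, 15, 20, 25, 30),
) -> dict[int, np.ndarray]:
    """Robustness sweep: H(q) recomputed with 5, 10, ..., 30 scale values.

    The 30-scale result is the canonical output; the sweep documents how
    stable the exponents are to the scale-grid resolution.
    """
    import dataclasses as _dc

    params = params or MfdfaParams()
    out = {}
    for c in counts:
        out[c] = mfdfa(series, _dc.replace(params, n_scales=c)).hq
    return out


def multifractal_spectrum(result: MfdfaResult) -> MultifractalSpectrum:
    """Legendre transform of H(q) into the singularity spectrum and widths.

    The left (q > 0) width is ``alpha0 - min alpha`` and the right (q < 0)
    width ``max alpha - alpha0``; the total width is their sum. A
    non-monotone alpha(q) grid marks the spectrum degenerate (widths still
    reported from the extreme values).
    """
    q = result.q_grid
    if q.size < 5:
        raise ValueError("need at least 5 q values including 0")
    hq = result.hq
    dh = np.gradient(hq, q)
    alpha = hq + q * dh
    f_alpha = q * (alpha - hq) + 1.0
    i0 = int(np.argmin(np.abs(q)))
    alpha0 = float(alpha[i0])
    degenerate = bool(np.any(np.diff(alpha) > 1e-9))  # alpha should decrease in q
    if degenerate:
        warnings.warn(
            "non-monotone singularity strengths; spectrum may be degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    pos = alpha[q > 0]
    neg = alpha[q < 0]
    positive_width = float(alpha0 - pos.min()) if pos.size else 0.0
    negative_width = float(neg.max() - alpha0) if neg.size else 0.0
    return MultifractalSpectrum(
        alpha=alpha,
        f_alpha=f_alpha,
        alpha0=alpha0,
        total_width=positive_width + negative_width,
        positive_width=positive_width,
        negative_width=negative_width,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy configuration: embedding dimension and tolerance as a
    fraction of the series SD."""

    m: int = 4
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be positive")


def sample_entropy(series: np.ndarray, params: SampEnParams | None = None) -> float:
    """SampEn = -ln(A / B): A, B = template-pair counts at lengths m+1, m.

    Chebyshev distance with tolerance ``r * SD(series)``; self-matches are
    excluded. Raises :class:`UndefinedEntropyError` if either count is zero.
    """
    params = params or SampEnParams()
    x = np.asarray(series, dtype=float)
    m = params.m
    n = x.size
    if n < 10 * m:
        raise ValueError(f"series too short: {n} < {10 * m}")
    tol = params.r * x.std()
    n_templates = n - m  # same template count at both lengths
    emb_m = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    b = _pair_count(emb_m, tol)
    a = _pair_count(emb_m1, tol)
    if a == 0 or b == 0:
        raise UndefinedEntropyError(
            f"no template matches at length {'m+1' if a == 0 else 'm'}"
        )
    return float(-np.log(a / b))


def _pair_count(embedded: np.ndarray, tol: float) -> int:
    """Unordered template pairs (i < j) within Chebyshev distance tol."""
    tree = cKDTree(embedded)
    total = tree.count_neighbors(tree, tol, p=np.inf)
    return int((total - embedded.shape[0]) // 2)


def nonlinear_feature_rows(
    series_by_direction: dict[str, np.ndarray],
    mfdfa_params: MfdfaParams | None = None,
    sampen_params: SampEnParams | None = None,
    q_report: tuple[float, ...] = (-5.0, 0.0, 2.0, 4.5),
) -> list[dict]:
    """Tidy rows of the reported nonlinear measures per direction."""
    mfdfa_params = mfdfa_params or MfdfaParams()
    sampen_params = sampen_params or SampEnParams()
    rows: list[dict] = []
    for direction, series in series_by_direction.items():
        res = mfdfa(series, mfdfa_params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            spec = multifractal_spectrum(res)
        vals = {f"hq_{q:g}": res.h_at(q) for q in q_report}
        vals.update(
            {
                "total_width": spec.total_width,
                "positive_width": spec.positive_width,
                "negative_width": spec.negative_width,
                "spectrum_maximum": spec.spectrum_maximum,
            }
        )
        try:
            vals["sampen"] = sample_entropy(series, sampen_params)
        except UndefinedEntropyError:
            vals["sampen"] = np.nan
        rows.extend(
            {"direction": direction, "feature": k, "value": v}
            for k, v in vals.items()
        )
    return rows
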