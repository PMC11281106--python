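"""IAAFT surrogates and the 95%-interval significance test.

An IAAFT surrogate preserves a series' amplitude distribution exactly (every
surrogate is a permutation of the original values) and its power spectrum
approximately, while destroying any nonlinear temporal structure. Comparing
a fractal or entropy statistic on the original series against its value on
100 surrogates tells whether that structure is genuine: if the original
falls outside the central 95% interval of the surrogate distribution, the
series carries structure no linear Gaussian process (measured through a
static transform) reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


class SurrogateTestInvalidError(RuntimeError):
    """The statistic was undefined on too many surrogates."""


@dataclass(frozen=True)
class SurrogateOutcome:
    statistic_name: str
    original_value: float
    surrogate_values: np.ndarray
    ci_low: float
    ci_high: float
    outside: bool
    seed: int

    @property
    def n_surrogates(self) -> int:
        return int(self.surrogate_values.size)


def iaaft(series: np.ndarray, seed: int = 0, max_iter: int = 100) -> np.ndarray:
    """One iterated amplitude-adjusted Fourier-transform surrogate.

    Alternates between imposing the original Fourier amplitudes and
    rank-remapping onto the original value distribution, until the rank
    order stabilizes or ``max_iter`` iterations. The returned surrogate is
    an exact permutation of the input values.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 32:
        raise ValueError("need at least 32 samples")
    rng = np.random.default_rng(seed)
    sorted_vals = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    current = rng.permutation(x)
    prev_ranks = None
    for _ in range(max_iter):
        # impose the original spectrum, keep the current phases
        spec = np.fft.rfft(current)
        phases = np.angle(spec)
        current = np.fft.irfft(target_amp * np.exp(1j * phases), n=x.size)
        # impose the original amplitude distribution by rank remapping
        ranks = np.argsort(np.argsort(current))
        current = sorted_vals[ranks]
        if prev_ranks is not None and np.array_equal(ranks, prev_ranks):
            break
        prev_ranks = ranks
    return current


def surrogate_test(
    series: np.ndarray,
    statistic: Callable[[np.ndarray], float],
    statistic_name: str = "statistic",
    n_surrogates: int = 100,
    level: float = 0.95,
    seed: int = 0,
    max_iter: int = 100,
) -> SurrogateOutcome:
    """Percentile surrogate test of one statistic at the given level.

    The statistic is evaluated on the original series and on ``n_surrogates``
    IAAFT surrogates; ``outside`` is True when the original value falls
    outside the central ``level`` percentile interval. Surrogates on which
    the statistic raises are skipped; if more than 10% are undefined the
    test is invalid.
    """
    x = np.asarray(series, dtype=float)
    original = float(statistic(x))
    rng = np.random.default_rng(seed)
    values = []
    n_failed = 0
    for _ in range(n_surrogates):
        surr = iaaft(x, seed=int(rng.integers(2**31)), max_iter=max_iter)
        try:
            values.append(float(statistic(surr)))
        except Exception:
            n_failed += 1
    if n_failed > 0.1 * n_surrogates:
        raise SurrogateTestInvalidError(
            f"statistic undefined on {n_failed}/{n_surrogates} surrogates"
        )
    vals = np.asarray(values)
    tail = 100.0 * (1.0 - level) / 2.0
    ci_low, ci_high = np.percentile(vals, [tail, 100.0 - tail])
    return SurrogateOutcome(
        statistic_name=statistic_name,
        original_value=original,
        surrogate_values=vals,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        outside=bool(original < ci_low or original > ci_high),
        seed=seed,
    )
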