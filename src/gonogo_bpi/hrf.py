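"""Canonical double-gamma haemodynamic response function.

The kernel is the difference of two gamma densities,

    h(t) = g(t; 6, 1) - g(t; 16, 1) / 6,

peak delay 6 s, undershoot delay 16 s, peak:undershoot ratio 6, length
32 s, normalized so its continuous peak equals 1. Because the kernel is a
pure function of time, sampling it at any step dt and decimating gives
identical values at shared time points.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import optimize, stats

HRF_PEAK_DELAY_S = 6.0
HRF_UNDERSHOOT_DELAY_S = 16.0
HRF_RATIO = 6.0
HRF_LENGTH_S = 32.0

__all__ = ["double_gamma_hrf", "hrf_time_grid"]


def _raw(t: np.ndarray, peak_delay: float, undershoot_delay: float, ratio: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return stats.gamma.pdf(t, a=peak_delay) - stats.gamma.pdf(t, a=undershoot_delay) / ratio


@lru_cache(maxsize=None)
def _peak_value(peak_delay: float, undershoot_delay: float, ratio: float) -> float:
    # continuous maximum, located near (peak_delay - 1) s for unit scale
    res = optimize.minimize_scalar(
        lambda t: -_raw(t, peak_delay, undershoot_delay, ratio),
        bounds=(1.0, undershoot_delay),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(-res.fun)


def hrf_time_grid(dt: float, duration: float = HRF_LENGTH_S) -> np.ndarray:
    n = int(np.floor(duration / dt + 1e-9)) + 1
    return np.arange(n) * dt


def double_gamma_hrf(
    dt: float,
    duration: float = HRF_LENGTH_S,
    peak_delay: float = HRF_PEAK_DELAY_S,
    undershoot_delay: float = HRF_UNDERSHOOT_DELAY_S,
    ratio: float = HRF_RATIO,
) -> np.ndarray:
    """Sample the peak-normalized double-gamma kernel at step ``dt`` seconds.

    Parameters are the gamma shape parameters (unit scale), so the
    response peaks near ``peak_delay - 1`` seconds and shows a late
    negative undershoot. Raises ``ValueError`` for non-positive ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = hrf_time_grid(dt, duration)
    return _raw(t, peak_delay, undershoot_delay, ratio) / _peak_value(
        peak_delay, undershoot_delay, ratio
    )
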