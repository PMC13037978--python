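"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the sinusoid fit is
a plain linear least-squares projection, the frequency estimator uses the
three-term cosine recurrence, and the DTW oracle enumerates every monotone
warping path explicitly.
"""

from __future__ import annotations

import math

import numpy as np


def fit_sinusoid(t: np.ndarray, x: np.ndarray, omega: float) -> tuple[float, float]:
    """Least-squares fit ``x ~ amp * cos(omega*t + phase_deg)``.

    Returns ``(amp, phase_deg)`` with phase in (-180, 180].
    """
    A = np.column_stack([np.cos(omega * t), np.sin(omega * t)])
    (a, b), *_ = np.linalg.lstsq(A, x, rcond=None)
    amp = float(np.hypot(a, b))
    phase = -math.degrees(math.atan2(b, a))
    return amp, phase


def estimate_frequency(x: np.ndarray, fs: float) -> float:
    """Frequency (rad/s) of a pure sampled sinusoid via the exact identity
    ``x[n+1] + x[n-1] = 2 cos(w/fs) x[n]``."""
    num = float(np.sum(x[1:-1] * (x[2:] + x[:-2])))
    den = 2.0 * float(np.sum(x[1:-1] ** 2))
    return math.acos(max(-1.0, min(1.0, num / den))) * fs


def brute_force_dtw(x, y, squared: bool = False) -> float:
    """Minimum accumulated cost over an explicit enumeration of every
    monotone path from (0,0) to (N-1,M-1).  Exponential; tiny inputs only."""
    n, m = len(x), len(y)

    def cost(i, j):
        d = x[i] - y[j]
        return d * d if squared else abs(d)

    best = [math.inf]

    def walk(i, j, acc):
        acc += cost(i, j)
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def monotone_warp_resample(x: np.ndarray, strength: float = 0.3) -> np.ndarray:
    """Resample ``x`` through a smooth strictly monotone time warp
    ``u -> u + strength * sin(pi * u) * (1 - u) * u`` on [0, 1]."""
    n = len(x)
    u = np.linspace(0.0, 1.0, n)
    w = u + strength * np.sin(np.pi * u) * u * (1.0 - u)
    w = (w - w[0]) / (w[-1] - w[0])
    return np.interp(w, u, x)
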