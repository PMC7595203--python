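"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: the stepping-curve
fit oracle is a dense grid search + golden-section refinement of the
least-squares objective, and the paired-t p-value oracle integrates the
Student t density numerically from its Gamma-function definition.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def lsq_stepping_oracle(intensities: np.ndarray, n_grid: int = 4096, refine_iters: int = 70):
    """Brute-force least-squares fit of ``a0 + a1*cos(theta_k + phi)``.

    Scans ``phi`` over a dense grid (solving the 2x2 linear system for
    ``a0, a1`` at each), then refines the minimum by golden-section search.
    Returns ``(a0, a1, phi)`` with ``a1 >= 0`` and ``phi`` in (-pi, pi].
    """
    I = np.asarray(intensities, dtype=np.float64)
    M = len(I)
    theta = 2.0 * np.pi * np.arange(M) / M

    def solve(phis):
        phis = np.atleast_1d(phis)
        c = np.cos(theta[None, :] + phis[:, None])
        S1 = c.sum(axis=1)
        S2 = (c * c).sum(axis=1)
        Sy = I.sum()
        Syc = (I[None, :] * c).sum(axis=1)
        det = M * S2 - S1 * S1
        a0 = (S2 * Sy - S1 * Syc) / det
        a1 = (M * Syc - S1 * Sy) / det
        resid = I[None, :] - a0[:, None] - a1[:, None] * c
        return (resid * resid).sum(axis=1), a0, a1

    phis = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    sse, _, _ = solve(phis)
    i = int(np.argmin(sse))
    width = 2.0 * np.pi / n_grid
    a, b = phis[i] - width, phis[i] + width
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    c1, c2 = b - gr * (b - a), a + gr * (b - a)
    f1, f2 = solve(c1)[0][0], solve(c2)[0][0]
    for _ in range(refine_iters):
        if f1 < f2:
            b, c2, f2 = c2, c1, f1
            c1 = b - gr * (b - a)
            f1 = solve(c1)[0][0]
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + gr * (b - a)
            f2 = solve(c2)[0][0]
    phi = 0.5 * (a + b)
    _, a0, a1 = solve(phi)
    a0, a1 = float(a0[0]), float(a1[0])
    if a1 < 0:
        a1, phi = -a1, phi + np.pi
    phi = float(np.mod(phi + np.pi, 2.0 * np.pi) - np.pi)
    if phi == -np.pi:
        phi = np.pi
    return a0, a1, phi


def paired_t_p_oracle(x, y) -> float:
    """Two-sided paired-t p-value by numerical integration of the t density."""
    d = np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        return 1.0 if d.mean() == 0.0 else 0.0
    t = abs(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    lognorm = math.lgamma((df + 1) / 2.0) - math.lgamma(df / 2.0) - 0.5 * math.log(df * math.pi)
    norm = math.exp(lognorm)

    def pdf(u):
        return norm * (1.0 + u * u / df) ** (-(df + 1) / 2.0)

    tail, _ = quad(pdf, t, np.inf)
    return 2.0 * tail


def circular_diff(a, b):
    """Smallest absolute angular difference, modulo 2*pi."""
    d = np.mod(np.asarray(a) - np.asarray(b) + np.pi, 2.0 * np.pi) - np.pi
    return np.abs(d)
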