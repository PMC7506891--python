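"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by explicit summation /
enumeration, deliberately avoiding the package's own code paths.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


def dipole_gain_phasor(theta_deg: float, f: float, d: float,
                       v: float = 343.0) -> float:
    """Two-element delay-and-subtract response by explicit phasor summation."""
    # plane wave hitting mic A, then mic B after path difference d*cos(theta)
    tau = d * math.cos(math.radians(theta_deg)) / v
    phasor = 1.0 - cmath.exp(-2j * math.pi * f * tau)
    return abs(phasor)


def dft_coefficient(x: np.ndarray, k: int) -> complex:
    """Naive O(n^2) DFT coefficient."""
    n = len(x)
    return sum(x[i] * cmath.exp(-2j * math.pi * k * i / n) for i in range(n))


def autocorrelation_loop(x: np.ndarray, lag: int) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    if var == 0:
        return 0.0
    s = sum((x[i] - mu) * (x[i + lag] - mu) for i in range(n - lag))
    return s / ((n - lag) * var)


def c3_loop(x: np.ndarray, lag: int) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    terms = [x[i + 2 * lag] ** 2 * x[i + lag] * x[i]
             for i in range(n - 2 * lag)]
    return sum(terms) / len(terms)


def count_below_mean_loop(x: np.ndarray) -> int:
    x = np.asarray(x, dtype=float)
    mu = sum(x) / len(x)
    return sum(1 for v in x if v < mu)


def energy_ratio_loop(x: np.ndarray, n_segments: int, focus: int) -> float:
    x = np.asarray(x, dtype=float)
    segments = np.array_split(x, n_segments)
    total = sum(float(v) ** 2 for v in x)
    seg = segments[focus - 1]
    return sum(float(v) ** 2 for v in seg) / total


def ratio_beyond_loop(x: np.ndarray, r: float) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    mu = sum(x) / n
    sd = math.sqrt(sum((v - mu) ** 2 for v in x) / n)
    if sd == 0:
        return 0.0
    return sum(1 for v in x if abs(v - mu) > r * sd) / n


def mean_abs_change_loop(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    diffs = [abs(x[i + 1] - x[i]) for i in range(len(x) - 1)]
    return sum(diffs) / len(diffs)


def by_step_up_exhaustive(pvalues: np.ndarray, alpha: float,
                          arbitrary: bool = True) -> np.ndarray:
    """BY retained mask by explicitly testing every cut k."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    cm = sum(1.0 / i for i in range(1, m + 1)) if arbitrary else 1.0
    order = np.argsort(p, kind="stable")
    sp = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if sp[k - 1] <= k * alpha / (m * cm):
            k_star = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask


def simulate_ou(seed: int, n: int = 10000, mu: float = 3.0,
                theta: float = 0.5, sigma: float = 0.5,
                dt: float = 0.05) -> np.ndarray:
    """Euler-Maruyama Ornstein-Uhlenbeck path with fixed point at mu."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = mu
    for i in range(1, n):
        x[i] = (x[i - 1] + theta * (mu - x[i - 1]) * dt
                + sigma * math.sqrt(dt) * rng.standard_normal())
    return x


def simulate_bistable(seed: int, n: int = 50000, sigma: float = 0.6,
                      dt: float = 0.02) -> np.ndarray:
    """Euler-Maruyama path of dx = x(1 - x^2) dt + sigma dW (fixed points 0, +/-1)."""
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = 1.0
    for i in range(1, n):
        xi = x[i - 1]
        x[i] = xi + xi * (1 - xi * xi) * dt + sigma * math.sqrt(dt) * rng.standard_normal()
    return x
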