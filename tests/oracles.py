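"""Independent reference implementations used only by the test suite.

Everything here is deliberately written with a different algorithmic route
than the package (naive loops, tangent-space integration, exact spectral
synthesis) so the tests compare two independent paths.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Lorenz system and the Benettin largest-Lyapunov-exponent estimator
# ---------------------------------------------------------------------------

def lorenz_rhs(s: np.ndarray, sigma: float = 10.0, rho: float = 28.0,
               beta: float = 8.0 / 3.0) -> np.ndarray:
    x, y, z = s
    return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])


def rk4_step(f, s: np.ndarray, dt: float) -> np.ndarray:
    k1 = f(s)
    k2 = f(s + dt / 2 * k1)
    k3 = f(s + dt / 2 * k2)
    k4 = f(s + dt * k3)
    return s + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


def lorenz_trajectory(n: int, dt: float = 0.01,
                      transient: int = 2000) -> np.ndarray:
    """(n, 3) states on the attractor after discarding a transient."""
    s = np.array([1.0, 1.0, 20.0])
    for _ in range(transient):
        s = rk4_step(lorenz_rhs, s, dt)
    out = np.empty((n, 3))
    for i in range(n):
        s = rk4_step(lorenz_rhs, s, dt)
        out[i] = s
    return out


def benettin_lle(dt: float = 0.002, n_steps: int = 100000,
                 d0: float = 1e-8) -> float:
    """Largest Lyapunov exponent by repeated renormalization of a
    companion trajectory started d0 away (Benettin's classical scheme)."""
    s = np.array([1.0, 1.0, 20.0])
    for _ in range(5000):
        s = rk4_step(lorenz_rhs, s, dt)
    pert = s + d0 * np.array([1.0, 0.0, 0.0])
    acc = 0.0
    for _ in range(n_steps):
        s = rk4_step(lorenz_rhs, s, dt)
        pert = rk4_step(lorenz_rhs, pert, dt)
        d = float(np.linalg.norm(pert - s))
        acc += np.log(d / d0)
        pert = s + (pert - s) * (d0 / d)
    return acc / (n_steps * dt)


# ---------------------------------------------------------------------------
# Exact fractional Gaussian noise (Davies-Harte circulant embedding)
# ---------------------------------------------------------------------------

def fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary fGn increments with exact autocovariance
    gamma(k) = 0.5 (|k+1|^2H - 2|k|^2H + |k-1|^2H)."""
    k = np.arange(n + 1)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.maximum(np.fft.fft(row).real, 0.0)
    m = 2 * n
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    f = np.fft.fft(z * np.sqrt(lam / (2 * m)))
    return f.real[:n]


def fbm(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Fractional Brownian path: cumulative sum of exact fGn increments."""
    return np.cumsum(fgn(n, hurst, rng))


# ---------------------------------------------------------------------------
# Naive Higuchi curve-length algorithm (plain loops, no vectorization)
# ---------------------------------------------------------------------------

def higuchi_fd_naive(x, k_max: int) -> float:
    x = np.asarray(x, dtype=float)
    N = len(x)
    logs = []
    for k in range(1, k_max + 1):
        Lk = []
        for m in range(1, k + 1):
            n_int = (N - m) // k
            total = 0.0
            for i in range(1, n_int + 1):
                total += abs(x[m - 1 + i * k] - x[m - 1 + (i - 1) * k])
            Lk.append(total * (N - 1) / (n_int * k) / k)
        logs.append((np.log(k), np.log(np.mean(Lk))))
    lk, ll = np.array(logs).T
    return -float(np.polyfit(lk, ll, 1)[0])


# ---------------------------------------------------------------------------
# Brute-force divergence curve (independent of the package implementation)
# ---------------------------------------------------------------------------

def divergence_curve_naive(points: np.ndarray, theiler: int,
                           horizon: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean ln d(k) and the chosen neighbour of every point, via an
    explicit full pairwise loop."""
    T = len(points)
    nb = np.empty(T, dtype=int)
    for i in range(T):
        best, best_d = -1, np.inf
        for j in range(T):
            if abs(i - j) <= theiler:
                continue
            d = float(np.linalg.norm(points[i] - points[j]))
            if d < best_d:
                best, best_d = j, d
        nb[i] = best
    mean_log = np.empty(horizon + 1)
    for k in range(horizon + 1):
        vals = []
        for i in range(T):
            j = nb[i]
            if i + k < T and j + k < T:
                d = float(np.linalg.norm(points[i + k] - points[j + k]))
                vals.append(np.log(max(d, 1e-300)))
        mean_log[k] = float(np.mean(vals))
    return mean_log, nb
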