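"""Complexity of motor primitives via Higuchi's fractal dimension.

A 1-D series is resampled at coarseness k with k interleaved offsets; the
normalized curve length L(k) of a fractal series scales as k^(-D), and the
fractal dimension D — between 1 (smooth) and 2 (space-filling, e.g. white
noise) — is the negative slope of ln L(k) vs ln k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synergies import SynergySet

__all__ = ["HFDResult", "higuchi_fd", "higuchi_curve", "trial_hfd"]


@dataclass
class HFDResult:
    """Per-primitive Higuchi fractal dimension and the trial mean."""

    labels: list[str]
    hfd: np.ndarray
    mean: float
    k_max: int
    log_k: np.ndarray          # ln k, shared regression abscissa
    log_length: np.ndarray     # (n_primitives, k_max) ln L(k) per primitive


def higuchi_curve(series: np.ndarray, k_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized curve lengths L(k) for k = 1..k_max.

    L_m(k) = [ sum_{i=1}^{floor((N-m)/k)} |x(m+ik) - x(m+(i-1)k)| ]
             * (N-1) / (floor((N-m)/k) * k) / k
    with L(k) the mean over the k offsets m = 1..k.
    """
    x = np.asarray(series, dtype=float).ravel()
    N = x.size
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if N < 10 * k_max:
        raise ValueError(f"series length {N} < 10 * k_max = {10 * k_max}")
    if np.ptp(x) == 0:
        raise ValueError("constant series: complexity undefined")
    ks = np.arange(1, k_max + 1)
    L = np.empty(k_max)
    for k in ks:
        lengths = np.empty(k)
        for m in range(1, k + 1):
            n_int = (N - m) // k
            idx = m - 1 + np.arange(n_int + 1) * k
            dist = np.sum(np.abs(np.diff(x[idx])))
            lengths[m - 1] = dist * (N - 1) / (n_int * k) / k
        L[k - 1] = lengths.mean()
    return ks.astype(float), L


def higuchi_fd(series: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension: -slope of ln L(k) vs ln k.

    Lies in [1, 2] for finite non-constant series (up to small numerical
    tolerance); a straight line gives 1, Gaussian white noise approaches 2.
    """
    ks, L = higuchi_curve(series, k_max)
    slope = float(np.polyfit(np.log(ks), np.log(L), 1)[0])
    return -slope


def trial_hfd(syn: SynergySet, k_max: int = 64,
              mode: str = "per_primitive") -> HFDResult:
    """HFD of every motor primitive over the whole trial.

    mode "per_primitive" (default) evaluates each primitive on its
    full-trial concatenated-cycle series and averages across primitives;
    mode "cycle_average" evaluates the cycle-averaged primitives instead
    (a 200-point series needs a correspondingly smaller k_max).
    """
    if mode not in ("per_primitive", "cycle_average"):
        raise ValueError("mode must be 'per_primitive' or 'cycle_average'")
    if syn.n_cycles < 3:
        raise ValueError("primitives must span at least 3 cycles")
    labels = syn.labels or [f"synergy_{s + 1}" for s in range(syn.rank)]
    hfds, logL = [], []
    log_k = None
    for s in range(syn.rank):
        x = syn.mean_primitive(s) if mode == "cycle_average" else syn.H[s]
        try:
            ks, L = higuchi_curve(x, k_max)
        except ValueError as err:
            raise ValueError(f"synergy '{labels[s]}': {err}") from err
        log_k = np.log(ks)
        logL.append(np.log(L))
        hfds.append(-float(np.polyfit(log_k, np.log(L), 1)[0]))
    hfds = np.asarray(hfds)
    return HFDResult(labels=list(labels), hfd=hfds, mean=float(hfds.mean()),
                     k_max=k_max, log_k=log_k, log_length=np.asarray(logL))
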