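"""Local dynamic stability of motor primitives in the synergy space.

The short-term maximum Lyapunov exponent (sMLE) is estimated directly in
the rank-dimensional space spanned by the motor primitives: the state at
time k is the vector of primitive activations, so no delay-embedding
reconstruction (and no embedding-dimension or time-delay choice) is needed —
the factorization rank IS the state-space dimension.  For every point the
nearest neighbour outside a Theiler exclusion window is tracked forward,
and the sMLE is the least-squares slope of the mean logarithmic divergence
<ln d(k)> over a short fit window.  Lower sMLE means less locally unstable
primitives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synergies import SynergySet

__all__ = ["SynergyTrajectory", "DivergenceCurve", "build_trajectory",
           "divergence", "fit_smle"]

_LOG_FLOOR = 1e-300  # zero distances (exactly periodic input) stay finite

#: above this many points the O(T^2) distance matrix is computed in chunks
_CHUNK = 512


@dataclass
class SynergyTrajectory:
    """Trajectory in synergy space: row k = primitive activations at time k."""

    points: np.ndarray            # (T, M), M = factorization rank
    samples_per_cycle: int
    normalized: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be (T, M)")
        if self.points.shape[1] < 2:
            raise ValueError(
                "synergy space must be at least 2-D; a single primitive "
                "cannot support a divergence analysis — extract more "
                "synergies or check the rank selection")

    @property
    def T(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass
class DivergenceCurve:
    """Mean logarithmic divergence of initially nearest neighbours.

    mean_log_divergence[k] = <ln d(k)> over all neighbour pairs whose
    forward tracks are still inside the series at step k; n_pairs records
    how many contribute at each k.
    """

    horizon_samples: int
    mean_log_divergence: np.ndarray
    n_pairs: np.ndarray
    samples_per_cycle: int
    theiler_window: int
    fit_window: tuple[int, int] | None = None
    smle_per_sample: float | None = None
    smle_per_cycle: float | None = None
    pairs: np.ndarray | None = None  # (T, 2) chosen (i, nearest j) indices


def build_trajectory(syn: SynergySet) -> SynergyTrajectory:
    """Arrange the primitives as a trajectory, max-normalized per primitive.

    No time-delay reconstruction is performed: the coordinates are the
    motor primitives themselves and the dimension equals the factorization
    rank.
    """
    if syn.rank < 2:
        raise ValueError(
            "synergy space must be at least 2-D; a 1-D space cannot "
            "support a local-stability analysis")
    if syn.n_cycles < 3:
        raise ValueError("primitives must cover at least 3 gait cycles")
    pts = syn.H.T.copy()
    mx = pts.max(axis=0)
    mx[mx == 0] = 1.0
    pts /= mx
    return SynergyTrajectory(points=pts,
                             samples_per_cycle=syn.samples_per_cycle)


def divergence(traj: SynergyTrajectory, theiler_window: int | None = None,
               horizon: int | None = None) -> DivergenceCurve:
    """Track each point's nearest neighbour and average ln d(k).

    For each point i the nearest neighbour j minimizes the Euclidean
    distance subject to |i - j| > theiler_window (default: one gait cycle,
    so "infinitesimally close" pairs always lie on different cycles).
    Pairs whose tracks run past the end of the series are dropped from
    subsequent steps.
    """
    T = traj.T
    if theiler_window is None:
        theiler_window = traj.samples_per_cycle
    if theiler_window < 1:
        raise ValueError("theiler_window must be >= 1")
    if horizon is None:
        horizon = min(3 * traj.samples_per_cycle, T // 2)
    if horizon > T // 2:
        raise ValueError("horizon must not exceed T/2")
    if T - theiler_window < 2:
        raise ValueError("series too short for the Theiler window")

    pts = traj.points
    sq = np.sum(pts * pts, axis=1)
    neighbours = np.empty(T, dtype=np.intp)
    for start in range(0, T, _CHUNK):
        stop = min(start + _CHUNK, T)
        # squared Euclidean distances of this block against all points
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (pts[start:stop] @ pts.T)
        for i in range(start, stop):
            lo = max(0, i - theiler_window)
            hi = min(T, i + theiler_window + 1)
            d2[i - start, lo:hi] = np.inf
        neighbours[start:stop] = np.argmin(d2, axis=1)

    idx_i = np.arange(T)
    idx_j = neighbours
    if idx_i.size < 10:
        raise ValueError("fewer than 10 valid neighbour pairs at k = 0")

    mean_log = np.empty(horizon + 1)
    n_pairs = np.empty(horizon + 1, dtype=np.intp)
    for k in range(horizon + 1):
        keep = (idx_i + k < T) & (idx_j + k < T)
        n_pairs[k] = int(np.count_nonzero(keep))
        if n_pairs[k] == 0:
            mean_log[k] = np.nan
            continue
        diff = pts[idx_i[keep] + k] - pts[idx_j[keep] + k]
        d = np.linalg.norm(diff, axis=1)
        mean_log[k] = float(np.mean(np.log(np.maximum(d, _LOG_FLOOR))))
    if n_pairs[0] < 10:
        raise ValueError("fewer than 10 valid neighbour pairs at k = 0")

    return DivergenceCurve(horizon_samples=horizon,
                           mean_log_divergence=mean_log, n_pairs=n_pairs,
                           samples_per_cycle=traj.samples_per_cycle,
                           theiler_window=theiler_window,
                           pairs=np.column_stack([idx_i, idx_j]))


def fit_smle(curve: DivergenceCurve,
             fit_window: tuple[int, int] | None = None) -> DivergenceCurve:
    """Least-squares slope of <ln d(k)> over the fit window.

    Returns a copy of the curve with ``smle_per_sample`` (ln-units per
    sample) and ``smle_per_cycle`` (x samples_per_cycle) filled in.  The
    default window is the first half gait cycle, the conventional
    "short-term" horizon.
    """
    if fit_window is None:
        fit_window = (0, curve.samples_per_cycle // 2)
    k0, k1 = int(fit_window[0]), int(fit_window[1])
    if not 0 <= k0 < k1 <= curve.horizon_samples:
        raise ValueError("fit window must lie inside the computed horizon")
    if k1 - k0 + 1 < 5:
        raise ValueError("fit window must span at least 5 samples")
    ks = np.arange(k0, k1 + 1)
    ys = curve.mean_log_divergence[k0:k1 + 1]
    if np.any(curve.n_pairs[k0:k1 + 1] == 0) or np.any(~np.isfinite(ys)):
        raise ValueError("fit window contains undefined curve values")
    slope = float(np.polyfit(ks, ys, 1)[0])
    return DivergenceCurve(
        horizon_samples=curve.horizon_samples,
        mean_log_divergence=curve.mean_log_divergence,
        n_pairs=curve.n_pairs, samples_per_cycle=curve.samples_per_cycle,
        theiler_window=curve.theiler_window, fit_window=(k0, k1),
        smle_per_sample=slope,
        smle_per_cycle=slope * curve.samples_per_cycle,
        pairs=curve.pairs)
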