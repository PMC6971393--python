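"""Muscle-synergy extraction, rank selection, classification and FWHM.

The EMG cycle matrix V (muscles x time, cycles concatenated) is factorized
as V ~ W.H with non-negative motor modules W (muscles x rank) and motor
primitives H (rank x time) by multiplicative updates minimizing the squared
reconstruction error.  The factorization rank — the dimension of the synergy
space — is the smallest rank at which the reconstruction-R^2 curve has
flattened into a straight line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment

from .preprocess import CycleMatrix
from .synthetic_emg import ReferenceSynergies

__all__ = ["SynergySet", "FWHMResult", "nmf", "select_rank", "classify",
           "fwhm", "trial_fwhm"]

_EPS = 1e-12


@dataclass
class SynergySet:
    """Motor modules W, motor primitives H and factorization bookkeeping.

    H rows are scaled to maximum 1, with the compensating scale folded into
    the W columns, so primitives are directly comparable across synergies.
    ``samples_per_cycle`` is carried along for synergy-space trajectory
    construction downstream.
    """

    W: np.ndarray
    H: np.ndarray
    rank: int
    r2: float
    muscle_labels: list[str]
    samples_per_cycle: int
    n_cycles: int
    r2_curve: np.ndarray | None = None
    labels: list[str] | None = None
    restarts_used: int = 1
    seed: int | None = None
    rank_warning: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValueError("W and H must be non-negative")

    def primitive_cycles(self, s: int) -> np.ndarray:
        """Primitive ``s`` reshaped to (n_cycles, samples_per_cycle)."""
        return self.H[s].reshape(self.n_cycles, self.samples_per_cycle)

    def mean_primitive(self, s: int) -> np.ndarray:
        return self.primitive_cycles(s).mean(axis=0)


@dataclass
class FWHMResult:
    """Full width at half maximum per synergy: mean and sd over cycles."""

    labels: list[str]
    mean_points: np.ndarray
    sd_points: np.ndarray


def _r2(V: np.ndarray, W: np.ndarray, H: np.ndarray, sst: float) -> float:
    resid = V - W @ H
    return 1.0 - float(np.sum(resid * resid)) / sst


def _as_V(V) -> tuple[np.ndarray, int, int, list[str]]:
    if isinstance(V, CycleMatrix):
        return V.to_V(), V.n_points, V.n_cycles, list(V.muscle_labels)
    V = np.asarray(V, dtype=float)
    return V, V.shape[1], 1, [f"m{i}" for i in range(V.shape[0])]


def nmf(V, rank: int, n_restarts: int = 10, max_iter: int = 1000,
        tol: float = 1e-5, seed: int | None = 0, patience: int = 20) -> SynergySet:
    """Non-negative factorization V ~ W.H by multiplicative updates.

    The best of ``n_restarts`` random initializations by final R^2 is kept.
    A restart stops when the relative R^2 improvement over the last
    ``patience`` iterations falls below ``tol``, or at ``max_iter``.

    Parameters
    ----------
    V : CycleMatrix or ndarray (muscles x time)
        Non-negative input; cycles concatenated along time.
    rank : int
        Number of synergies to extract.
    """
    Vm, spc, n_cycles, muscle_labels = _as_V(V)
    if np.any(Vm < 0):
        raise ValueError("V must be non-negative")
    zero_rows = np.flatnonzero(Vm.sum(axis=1) == 0)
    if zero_rows.size:
        names = ", ".join(muscle_labels[i] for i in zero_rows)
        raise ValueError(f"all-zero muscle row(s): {names}")
    if not 1 <= rank <= Vm.shape[0]:
        raise ValueError("rank must be between 1 and n_muscles")

    sst = float(np.sum((Vm - Vm.mean()) ** 2))
    rng = np.random.default_rng(seed)
    scale = np.sqrt(Vm.mean() / rank)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        W = scale * rng.random((Vm.shape[0], rank)) + _EPS
        H = scale * rng.random((rank, Vm.shape[1])) + _EPS
        history: list[float] = []
        for _it in range(max_iter):
            H *= (W.T @ Vm) / (W.T @ W @ H + _EPS)
            W *= (Vm @ H.T) / (W @ (H @ H.T) + _EPS)
            r2 = _r2(Vm, W, H, sst)
            history.append(r2)
            if len(history) > patience and \
                    r2 - history[-1 - patience] < tol * max(abs(r2), _EPS):
                break
        r2 = history[-1]
        if best is None or r2 > best[0]:
            best = (r2, W, H, history)

    r2, W, H, history = best
    h_max = H.max(axis=1)
    h_max[h_max == 0] = 1.0
    H = H / h_max[:, None]
    W = W * h_max[None, :]
    return SynergySet(W=W, H=H, rank=rank, r2=r2, muscle_labels=muscle_labels,
                      samples_per_cycle=spc, n_cycles=n_cycles,
                      restarts_used=n_restarts, seed=seed,
                      meta={"r2_history": np.asarray(history)})


def select_rank(V, max_rank: int = 8, n_restarts: int = 10,
                plateau_mse: float = 1e-4, seed: int | None = 0,
                **nmf_kwargs) -> tuple[int, np.ndarray]:
    """Smallest rank at which the R^2 curve has become linear.

    The reconstruction R^2 is computed for ranks 1..``max_rank``
    (best-of-restarts, enforced non-decreasing).  For each candidate rank r
    a straight line is fit to the curve restricted to ranks r..max_rank; the
    smallest r whose fit mean-squared-error falls below ``plateau_mse`` is
    selected — at that point adding synergies only tracks noise.
    """
    Vm, *_ = _as_V(V)
    if max_rank > Vm.shape[0]:
        raise ValueError("max_rank must not exceed n_muscles")
    curve = np.empty(max_rank)
    for r in range(1, max_rank + 1):
        res = nmf(V, r, n_restarts=n_restarts, seed=seed, **nmf_kwargs)
        curve[r - 1] = res.r2
    curve = np.maximum.accumulate(curve)  # nesting: best-of-restarts monotone

    ranks = np.arange(1, max_rank + 1, dtype=float)
    for r in range(1, max_rank + 1):
        xs, ys = ranks[r - 1:], curve[r - 1:]
        if xs.size < 2:
            warnings.warn("R^2 plateau criterion never satisfied; "
                          "returning max_rank")
            return max_rank, curve
        coef = np.polyfit(xs, ys, 1)
        mse = float(np.mean((np.polyval(coef, xs) - ys) ** 2))
        if mse < plateau_mse:
            return r, curve
    warnings.warn("R^2 plateau criterion never satisfied; returning max_rank")
    return max_rank, curve


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def classify(syn: SynergySet, reference: ReferenceSynergies) -> SynergySet:
    """Label extracted synergies against the fundamental templates.

    Each synergy is compared with every reference synergy by the cosine
    similarity of the concatenated (unit-normalized) module and
    cycle-averaged primitive; labels are assigned one-to-one so that the
    total similarity is maximal.  Extra synergies beyond the reference set
    are labeled ``"combined"``.  The returned set is reordered into
    gait-phase order (fundamental labels first, combined last).
    """
    if list(reference.muscle_labels) != list(syn.muscle_labels):
        raise ValueError("muscle labels of synergy set and reference differ")
    n_ref = reference.n_synergies
    ref_feats, syn_feats = [], []
    ref_prim_grid = (np.arange(reference.n_points) + 0.5) / reference.n_points
    grid = (np.arange(syn.samples_per_cycle) + 0.5) / syn.samples_per_cycle
    for s in range(n_ref):
        mod = reference.modules[:, s]
        prim = np.interp(grid, ref_prim_grid, reference.primitives[s], period=1.0)
        ref_feats.append((_unit(mod), _unit(prim)))
    for s in range(syn.rank):
        syn_feats.append((_unit(syn.W[:, s]), _unit(syn.mean_primitive(s))))

    sim = np.zeros((syn.rank, n_ref))
    for i, (mw, mp) in enumerate(syn_feats):
        for j, (rw, rp) in enumerate(ref_feats):
            sim[i, j] = _cosine(np.concatenate([mw, mp]),
                                np.concatenate([rw, rp]))
    rows, cols = linear_sum_assignment(-sim)
    assigned = dict(zip(rows.tolist(), cols.tolist()))

    labels = ["combined"] * syn.rank
    for i, j in assigned.items():
        labels[i] = reference.labels[j]

    # gait-phase order: fundamental labels in reference order, combined
    # synergies after, ordered by the phase of their primitive peak
    def order_key(i: int) -> tuple[int, float]:
        if labels[i] != "combined":
            return (reference.labels.index(labels[i]), 0.0)
        peak = float(np.argmax(syn.mean_primitive(i))) / syn.samples_per_cycle
        return (n_ref, peak)

    order = sorted(range(syn.rank), key=order_key)
    return SynergySet(W=syn.W[:, order], H=syn.H[order], rank=syn.rank,
                      r2=syn.r2, muscle_labels=list(syn.muscle_labels),
                      samples_per_cycle=syn.samples_per_cycle,
                      n_cycles=syn.n_cycles, r2_curve=syn.r2_curve,
                      labels=[labels[i] for i in order],
                      restarts_used=syn.restarts_used, seed=syn.seed,
                      rank_warning=syn.rank_warning, meta=dict(syn.meta))


def _unit(x: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(x)
    return x / n if n > 0 else x


def fwhm(primitive_cycle: np.ndarray) -> int:
    """Full width at half maximum of one activation cycle, in points.

    The cycle minimum is subtracted first (offset invariance), then the
    points strictly above half of the resulting maximum are counted.
    """
    x = np.asarray(primitive_cycle, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("primitive cycle must be 1-D with length >= 3")
    x = x - x.min()
    peak = x.max()
    if peak == 0:
        raise ValueError("constant series: FWHM undefined")
    return int(np.count_nonzero(x > 0.5 * peak))


def trial_fwhm(syn: SynergySet, include_combined: bool = False) -> FWHMResult:
    """Per-synergy FWHM, cycle-by-cycle, averaged across cycles.

    Synergies labeled ``"combined"`` are excluded unless requested.
    """
    labels = syn.labels or [f"synergy_{s + 1}" for s in range(syn.rank)]
    keep = [s for s, lab in enumerate(labels)
            if include_combined or lab != "combined"]
    means, sds, out_labels = [], [], []
    for s in keep:
        widths = np.array([fwhm(c) for c in syn.primitive_cycles(s)], dtype=float)
        means.append(widths.mean())
        sds.append(widths.std(ddof=0))
        out_labels.append(labels[s])
    return FWHMResult(labels=out_labels, mean_points=np.asarray(means),
                      sd_points=np.asarray(sds))
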