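"""File formats and run configuration.

All on-disk formats are tab-delimited UTF-8 text with period decimal
separators; times are in seconds, EMG amplitudes unitless. One touchdown /
lift-off event stream describes a single limb, which is sufficient for
gait-cycle-normalized analyses.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EMGRecording",
    "GaitEvents",
    "FormatError",
    "read_emg",
    "write_emg",
    "read_events",
    "write_events",
    "default_config",
    "read_config",
    "write_metrics",
]


class FormatError(ValueError):
    """Malformed input file or inconsistent event sequence."""


@dataclass
class EMGRecording:
    """Multi-channel surface EMG trace.

    Attributes
    ----------
    samples : ndarray, shape (n_samples, n_muscles)
        Signal amplitudes, volts or arbitrary units.
    fs : float
        Sampling rate in Hz.
    muscle_labels : list of str
        Channel names, ordered as the columns of ``samples``.
    trial_id : str
    meta : dict
        Free-form provenance (e.g. generator parameters).
    """

    samples: np.ndarray
    fs: float
    muscle_labels: list[str]
    trial_id: str = "trial"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_samples, n_muscles)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.muscle_labels) != self.samples.shape[1]:
            raise ValueError("one label per muscle column required")
        if len(set(self.muscle_labels)) != len(self.muscle_labels):
            raise FormatError("duplicate muscle labels")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class GaitEvents:
    """Touchdown (TD) and lift-off (LO) times of one limb, in seconds.

    A gait cycle runs TD_i -> LO_i -> TD_{i+1}; stance is TD_i..LO_i and
    swing LO_i..TD_{i+1}.  Times must strictly alternate.
    """

    touchdowns: np.ndarray
    liftoffs: np.ndarray

    def __post_init__(self) -> None:
        self.touchdowns = np.asarray(self.touchdowns, dtype=float)
        self.liftoffs = np.asarray(self.liftoffs, dtype=float)
        if self.touchdowns.size == 0:
            raise FormatError("no touchdown events")
        if np.any(np.diff(self.touchdowns) <= 0) or np.any(np.diff(self.liftoffs) <= 0):
            raise FormatError("event times must be strictly increasing")
        n = min(self.touchdowns.size, self.liftoffs.size)
        td, lo = self.touchdowns[:n], self.liftoffs[:n]
        if np.any(lo <= td):
            raise FormatError("each lift-off must follow its touchdown")
        if np.any(self.touchdowns[1 : n + 1] <= lo[: self.touchdowns.size - 1]):
            raise FormatError("each touchdown must follow the previous lift-off")

    @property
    def n_cycles(self) -> int:
        """Number of complete TD -> LO -> TD cycles."""
        n = 0
        for i in range(self.touchdowns.size - 1):
            if i < self.liftoffs.size and self.touchdowns[i] < self.liftoffs[i] < self.touchdowns[i + 1]:
                n += 1
        return n

    def cycles(self) -> list[tuple[float, float, float]]:
        """(TD, LO, next TD) triplets for every complete cycle."""
        out = []
        for i in range(self.touchdowns.size - 1):
            if i < self.liftoffs.size and self.touchdowns[i] < self.liftoffs[i] < self.touchdowns[i + 1]:
                out.append((self.touchdowns[i], self.liftoffs[i], self.touchdowns[i + 1]))
        return out


# ---------------------------------------------------------------------------
# EMG files: first column time (s), one column per muscle, header row.
# ---------------------------------------------------------------------------

_MAX_DT_DEVIATION = 1e-3  # 0.1% of the mean step


def write_emg(rec: EMGRecording, path) -> None:
    df = pd.DataFrame(rec.samples, columns=rec.muscle_labels)
    df.insert(0, "time", rec.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_emg(path, trial_id: str | None = None) -> EMGRecording:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a time column plus at least one muscle")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    mean_dt = float(np.mean(dt))
    if mean_dt <= 0 or np.max(np.abs(dt - mean_dt)) > _MAX_DT_DEVIATION * mean_dt:
        raise FormatError(f"{path}: non-uniform time step (>0.1% deviation)")
    labels = [str(c) for c in df.columns[1:]]
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate muscle labels")
    tid = trial_id if trial_id is not None else str(path)
    return EMGRecording(df.iloc[:, 1:].to_numpy(dtype=float), fs=1.0 / mean_dt,
                        muscle_labels=labels, trial_id=tid)


# ---------------------------------------------------------------------------
# Gait-event files: two columns, event_type in {TD, LO} and time_s.
# ---------------------------------------------------------------------------

def write_events(ev: GaitEvents, path) -> None:
    rows = [("TD", t) for t in ev.touchdowns] + [("LO", t) for t in ev.liftoffs]
    rows.sort(key=lambda r: r[1])
    pd.DataFrame(rows, columns=["event_type", "time_s"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_events(path) -> GaitEvents:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise FormatError(f"{path}: no events")
    if list(df.columns[:2]) != ["event_type", "time_s"]:
        raise FormatError(f"{path}: expected columns event_type, time_s")
    bad = set(df["event_type"]) - {"TD", "LO"}
    if bad:
        raise FormatError(f"{path}: unknown event types {sorted(bad)}")
    df = df.sort_values("time_s", kind="stable")
    kinds = df["event_type"].to_numpy()
    times = df["time_s"].to_numpy(dtype=float)
    # alternation is enforced by the GaitEvents invariant after the split
    for i in range(len(kinds) - 1):
        if kinds[i] == kinds[i + 1]:
            raise FormatError(
                f"{path}: two consecutive {kinds[i]} events at "
                f"t={times[i]:g} and t={times[i + 1]:g}")
    return GaitEvents(touchdowns=times[kinds == "TD"], liftoffs=times[kinds == "LO"])


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Full default parameter tree covering every stage."""
    return {
        "synthetic": {
            "n_muscles": 13,
            "n_points": 200,
            "centers": [15.0, 40.0, 65.0, 90.0],
            "widths": [18.0, 18.0, 18.0, 18.0],
            "n_cycles": 30,
            "stance_ms": 689.0,
            "swing_ms": 393.0,
            "timing_jitter_sd_ms": 20.0,
            "fs": 2000.0,
            "variability": {
                "timing_jitter_sd": 1.0,
                "amplitude_jitter_sd": 0.1,
                "sdn_coeff": 0.05,
                "width_scale": 1.0,
                "noise_color": 0.0,
            },
        },
        "preprocess": {
            "apply_envelope": True,   # False for pre-enveloped inputs
            "band_hz": [50.0, 450.0],
            "lowpass_hz": 4.0,
            "filter_order": 4,
            "points_stance": 100,
            "points_swing": 100,
        },
        "synergies": {
            "rank": None,          # None -> select automatically
            "max_rank": 8,
            "n_restarts": 10,
            "max_iter": 1000,
            "tol": 1e-5,
            "patience": 20,
            "plateau_mse": 1e-4,
        },
        "dynamics": {
            "theiler_window": None,   # None -> samples per cycle
            "horizon": None,          # None -> min(3 cycles, T//2)
            "fit_window": None,       # None -> (0, samples_per_cycle//2)
        },
        "complexity": {
            "k_max": 64,
            "mode": "per_primitive",
        },
    }


def _check_keys(user: dict, ref: dict, prefix: str, unknown: list[str]) -> None:
    for k, v in user.items():
        if k not in ref:
            unknown.append(prefix + k)
        elif isinstance(v, dict) and isinstance(ref[k], dict):
            _check_keys(v, ref[k], prefix + k + ".", unknown)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def read_config(path=None) -> dict:
    """Load a YAML config, validate keys and fill defaults.

    An empty / absent file yields the full default tree; unknown keys raise
    with every offending dotted key named.
    """
    defaults = default_config()
    if path is None:
        return defaults
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise FormatError(f"{path}: config root must be a mapping")
    unknown: list[str] = []
    _check_keys(user, defaults, "", unknown)
    if unknown:
        raise FormatError(f"unknown config keys: {', '.join(sorted(unknown))}")
    return _merge(defaults, user)


def write_metrics(table: pd.DataFrame, path) -> None:
    """One row per trial; columns are the per-trial metric set."""
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")
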