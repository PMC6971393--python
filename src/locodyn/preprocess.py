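"""Raw EMG conditioning, gait-cycle segmentation and spatiotemporal parameters.

The envelope chain is the conventional one for locomotor surface EMG:
zero-lag band-pass (4th-order Butterworth, 50-450 Hz), full-wave
rectification, zero-lag low-pass (4 Hz).  Each gait cycle is then time
normalized so that stance and swing occupy the same number of points, and
every muscle is amplitude normalized to its trial maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_gait import EMGRecording, GaitEvents

__all__ = ["CycleMatrix", "SpatiotemporalResult", "envelope",
           "segment_normalize", "spatiotemporal"]


@dataclass
class CycleMatrix:
    """Cycle-segmented, phase- and amplitude-normalized envelopes.

    data : (n_cycles, n_muscles, n_points), non-negative; per-muscle maximum
        over all cycles and points is 1.  Index ``points_stance`` marks the
        stance-to-swing boundary in every cycle.
    cycle_durations : (n_cycles, 2) stance_ms, swing_ms per cycle.
    """

    data: np.ndarray
    points_stance: int
    points_swing: int
    muscle_labels: list[str]
    cycle_durations: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_cycles, n_muscles, n_points)")
        if self.data.shape[2] != self.points_stance + self.points_swing:
            raise ValueError("n_points must equal points_stance + points_swing")

    @property
    def n_cycles(self) -> int:
        return self.data.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.data.shape[1]

    @property
    def n_points(self) -> int:
        return self.data.shape[2]

    def to_V(self) -> np.ndarray:
        """Muscles x time matrix with cycles concatenated along time."""
        return self.data.transpose(1, 0, 2).reshape(self.n_muscles, -1)


@dataclass
class SpatiotemporalResult:
    """Per-trial gait parameters, mean and sd over cycles."""

    stance_ms: float
    stance_ms_sd: float
    swing_ms: float
    swing_ms_sd: float
    cadence_steps_per_min: float
    cadence_sd: float
    n_cycles: int


def envelope(raw: EMGRecording, band_hz=(50.0, 450.0), lowpass_hz: float = 4.0,
             order: int = 4) -> EMGRecording:
    """Linear envelope: zero-lag band-pass, rectify, zero-lag low-pass.

    Output is clipped at zero (forward-backward filtering can undershoot),
    so downstream non-negative factorization is well posed.
    """
    nyq = raw.fs / 2.0
    lo, hi = band_hz
    if hi >= nyq or lowpass_hz >= nyq:
        raise ValueError(f"filter edges must lie below Nyquist ({nyq:g} Hz)")
    if not 0 < lo < hi:
        raise ValueError("band edges must satisfy 0 < low < high")
    sos_band = signal.butter(order, (lo, hi), btype="bandpass", fs=raw.fs,
                             output="sos")
    sos_low = signal.butter(order, lowpass_hz, btype="lowpass", fs=raw.fs,
                            output="sos")
    x = signal.sosfiltfilt(sos_band, raw.samples, axis=0)
    x = np.abs(x)
    x = signal.sosfiltfilt(sos_low, x, axis=0)
    np.clip(x, 0.0, None, out=x)
    return EMGRecording(x, fs=raw.fs, muscle_labels=list(raw.muscle_labels),
                        trial_id=raw.trial_id, meta=dict(raw.meta))


def segment_normalize(env: EMGRecording, events: GaitEvents,
                      points_stance: int = 100,
                      points_swing: int = 100) -> CycleMatrix:
    """Segment into gait cycles and normalize time and amplitude.

    Stance is linearly resampled to ``points_stance`` points and swing to
    ``points_swing``; each muscle is then divided by its maximum over the
    whole trial.  Cycles with fewer than 4 samples in either phase are
    dropped with a warning.
    """
    cycles = events.cycles()
    if not cycles:
        raise ValueError("no complete TD->LO->TD cycle in the events")
    t = env.times
    rows, durations = [], []
    dropped = 0
    for td, lo, td_next in cycles:
        stance_idx = np.flatnonzero((t >= td) & (t < lo))
        swing_idx = np.flatnonzero((t >= lo) & (t < td_next))
        if stance_idx.size < 4 or swing_idx.size < 4:
            dropped += 1
            continue
        cyc = np.empty((env.n_muscles, points_stance + points_swing))
        grid_st = np.linspace(td, lo, points_stance, endpoint=False)
        grid_sw = np.linspace(lo, td_next, points_swing, endpoint=False)
        for m in range(env.n_muscles):
            cyc[m, :points_stance] = np.interp(grid_st, t[stance_idx],
                                               env.samples[stance_idx, m])
            cyc[m, points_stance:] = np.interp(grid_sw, t[swing_idx],
                                               env.samples[swing_idx, m])
        rows.append(cyc)
        durations.append(((lo - td) * 1000.0, (td_next - lo) * 1000.0))
    if dropped:
        warnings.warn(f"dropped {dropped} cycle(s) shorter than 4 samples per phase")
    if not rows:
        raise ValueError("all cycles were dropped")
    data = np.stack(rows)
    peak = data.max(axis=(0, 2), keepdims=True)
    peak[peak == 0] = 1.0
    data = data / peak
    return CycleMatrix(data=data, points_stance=points_stance,
                       points_swing=points_swing,
                       muscle_labels=list(env.muscle_labels),
                       cycle_durations=np.asarray(durations))


def spatiotemporal(events: GaitEvents) -> SpatiotemporalResult:
    """Stance/swing times and cadence (2 steps per gait cycle).

    cadence_c = 2 * 60000 / (stance_c + swing_c) steps/min, averaged over
    cycles.
    """
    cycles = events.cycles()
    if not cycles:
        raise ValueError("no complete gait cycle in the events")
    stance = np.array([(lo - td) * 1000.0 for td, lo, _ in cycles])
    swing = np.array([(td2 - lo) * 1000.0 for _, lo, td2 in cycles])
    cadence = 2.0 * 60000.0 / (stance + swing)
    return SpatiotemporalResult(
        stance_ms=float(stance.mean()), stance_ms_sd=float(stance.std(ddof=0)),
        swing_ms=float(swing.mean()), swing_ms_sd=float(swing.std(ddof=0)),
        cadence_steps_per_min=float(cadence.mean()),
        cadence_sd=float(cadence.std(ddof=0)), n_cycles=len(cycles))
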