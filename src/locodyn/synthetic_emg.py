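"""Synthetic locomotor EMG with planted synergy structure.

The generator is a forward model of the synergy factorization V ~ W.H: a
small set of non-negative motor modules (muscle weightings) and Gaussian-bump
motor primitives (one activation bump per gait phase) is mixed into
per-muscle activation envelopes, corrupted with signal-dependent noise, and
multiplied by a zero-mean band-limited carrier to emulate raw surface EMG.
Cycle-to-cycle variability (phase jitter, amplitude jitter, primitive
widening) is controllable so that every downstream stage — envelope
extraction, factorization, stability, complexity and width metrics — can be
exercised against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io_gait import EMGRecording, GaitEvents

__all__ = [
    "DEFAULT_MUSCLES",
    "DEFAULT_LABELS",
    "ReferenceSynergies",
    "VariabilityParams",
    "make_reference_synergies",
    "make_gait_events",
    "synthesize_trial",
    "make_condition_pair",
]

#: Lower-limb montage: gluteus medius, gluteus maximus, tensor fasciae
#: latae, rectus femoris, vastus medialis, vastus lateralis, semitendinosus,
#: biceps femoris, tibialis anterior, peroneus longus, gastrocnemius
#: medialis, gastrocnemius lateralis, soleus.
DEFAULT_MUSCLES = ["ME", "MA", "FL", "RF", "VM", "VL", "ST",
                   "BF", "TA", "PL", "GM", "GL", "SO"]

#: The four fundamental locomotor synergies, in gait-phase order.
DEFAULT_LABELS = ["weight_acceptance", "propulsion", "early_swing", "late_swing"]

# Dominant / secondary muscle loadings per fundamental synergy:
# weight acceptance -> knee extensors and glutei; propulsion ->
# plantarflexors; early swing -> foot dorsiflexors; late swing -> knee
# flexors and dorsiflexors.
_SYNERGY_MUSCLES = {
    "weight_acceptance": (["VM", "VL", "ME", "MA"], ["RF", "FL"]),
    "propulsion": (["SO", "GM", "GL"], ["PL"]),
    "early_swing": (["TA", "PL"], ["RF"]),
    "late_swing": (["ST", "BF", "TA"], ["ME"]),
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM/2.355


@dataclass
class ReferenceSynergies:
    """Ground-truth modules and primitives used to synthesize trials.

    modules : (n_muscles, n_synergies), non-negative, unit-norm columns.
    primitives : (n_synergies, n_points), non-negative, max 1 per row.
    centers / widths : bump center and FWHM per synergy, % of gait cycle.
    """

    modules: np.ndarray
    primitives: np.ndarray
    labels: list[str]
    centers: np.ndarray
    widths: np.ndarray
    muscle_labels: list[str] = field(default_factory=lambda: list(DEFAULT_MUSCLES))

    def __post_init__(self) -> None:
        self.modules = np.asarray(self.modules, dtype=float)
        self.primitives = np.asarray(self.primitives, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if np.any(self.modules < 0) or np.any(self.primitives < 0):
            raise ValueError("modules and primitives must be non-negative")
        if not np.allclose(self.primitives.max(axis=1), 1.0):
            raise ValueError("each primitive must have maximum 1")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("bump centers must be strictly increasing")

    @property
    def n_muscles(self) -> int:
        return self.modules.shape[0]

    @property
    def n_synergies(self) -> int:
        return self.modules.shape[1]

    @property
    def n_points(self) -> int:
        return self.primitives.shape[1]


@dataclass
class VariabilityParams:
    """Cycle-to-cycle variability and noise knobs.

    timing_jitter_sd : per-cycle circular phase shift sd, % of gait cycle.
    amplitude_jitter_sd : per-cycle multiplicative amplitude sd.
    sdn_coeff : signal-dependent noise coefficient; the envelope noise sd at
        any instant equals sdn_coeff times the instantaneous activation.
    width_scale : multiplicative widening of every primitive about its peak.
    noise_color : spectral exponent beta of the envelope noise (0 = white;
        the noise amplitude stays signal-dependent, only its spectrum tilts).
    seed : RNG seed; identical parameters and seed give identical trials.
    """

    timing_jitter_sd: float = 1.0
    amplitude_jitter_sd: float = 0.1
    sdn_coeff: float = 0.05
    width_scale: float = 1.0
    noise_color: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.timing_jitter_sd < 0 or self.amplitude_jitter_sd < 0
                or self.sdn_coeff < 0):
            raise ValueError("jitter sds and sdn_coeff must be >= 0")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be > 0")


def _gaussian_bump_circular(phase: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Gaussian bump on the circular phase axis [0, 1)."""
    d = np.abs(phase - center)
    d = np.minimum(d, 1.0 - d)
    return np.exp(-0.5 * (d / sigma) ** 2)


def make_reference_synergies(
    n_muscles: int = 13,
    n_points: int = 200,
    centers=(15.0, 40.0, 65.0, 90.0),
    widths=(18.0, 18.0, 18.0, 18.0),
    seed: int = 0,
    labels=None,
    muscle_labels=None,
) -> ReferenceSynergies:
    """Build the ground-truth synergy set.

    Primitives are circular Gaussian bumps centered at ``centers`` (% of the
    gait cycle) with full width at half maximum ``widths``; modules load the
    muscle groups characteristic of each locomotor phase, plus a small
    seeded baseline on the remaining muscles.
    """
    centers = np.asarray(centers, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if n_muscles < 1:
        raise ValueError("n_muscles must be >= 1")
    if n_points % 2:
        raise ValueError("n_points must be even (equal stance/swing halves)")
    if centers.shape != widths.shape:
        raise ValueError("centers and widths must have equal length")
    if np.any(widths <= 0):
        raise ValueError("widths must be positive")
    if np.any((centers <= 0) | (centers >= 100)):
        raise ValueError("centers must lie in (0, 100) % of the cycle")
    n_syn = centers.size
    if labels is None:
        labels = list(DEFAULT_LABELS[:n_syn]) if n_syn <= 4 else [
            f"synergy_{i + 1}" for i in range(n_syn)]
    if muscle_labels is None:
        muscle_labels = list(DEFAULT_MUSCLES) if n_muscles == 13 else [
            f"M{i + 1:02d}" for i in range(n_muscles)]

    phase = (np.arange(n_points) + 0.5) / n_points
    primitives = np.stack([
        _gaussian_bump_circular(phase, c / 100.0, (w / 100.0) * _FWHM_TO_SIGMA)
        for c, w in zip(centers, widths)
    ])
    primitives /= primitives.max(axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    modules = rng.uniform(0.02, 0.10, size=(n_muscles, n_syn))
    if muscle_labels == DEFAULT_MUSCLES and n_syn <= 4:
        idx = {m: i for i, m in enumerate(muscle_labels)}
        for s, lab in enumerate(labels):
            dominant, secondary = _SYNERGY_MUSCLES.get(lab, ([], []))
            for m in dominant:
                modules[idx[m], s] = rng.uniform(0.85, 1.0)
            for m in secondary:
                modules[idx[m], s] = rng.uniform(0.30, 0.45)
    else:
        # generic montage: block-wise dominance so every synergy owns a
        # distinct muscle group
        for m in range(n_muscles):
            s = (m * n_syn) // n_muscles
            modules[m, s] = rng.uniform(0.85, 1.0)
    modules /= np.linalg.norm(modules, axis=0, keepdims=True)

    return ReferenceSynergies(modules=modules, primitives=primitives,
                              labels=list(labels), centers=centers,
                              widths=widths, muscle_labels=list(muscle_labels))


def make_gait_events(
    n_cycles: int = 30,
    stance_ms: float = 689.0,
    swing_ms: float = 393.0,
    timing_jitter_sd_ms: float = 0.0,
    seed: int = 0,
) -> GaitEvents:
    """Alternating touchdown/lift-off times for ``n_cycles`` full cycles.

    Per-cycle stance and swing durations are drawn from normal distributions
    around the nominal values (truncated at 10% of nominal to stay positive);
    jitter 0 gives an exactly periodic sequence.
    """
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2")
    if stance_ms <= 0 or swing_ms <= 0:
        raise ValueError("stance_ms and swing_ms must be positive")
    if timing_jitter_sd_ms < 0:
        raise ValueError("timing jitter sd must be >= 0")
    rng = np.random.default_rng(seed)
    stances = stance_ms + timing_jitter_sd_ms * rng.standard_normal(n_cycles)
    swings = swing_ms + timing_jitter_sd_ms * rng.standard_normal(n_cycles)
    stances = np.maximum(stances, 0.1 * stance_ms) / 1000.0
    swings = np.maximum(swings, 0.1 * swing_ms) / 1000.0
    touchdowns = np.empty(n_cycles + 1)
    liftoffs = np.empty(n_cycles)
    t = 0.0
    for c in range(n_cycles):
        touchdowns[c] = t
        liftoffs[c] = t + stances[c]
        t += stances[c] + swings[c]
    touchdowns[n_cycles] = t
    return GaitEvents(touchdowns=touchdowns, liftoffs=liftoffs)


def _colored_noise(rng: np.random.Generator, n: int, beta: float) -> np.ndarray:
    """Unit-sd Gaussian noise with power spectrum ~ 1/f^beta."""
    white = rng.standard_normal(n)
    if beta == 0.0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-beta / 2.0)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_limited_carrier(rng: np.random.Generator, n: int, fs: float,
                          band=(20.0, 450.0)) -> np.ndarray:
    """Zero-mean unit-sd Gaussian noise band-limited to ``band`` Hz."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    return x / x.std()


def _cycle_phase(t: np.ndarray, td: float, lo: float, td_next: float) -> np.ndarray:
    """Map sample times inside one cycle to phase in [0, 1).

    Stance (TD..LO) occupies phase [0, 0.5), swing (LO..next TD) phase
    [0.5, 1), matching equal-point stance/swing time normalization.
    """
    phase = np.empty_like(t)
    stance = t < lo
    phase[stance] = 0.5 * (t[stance] - td) / (lo - td)
    phase[~stance] = 0.5 + 0.5 * (t[~stance] - lo) / (td_next - lo)
    return phase


def _primitive_value(ref: ReferenceSynergies, s: int, phase: np.ndarray,
                     shift: float, width_scale: float) -> np.ndarray:
    """Sample primitive ``s`` at circular phases, shifted and widened."""
    center = ref.centers[s] / 100.0
    # widen about the bump center; wrap circularly
    ph = (phase - shift) % 1.0
    d = ph - center
    d = (d + 0.5) % 1.0 - 0.5
    ph_eff = (center + d / width_scale) % 1.0
    template = ref.primitives[s]
    n = template.size
    grid = (np.arange(n) + 0.5) / n
    return np.interp(ph_eff, grid, template, period=1.0)


def synthesize_trial(
    ref: ReferenceSynergies,
    events: GaitEvents,
    var: VariabilityParams,
    fs: float = 2000.0,
    trial_id: str = "synthetic",
    carrier: bool = True,
) -> EMGRecording:
    """Forward-simulate a raw EMG trial from planted synergies.

    For each gait cycle the primitive templates are circularly phase-shifted
    and amplitude-scaled per :class:`VariabilityParams`, widened by
    ``width_scale``, mixed through the modules into per-muscle activation
    envelopes, corrupted with signal-dependent (optionally colored) noise,
    and finally multiplied by a zero-mean 20-450 Hz Gaussian carrier.

    With ``carrier=False`` the noisy envelopes themselves are returned
    (same RNG consumption, so trials remain comparable across the flag);
    useful for validating the noise model without the demodulation step.
    """
    if fs < 1000.0:
        raise ValueError("fs must be >= 1000 Hz for raw-EMG-like output")
    cycles = events.cycles()
    if len(cycles) < 2:
        raise ValueError("events must span at least 2 complete cycles")
    t_end = cycles[-1][2]
    if t_end <= cycles[0][0]:
        raise ValueError("inconsistent event times")

    n = int(round(t_end * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(var.seed)
    n_syn = ref.n_synergies

    # per-cycle draws (fixed order so equal params => identical output)
    shifts = (var.timing_jitter_sd / 100.0) * rng.standard_normal(len(cycles))
    amps = 1.0 + var.amplitude_jitter_sd * rng.standard_normal((len(cycles), n_syn))
    amps = np.maximum(amps, 0.0)

    activations = np.zeros((n, n_syn))
    for c, (td, lo, td_next) in enumerate(cycles):
        mask = (t >= td) & (t < td_next)
        phase = _cycle_phase(t[mask], td, lo, td_next)
        for s in range(n_syn):
            activations[mask, s] = amps[c, s] * _primitive_value(
                ref, s, phase, shifts[c], var.width_scale)

    envelopes = activations @ ref.modules.T  # (n, n_muscles)

    noisy = np.empty_like(envelopes)
    for m in range(ref.n_muscles):
        z = _colored_noise(rng, n, var.noise_color)
        noisy[:, m] = envelopes[:, m] * (1.0 + var.sdn_coeff * z)
    np.clip(noisy, 0.0, None, out=noisy)

    if carrier:
        raw = np.empty_like(noisy)
        for m in range(ref.n_muscles):
            raw[:, m] = noisy[:, m] * _band_limited_carrier(rng, n, fs)
    else:
        raw = noisy

    meta = {
        "generator": "locodyn.synthetic_emg.synthesize_trial",
        "variability": {
            "timing_jitter_sd": var.timing_jitter_sd,
            "amplitude_jitter_sd": var.amplitude_jitter_sd,
            "sdn_coeff": var.sdn_coeff,
            "width_scale": var.width_scale,
            "noise_color": var.noise_color,
            "seed": var.seed,
        },
        "n_cycles": len(cycles),
        "fs": fs,
    }
    return EMGRecording(raw, fs=fs, muscle_labels=list(ref.muscle_labels),
                        trial_id=trial_id, meta=meta)


def make_condition_pair(
    base: VariabilityParams,
    challenge: VariabilityParams,
    shared_seed_policy: str = "shared",
    ref: ReferenceSynergies | None = None,
    events: GaitEvents | None = None,
    fs: float = 2000.0,
) -> tuple[EMGRecording, EMGRecording]:
    """Two trials matched in muscles, cycles and events.

    With ``shared_seed_policy="shared"`` the challenge trial reuses the base
    seed, so identical parameter sets produce byte-identical recordings and
    any difference is attributable to the differing knobs (recorded in each
    recording's ``meta["differing_params"]``).
    """
    if shared_seed_policy not in ("shared", "independent"):
        raise ValueError("shared_seed_policy must be 'shared' or 'independent'")
    if ref is None:
        ref = make_reference_synergies(seed=base.seed)
    if events is None:
        events = make_gait_events(seed=base.seed)
    if shared_seed_policy == "shared":
        challenge = replace(challenge, seed=base.seed)
    diff = [f for f in ("timing_jitter_sd", "amplitude_jitter_sd", "sdn_coeff",
                        "width_scale", "noise_color")
            if getattr(base, f) != getattr(challenge, f)]
    rec_a = synthesize_trial(ref, events, base, fs=fs, trial_id="condition_a")
    rec_b = synthesize_trial(ref, events, challenge, fs=fs, trial_id="condition_b")
    for rec in (rec_a, rec_b):
        rec.meta["differing_params"] = diff
    return rec_a, rec_b
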