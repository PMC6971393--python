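# locodyn

Local dynamic stability, complexity and temporal width of muscle-synergy
motor primitives during human locomotion.

When humans walk or run, the central nervous system appears to coordinate
the many leg muscles through a small number of **muscle synergies**: a
non-negative matrix factorization of the surface-EMG envelopes,
V ≈ W·H, splits the signal into time-invariant **motor modules** W
(muscles × rank) and time-dependent **motor primitives** H (rank × time).
`locodyn` quantifies how those control signals behave over time:

- **sMLE** — short-term maximum Lyapunov exponents of the primitives,
  computed *directly in the synergy space*: the state at time *k* is the
  rank-dimensional vector of primitive activations, so no delay embedding
  (and no embedding-dimension or time-delay choice) is needed. For every
  point, the nearest neighbour outside a Theiler window is tracked forward;
  the sMLE is the least-squares slope of ⟨ln d(k)⟩ over a short fit window.
  Lower sMLE ⇒ less locally unstable control.
- **HFD** — Higuchi's fractal dimension of each primitive, a curve-length
  scaling exponent between 1 (smooth) and 2 (space-filling noise); lower
  HFD ⇒ less complex/irregular control.
- **FWHM** — full width at half maximum of each minimum-subtracted
  primitive per gait cycle; wider ⇒ temporally fuzzier activation.
- Spatiotemporal gait parameters (stance, swing, cadence at 2 steps per
  gait cycle) and automatic factorization-rank selection from the
  reconstruction-R² curve.

The intended users are motor-control and gait researchers who record
multi-muscle surface EMG with touchdown/lift-off events. Because real
recordings are not always at hand, the package ships a first-class
synthetic-EMG generator: Gaussian-bump primitives for the four fundamental
locomotor synergies (weight acceptance, propulsion, early swing, late
swing), mixed through plausible lower-limb modules, with signal-dependent
noise, cycle-to-cycle timing/amplitude jitter and primitive widening all
under seed control — so every metric can be validated against planted
ground truth.

## Worked example

```python
import numpy as np
from locodyn import synthetic_emg as se, preprocess as pp, synergies as sg
from locodyn import dynamics as dy, complexity as cx

ref = se.make_reference_synergies()                  # 13 muscles, 4 synergies
events = se.make_gait_events(n_cycles=30, stance_ms=689.0, swing_ms=393.0,
                             timing_jitter_sd_ms=20.0, seed=7)
rec = se.synthesize_trial(ref, events, se.VariabilityParams(seed=7))

env = pp.envelope(rec)                               # 50-450 Hz, rectify, 4 Hz
cm = pp.segment_normalize(env, events)               # 30 x 13 x 200
rank, r2_curve = sg.select_rank(cm, max_rank=8, n_restarts=5, seed=0)
syn = sg.classify(sg.nmf(cm, rank, n_restarts=5, seed=0), ref)

curve = dy.fit_smle(dy.divergence(dy.build_trajectory(syn)))
st = pp.spatiotemporal(events)
print("rank", rank, "R2 %.3f" % syn.r2)
print("sMLE %.2f per cycle" % curve.smle_per_cycle)
print("HFD mean %.3f" % cx.trial_hfd(syn).mean)
print("FWHM", dict(zip(*[sg.trial_fwhm(syn).labels,
                         np.round(sg.trial_fwhm(syn).mean_points, 1)])))
print("cadence %.0f steps/min" % st.cadence_steps_per_min)
```

prints

```
rank 4 R2 0.994
sMLE 1.73 per cycle
HFD mean 1.139
FWHM {'weight_acceptance': np.float64(37.4), 'propulsion': np.float64(36.3),
      'early_swing': np.float64(47.2), 'late_swing': np.float64(46.6)}
cadence 112 steps/min
```

The selected rank equals the four planted synergies; R² = 0.994 means the
four-synergy reconstruction accounts for almost all envelope variance. The
sMLE of 1.73 ln-units per gait cycle reflects the default cycle-to-cycle
variability (1% timing jitter, 10% amplitude jitter, 5% signal-dependent
noise); a perfectly periodic trial would give ≈ 0. HFD ≈ 1.14 indicates
smooth, weakly irregular primitives, and the FWHM values sit near the
planted 18%-of-cycle bump widths (36 of 200 points; the swing-phase bumps
widen through the carrier-demodulation noise floor). Cadence reproduces the
2 × 60000 / (stance + swing) arithmetic, 111 steps/min at the nominal
689 + 393 ms (112 here after 20 ms timing jitter).

A command-line interface mirrors the library:
`locodyn simulate | preprocess | extract | dynamics | pipeline | contrast`,
each accepting `--config`, `--seed`, `--out-dir`, `--log-level`.

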