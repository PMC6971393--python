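# Methods

This note documents the models, parameter choices and known limitations of
`locodyn`. It is written for users who want to audit or re-tune the
analysis, not as a tutorial (see the README for that).

## The analysis model

Surface EMG during locomotion is treated as a low-rank non-negative
mixture: the envelope matrix V (muscles × time, gait cycles concatenated
and each cycle time-normalized to 200 points) is factorized as V ≈ W·H.
Columns of W are motor modules (how strongly each muscle participates in a
synergy), rows of H are motor primitives (when that synergy is active).
All subsequent metrics are functions of H:

- **sMLE.** The primitives are read as a trajectory in an M-dimensional
  space, M = factorization rank, one point per time sample, each primitive
  max-normalized to 1. For each point the nearest Euclidean neighbour
  outside a Theiler exclusion window is found; d(k) is the distance between
  the two forward-tracked points after k samples, and the curve ⟨ln d(k)⟩
  averages over all pairs still inside the series. The sMLE is the ordinary
  least-squares slope of this curve over a short window, reported per
  sample and per gait cycle (slope × samples-per-cycle). No delay embedding
  is performed anywhere: the synergy space itself is the state space and
  its dimension is fixed by the factorization, which removes the two
  classical free choices (time delay and embedding dimension).
- **HFD.** Higuchi's curve-length estimator: for coarseness k and offset m,
  the normalized length L_m(k) sums |x(m+ik) − x(m+(i−1)k)| and rescales by
  (N−1)/(⌊(N−m)/k⌋·k)/k; L(k) averages over the k offsets, and the fractal
  dimension is the negative slope of ln L(k) vs ln k. Values lie in [1, 2]
  for series with a genuine scaling region.
- **FWHM.** Per cycle and synergy: subtract the cycle minimum, count the
  points strictly above half the resulting maximum, average over cycles.
  The minimum-subtraction makes the measure offset-invariant; it is
  trivially scale-invariant.
- **Spatiotemporal.** stance = LO − TD, swing = next TD − LO, cadence =
  2 × 60000/(stance + swing) steps/min (two steps per gait cycle), averaged
  over cycles.

## Preprocessing

Zero-lag (forward–backward) 4th-order Butterworth band-pass 50–450 Hz,
full-wave rectification, zero-lag 4th-order low-pass at 4 Hz, clipped at
zero (filtfilt can undershoot slightly negative, and the factorization
requires non-negative input). These are the conventional settings for
locomotor surface EMG and are all configurable (`preprocess.*`). Stance and
swing are each linearly resampled to 100 points (linear interpolation:
monotone, no overshoot on non-negative envelopes), so the stance→swing
boundary is always at index 100 of 200. Amplitude is normalized per muscle
to the trial maximum. Pre-enveloped inputs can skip the filter chain with
`preprocess.apply_envelope: false`.

## Factorization and rank selection

NMF by multiplicative updates on the squared error, best of `n_restarts`
(default 10) random initializations by final R² = 1 − SSE/SST. A restart
stops when the R² improvement over a 20-iteration patience window falls
below `tol` (1e-5 relative) or at `max_iter` = 1000. H rows are rescaled to
maximum 1 with the inverse scale folded into W, so primitives are
comparable across synergies and the reconstruction is unchanged. The
multiplicative updates guarantee a non-increasing objective, which the test
suite asserts iteration-by-iteration.

Rank selection computes the R² curve for ranks 1..`max_rank` (8) and picks
the smallest rank r for which a straight line fit to the curve restricted
to ranks r..max_rank has mean squared error < `plateau_mse` (1e-4) — i.e.
the point where the curve has flattened into the linear noise-tracking
regime. On synthetic four-synergy trials at the default noise this selects
rank 4 in ≈ 100% of seeds; the full curve is always retained for audit.

Classification matches each extracted synergy to the four fundamental
templates (weight acceptance, propulsion, early swing, late swing) by
cosine similarity of the concatenated unit-normalized module and
cycle-averaged primitive, with a one-to-one assignment maximizing total
similarity (Hungarian algorithm). Extra synergies are labeled "combined",
ordered after the fundamental ones by primitive peak phase, and excluded
from FWHM summaries.

## Dynamics parameters

- `theiler_window` defaults to one gait cycle (200 samples): nearest
  neighbours must come from *different* cycles for cycle-to-cycle
  divergence to be meaningful. The test suite asserts this on the selected
  pairs.
- `horizon` defaults to min(3 cycles, T/2); pairs whose tracks leave the
  series are dropped from later k, with the per-k pair count recorded.
- `fit_window` defaults to the first half gait cycle (samples 0–100), the
  conventional "short-term" range; it is always recorded in the result, and
  slopes are shift-invariant, so subtracting curve minima for display never
  affects the estimate.
- Euclidean metric: all coordinates are max-normalized primitives, hence
  commensurate.
- Nearest-neighbour search is an exact chunked brute-force distance
  computation (the test suite checks pair-for-pair identity against a naive
  loop). Exactly periodic input yields zero distances; ln d floors at
  1e-300 so the curve is flat rather than −∞ and the slope is 0, which is
  the correct limit.

On a Lorenz-system fixture (raw 3-D state, dt = 0.01, 20 000 samples,
Theiler 100), the divergence-curve slope over the post-transient window
k = 40..160 agrees with an independent Benettin estimate of the largest
Lyapunov exponent to ≈ 4%. The first ~40 samples of the curve are a
neighbour-alignment transient with a visibly steeper local slope and are
excluded from that fit; on gait-like data, where neighbours are genuinely
close and noise-dominated, the default 0–100 window is appropriate.

## Complexity parameters

`k_max` = 64 for full-trial primitives (≥ 6000 points) and 10 for
200-point cycle averages; the ln L(k) regression points are exposed in the
result so the log–log linearity can be audited. HFD is computed per
primitive on the full-trial concatenated series and averaged
(`complexity.mode: per_primitive`); a cycle-average mode exists as an
option. Known limitation: a strong periodicity *shorter than k_max*
(e.g. a 30-sample oscillation probed at k up to 64) violates the
curve-length scaling assumption and can push the estimate slightly above
2; motor primitives, with one or few bumps per 200-point cycle, are far
from this regime.

## The synthetic-EMG generator

The generator is the forward model of the factorization, used as ground
truth for every test:

- Primitives are circular Gaussian bumps at 15/40/65/90% of the cycle
  (the four locomotor phases), FWHM 18% of the cycle, max 1. Modules load
  the phase-typical muscle groups (knee extensors + glutei; plantarflexors;
  dorsiflexors; knee flexors + dorsiflexors) on a 13-muscle lower-limb
  montage, with a small seeded baseline elsewhere, unit-norm per synergy.
- Gait events default to 689 ms stance / 393 ms swing (unperturbed
  overground walking scale), 30 cycles, 20 ms per-phase timing jitter.
- Per cycle, primitives are circularly phase-shifted (sd
  `timing_jitter_sd`, default 1% of the cycle), amplitude-scaled
  (multiplicative sd `amplitude_jitter_sd`, default 0.1, truncated at 0)
  and widened about their centers by `width_scale`.
- Noise is signal-dependent: the envelope is multiplied by
  (1 + sdn_coeff·z) with z unit-sd noise, so the noise sd at any instant is
  `sdn_coeff` × activation (default 0.05; the proportionality slope is
  verified to 15%). `noise_color` tilts z's spectrum (1/f^β); there is
  deliberately no separate additive-noise amplitude — the signal-dependent
  coefficient is the single noise knob, and colored vs white is a spectral
  property of the same disturbance.
- The noisy envelope is multiplied by a zero-mean, unit-sd, 20–450 Hz
  band-limited Gaussian carrier at fs = 2000 Hz to emulate raw EMG, so the
  preprocessing chain is exercised end to end. `carrier=False` returns the
  noisy envelopes themselves.

Identical parameters and seed reproduce byte-identical recordings.
What the generator does **not** emulate: motion artifacts, electrode
cross-talk, non-stationary fatigue drifts, inter-muscle noise correlation,
and any biomechanics (no musculoskeletal model). Passing tests therefore
demonstrate correctness of the *analysis* under a controlled low-rank
generative model, not robustness to every pathology of real recordings.

## The paired-contrast experiment

`pipeline.run_contrast` synthesizes, per seed, two trials sharing the
synergy templates, gait events and noise streams, differing only in the
stated variability knobs, runs the full pipeline on both and reports
per-seed metric differences with medians and sign-consistency counts — no
p-values, by design. The "perturbation analogue" contrast (half timing
jitter, half amplitude jitter, half signal-dependent noise, width_scale
1.3) reproduces the direction pattern higher FWHM / lower sMLE / lower HFD
in ≈ 20/20 paired seeds. Contrast runs fix the factorization rank at the
planted rank 4 so paired trials are compared in the same-dimensional
synergy space; rank selection is validated separately. Problem sizes
throughout (30 cycles, 13 muscles, 20 seeds, 5 NMF restarts for rank
curves) were chosen so the whole validation battery runs in minutes on one
core while keeping every statistical check comfortably powered.

## Degenerate inputs and tie-breaks

All-zero muscle rows are rejected by name before factorization; constant
series are rejected by the FWHM and HFD estimators (both are undefined
there); a rank-1 synergy space is rejected by the trajectory builder with
guidance; classification ties are broken by gait-phase order of the
primitive peaks; cycles with fewer than 4 samples per phase are dropped
with a counted warning.
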