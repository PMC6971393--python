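import numpy as np
import pytest

import oracles
from locodyn.dynamics import (DivergenceCurve, SynergyTrajectory,
                              build_trajectory, divergence, fit_smle)
from locodyn.synergies import SynergySet


def _periodic_trajectory(n_cycles=10, spc=200, dim=3):
    phase = 2 * np.pi * np.arange(spc) / spc
    cycle = np.stack([np.sin(phase + 2 * np.pi * d / dim) * 0.5 + 0.5
                      for d in range(dim)], axis=1)
    return SynergyTrajectory(points=np.tile(cycle, (n_cycles, 1)),
                             samples_per_cycle=spc)


class TestBuildTrajectory:
    def test_shape_and_normalization(self, synergy_set):
        traj = build_trajectory(synergy_set)
        assert traj.points.shape == (30 * 200, 4)
        np.testing.assert_allclose(traj.points.max(axis=0), 1.0)
        assert traj.points.min() >= 0.0

    def test_rank1_rejected_with_guidance(self, synergy_set):
        syn1 = SynergySet(W=synergy_set.W[:, :1], H=synergy_set.H[:1],
                          rank=1, r2=0.5,
                          muscle_labels=synergy_set.muscle_labels,
                          samples_per_cycle=200, n_cycles=30)
        with pytest.raises(ValueError, match="at least 2-D"):
            build_trajectory(syn1)

    def test_noiseless_trial_retraces_closed_loop(self):
        traj = _periodic_trajectory()
        cyc = traj.points.reshape(10, 200, 3)
        np.testing.assert_array_equal(cyc[0], cyc[5])


class TestDivergence:
    def test_periodic_trajectory_flat_curve(self):
        traj = _periodic_trajectory()
        curve = fit_smle(divergence(traj, horizon=400))
        assert abs(curve.smle_per_sample) < 1e-6

    def test_negative_intercept_for_normalized_primitives(self, synergy_set):
        # all coordinates <= 1 and neighbours are close, so ln d(0) < 0
        curve = divergence(build_trajectory(synergy_set))
        assert curve.mean_log_divergence[0] < 0.0

    def test_theiler_window_respected(self, synergy_set):
        traj = build_trajectory(synergy_set)
        curve = divergence(traj, theiler_window=200)
        gaps = np.abs(curve.pairs[:, 0] - curve.pairs[:, 1])
        assert gaps.min() > 200

    def test_pair_dropout_recorded(self):
        traj = _periodic_trajectory(n_cycles=6)
        curve = divergence(traj, theiler_window=200, horizon=500)
        assert curve.n_pairs[0] == traj.T
        assert curve.n_pairs[-1] < curve.n_pairs[0]
        assert np.all(np.diff(curve.n_pairs) <= 0)

    def test_oracle_equivalence_noisy_sinusoid(self):
        rng = np.random.default_rng(12)
        t = np.arange(400)
        pts = np.stack([np.sin(2 * np.pi * t / 40),
                        np.cos(2 * np.pi * t / 40)], axis=1)
        pts += 0.05 * rng.standard_normal(pts.shape)
        traj = SynergyTrajectory(points=pts, samples_per_cycle=40)
        curve = divergence(traj, theiler_window=10, horizon=100)
        ref_curve, ref_nb = oracles.divergence_curve_naive(pts, 10, 100)
        np.testing.assert_array_equal(curve.pairs[:, 1], ref_nb)
        np.testing.assert_allclose(curve.mean_log_divergence, ref_curve,
                                   atol=1e-9)

    def test_oracle_equivalence_lorenz_snippet(self):
        pts = oracles.lorenz_trajectory(500, dt=0.02)
        traj = SynergyTrajectory(points=pts, samples_per_cycle=40)
        curve = divergence(traj, theiler_window=40, horizon=100)
        ref_curve, ref_nb = oracles.divergence_curve_naive(pts, 40, 100)
        np.testing.assert_array_equal(curve.pairs[:, 1], ref_nb)
        np.testing.assert_allclose(curve.mean_log_divergence, ref_curve,
                                   atol=1e-9)

    def test_horizon_beyond_half_rejected(self):
        traj = _periodic_trajectory(n_cycles=4)
        with pytest.raises(ValueError, match="horizon"):
            divergence(traj, horizon=500)


class TestFitSmle:
    def test_exact_line_slope_and_per_cycle_rescale(self):
        ml = -3.0 + 0.01 * np.arange(301)
        curve = DivergenceCurve(horizon_samples=300, mean_log_divergence=ml,
                                n_pairs=np.full(301, 50),
                                samples_per_cycle=200, theiler_window=200)
        out = fit_smle(curve, (0, 100))
        assert out.smle_per_sample == pytest.approx(0.01, abs=1e-12)
        assert out.smle_per_cycle == pytest.approx(2.0, abs=1e-10)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        ml = np.cumsum(rng.random(201) * 0.01)
        base = DivergenceCurve(horizon_samples=200, mean_log_divergence=ml,
                               n_pairs=np.full(201, 30),
                               samples_per_cycle=200, theiler_window=200)
        shifted = DivergenceCurve(horizon_samples=200,
                                  mean_log_divergence=ml + 4.2,
                                  n_pairs=np.full(201, 30),
                                  samples_per_cycle=200, theiler_window=200)
        a = fit_smle(base, (0, 100)).smle_per_sample
        b = fit_smle(shifted, (0, 100)).smle_per_sample
        assert a == pytest.approx(b, abs=1e-12)

    def test_window_with_dropouts_rejected(self):
        ml = np.zeros(101)
        n_pairs = np.full(101, 20)
        n_pairs[50:] = 0
        curve = DivergenceCurve(horizon_samples=100, mean_log_divergence=ml,
                                n_pairs=n_pairs, samples_per_cycle=200,
                                theiler_window=200)
        with pytest.raises(ValueError, match="undefined"):
            fit_smle(curve, (0, 80))

    def test_short_window_rejected(self):
        ml = np.zeros(101)
        curve = DivergenceCurve(horizon_samples=100, mean_log_divergence=ml,
                                n_pairs=np.full(101, 20),
                                samples_per_cycle=200, theiler_window=200)
        with pytest.raises(ValueError, match="at least 5"):
            fit_smle(curve, (0, 2))


class TestScalingInvariance:
    def test_global_scaling_shifts_curve_slope_unchanged(self, synergy_set):
        traj = build_trajectory(synergy_set)
        scaled = SynergyTrajectory(points=3.7 * traj.points,
                                   samples_per_cycle=200, normalized=False)
        a = fit_smle(divergence(traj))
        b = fit_smle(divergence(scaled))
        np.testing.assert_allclose(
            b.mean_log_divergence - a.mean_log_divergence, np.log(3.7),
            atol=1e-9)
        assert a.smle_per_cycle == pytest.approx(b.smle_per_cycle, abs=1e-9)


class TestJitterMonotonicity:
    def test_smle_increases_with_timing_jitter(self):
        from locodyn import preprocess, synergies
        from locodyn.synthetic_emg import (VariabilityParams, make_gait_events,
                                           make_reference_synergies,
                                           synthesize_trial)
        medians = []
        for jit in (0.0, 1.0, 3.0):
            vals = []
            for seed in range(7):
                ref = make_reference_synergies(seed=seed)
                ev = make_gait_events(n_cycles=30, timing_jitter_sd_ms=20,
                                      seed=seed)
                var = VariabilityParams(timing_jitter_sd=jit, seed=seed)
                rec = synthesize_trial(ref, ev, var)
                cm = preprocess.segment_normalize(preprocess.envelope(rec), ev)
                syn = synergies.nmf(cm, 4, n_restarts=2, seed=seed)
                c = fit_smle(divergence(build_trajectory(syn)))
                vals.append(c.smle_per_cycle)
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]
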