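import numpy as np
import pytest

from locodyn import preprocess, synergies
from locodyn.synthetic_emg import (DEFAULT_MUSCLES, VariabilityParams,
                                   make_condition_pair, make_gait_events,
                                   make_reference_synergies, synthesize_trial)

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.355


class TestReferenceSynergies:
    def test_default_dominant_muscle_groups(self, reference):
        idx = {m: i for i, m in enumerate(DEFAULT_MUSCLES)}
        expected = {
            "weight_acceptance": ["VM", "VL", "ME", "MA"],
            "propulsion": ["SO", "GM", "GL"],
            "early_swing": ["TA", "PL"],
            "late_swing": ["ST", "BF", "TA"],
        }
        for s, label in enumerate(reference.labels):
            col = reference.modules[:, s]
            dominant = set(np.argsort(col)[-len(expected[label]):])
            assert dominant == {idx[m] for m in expected[label]}, label

    def test_primitive_max_is_one(self, reference):
        np.testing.assert_allclose(reference.primitives.max(axis=1), 1.0)
        assert np.all(reference.primitives >= 0)
        assert np.all(reference.modules >= 0)

    def test_gaussian_bump_fwhm_matches_closed_form(self):
        # measured FWHM of the planted bump ~ 2 sqrt(2 ln 2) sigma
        width_pct = 20.0
        ref = make_reference_synergies(widths=[width_pct] * 4, n_points=2000)
        for s in range(4):
            w = synergies.fwhm(ref.primitives[s])
            sigma_pts = (width_pct / 100) * 2000 / FWHM_FACTOR
            assert w == pytest.approx(FWHM_FACTOR * sigma_pts, rel=0.02)

    def test_centers_strictly_increasing(self, reference):
        assert np.all(np.diff(reference.centers) > 0)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError, match="widths"):
            make_reference_synergies(widths=[18, -1, 18, 18])


class TestGaitEvents:
    def test_zero_jitter_cadence_matches_walking_row(self):
        ev = make_gait_events(n_cycles=10, stance_ms=689, swing_ms=393,
                              timing_jitter_sd_ms=0)
        st = preprocess.spatiotemporal(ev)
        assert round(st.cadence_steps_per_min) == 111

    def test_zero_jitter_is_exactly_periodic(self):
        ev = make_gait_events(n_cycles=10, timing_jitter_sd_ms=0)
        cycles = np.diff(ev.touchdowns)
        assert np.ptp(cycles) < 1e-12

    def test_jitter_sd_recovered_monte_carlo(self):
        ev = make_gait_events(n_cycles=1000, timing_jitter_sd_ms=20, seed=3)
        stance = (ev.liftoffs - ev.touchdowns[:-1]) * 1000
        assert np.std(stance) == pytest.approx(20.0, rel=0.10)

    def test_negative_jitter_rejected(self):
        with pytest.raises(ValueError):
            make_gait_events(timing_jitter_sd_ms=-1)


class TestSynthesizeTrial:
    def test_noiseless_forward_inverse_r2(self, reference):
        ev = make_gait_events(n_cycles=10, timing_jitter_sd_ms=0)
        var = VariabilityParams(timing_jitter_sd=0, amplitude_jitter_sd=0,
                                sdn_coeff=0, seed=0)
        rec = synthesize_trial(reference, ev, var)
        env = preprocess.envelope(rec)
        cm = preprocess.segment_normalize(env, ev)
        syn = synergies.nmf(cm, 4, n_restarts=3, seed=0)
        assert syn.r2 > 0.99

    def test_more_noise_worse_reconstruction(self, reference, events_30):
        for seed in range(3):
            resid = []
            for sdn in (0.05, 0.20):
                var = VariabilityParams(sdn_coeff=sdn, seed=seed)
                rec = synthesize_trial(reference, events_30, var)
                cm = preprocess.segment_normalize(preprocess.envelope(rec),
                                                  events_30)
                resid.append(1.0 - synergies.nmf(cm, 4, n_restarts=2,
                                                 seed=0).r2)
            assert resid[1] > resid[0]

    def test_width_scale_widens_recovered_primitives(self, reference, events_30):
        widths = []
        for ws in (1.0, 1.3):
            var = VariabilityParams(width_scale=ws, seed=5)
            rec = synthesize_trial(reference, events_30, var)
            cm = preprocess.segment_normalize(preprocess.envelope(rec),
                                              events_30)
            syn = synergies.classify(synergies.nmf(cm, 4, n_restarts=2, seed=0),
                                     reference)
            widths.append(synergies.trial_fwhm(syn).mean_points.mean())
        assert widths[1] > widths[0]

    def test_determinism_byte_identical(self, reference, events_30):
        var = VariabilityParams(seed=11)
        a = synthesize_trial(reference, events_30, var)
        b = synthesize_trial(reference, events_30, var)
        assert np.array_equal(a.samples, b.samples)

    def test_signal_dependent_noise_slope(self, reference):
        # noise sd conditional on activation level is proportional to the
        # level, with slope ~ sdn_coeff
        ev = make_gait_events(n_cycles=100, timing_jitter_sd_ms=0)
        sdn = 0.10
        clean = synthesize_trial(reference, ev, VariabilityParams(
            timing_jitter_sd=0, amplitude_jitter_sd=0, sdn_coeff=0, seed=2),
            carrier=False)
        noisy = synthesize_trial(reference, ev, VariabilityParams(
            timing_jitter_sd=0, amplitude_jitter_sd=0, sdn_coeff=sdn, seed=2),
            carrier=False)
        level = clean.samples.ravel()
        resid = (noisy.samples - clean.samples).ravel()
        keep = level > 0.05
        bins = np.quantile(level[keep], np.linspace(0, 1, 11))
        which = np.digitize(level[keep], bins[1:-1])
        sds = np.array([resid[keep][which == b].std() for b in range(10)])
        mids = np.array([level[keep][which == b].mean() for b in range(10)])
        slope = np.polyfit(mids, sds, 1)[0]
        assert slope == pytest.approx(sdn, rel=0.15)

    def test_fs_below_1khz_rejected(self, reference, events_30):
        with pytest.raises(ValueError, match="fs"):
            synthesize_trial(reference, events_30, VariabilityParams(), fs=500)


class TestConditionPair:
    def test_identical_conditions_identical_outputs(self):
        base = VariabilityParams(seed=3)
        challenge = VariabilityParams(seed=99)  # seed overridden by policy
        a, b = make_condition_pair(base, challenge, "shared")
        assert np.array_equal(a.samples, b.samples)
        assert a.meta["differing_params"] == []

    def test_differing_knobs_recorded(self):
        base = VariabilityParams(seed=3)
        challenge = VariabilityParams(seed=3, width_scale=1.3, sdn_coeff=0.1)
        a, b = make_condition_pair(base, challenge)
        assert set(a.meta["differing_params"]) == {"width_scale", "sdn_coeff"}
        assert not np.array_equal(a.samples, b.samples)
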