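"""Synthetic cohort generator: schedules, signal synthesis, planted effects."""

import numpy as np
import pytest

import fatiguekit as fk
from fatiguekit.io_formats import NONFREQUENT
from fatiguekit.preprocessing import SegmentView
from fatiguekit.spectral import band_power_series
from fatiguekit.synthetic import EffectSpec, generate_cohort


class TestStimulusSchedule:
    def test_default_counts_and_span(self, schedule):
        assert len(schedule) == 120
        assert len(schedule.where(NONFREQUENT)) == 24
        span_s = (schedule.onsets[-1] - schedule.onsets[0]) / 250.0 + 2.0
        assert span_s == 240.0
        assert schedule.onsets[0] == fk.SEGMENTS["AO"][0]

    def test_determinism_and_label_randomness(self):
        a = fk.generate_stimulus_schedule(10, 0.2, seed=1)
        b = fk.generate_stimulus_schedule(10, 0.2, seed=1)
        assert a.labels == b.labels and np.array_equal(a.onsets, b.onsets)
        assert len(a.where(NONFREQUENT)) == 2
        others = {fk.generate_stimulus_schedule(10, 0.2, seed=s).labels
                  for s in range(30)}
        assert len(others) > 1  # the order really is seed-dependent

    def test_nonfrequent_count_fixed_over_seeds(self):
        counts = {len(fk.generate_stimulus_schedule(seed=s).where(NONFREQUENT))
                  for s in range(100)}
        assert counts == {24}

    def test_non_integer_target_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fk.generate_stimulus_schedule(n_total=10, frac_nonfrequent=0.25)
        with pytest.raises(ValueError):
            fk.generate_stimulus_schedule(n_total=0)


class TestSynthesizeRecording:
    def test_durations_and_rates(self, default_bundle):
        bundle, _ = default_bundle
        assert bundle.eeg.shape == (8, 75000)  # 300 s x 250 Hz
        assert bundle.wristband["BVP"].values.size == 300 * 64
        assert bundle.wristband["EDA"].values.size == 300 * 4
        assert bundle.wristband["HR"].values.size == 300

    def test_bit_identical_regeneration(self, schedule):
        profile = fk.SubjectProfile()
        a = fk.synthesize_recording(profile, schedule, seed=5)
        b = fk.synthesize_recording(profile, schedule, seed=5)
        assert np.array_equal(a.eeg, b.eeg)
        assert np.array_equal(a.wristband["BVP"].values, b.wristband["BVP"].values)
        c = fk.synthesize_recording(profile, schedule, seed=6)
        assert not np.array_equal(a.eeg, c.eeg)

    def test_zero_p300_gives_equal_frequent_nonfrequent_erps(self, schedule):
        profile = fk.SubjectProfile(p300_amplitude_uv=0.0)
        bundle = fk.synthesize_recording(profile, schedule, seed=9)
        filt = fk.apply_filters(bundle)
        eo = fk.segment(filt, "EO")
        nf = fk.build_erp(filt.eeg, filt.markers, eo.eeg, filt.channel_names,
                          target_label="nonfrequent")
        fr = fk.build_erp(filt.eeg, filt.markers, eo.eeg, filt.channel_names,
                          target_label="frequent")
        # no planted effect: both averages are background residue at the
        # 1 / sqrt(n_epochs) level (per-epoch background RMS is ~6 uV here)
        for w_nf, w_fr in zip(nf, fr):
            diff = w_nf.amplitude_uv - w_fr.amplitude_uv
            assert np.sqrt(np.mean(diff ** 2)) < 3.0

    def test_alpha_amplitude_doubling_quadruples_eo_alpha_power(self, schedule):
        base = fk.SubjectProfile()
        doubled = fk.SubjectProfile(
            band_amplitude={b: np.full(8, 8.0 if b == "alpha" else 4.0)
                            for b in fk.BANDS})
        alpha_powers = []
        for profile in (base, doubled):
            bundle = fk.synthesize_recording(profile, schedule, seed=11)
            eo = SegmentView("EO", bundle.eeg[:, 7500:15000], 250.0, 7500)
            bps = band_power_series(eo)
            alpha_powers.append(bps.values[:, :, 2].mean())
        assert alpha_powers[1] / alpha_powers[0] == pytest.approx(4.0, rel=0.02)

    def test_power_monotone_in_amplitude(self, schedule):
        powers = []
        for amp in (2.0, 4.0, 6.0):
            profile = fk.SubjectProfile(
                band_amplitude={b: np.full(8, amp if b == "beta" else 4.0)
                                for b in fk.BANDS})
            bundle = fk.synthesize_recording(profile, schedule, seed=13)
            ao = SegmentView("AO", bundle.eeg[:, 15000:75000], 250.0, 15000)
            powers.append(band_power_series(ao).values[:, :, 3].mean())
        assert powers[0] < powers[1] < powers[2]

    def test_missing_streams_dropped(self, schedule):
        profile = fk.SubjectProfile(missing_streams=frozenset({"TEMP", "IBI"}))
        bundle = fk.synthesize_recording(profile, schedule, seed=3)
        assert "TEMP" not in bundle.wristband and "IBI" not in bundle.wristband
        assert "BVP" in bundle.wristband

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            fk.SubjectProfile(fas_total=60)
        with pytest.raises(ValueError):
            fk.SubjectProfile(p300_latency_ms=900.0)
        with pytest.raises(ValueError):
            fk.SubjectProfile(hrv_lf_hz=0.2)
        with pytest.raises(ValueError):
            fk.SubjectProfile(band_amplitude={b: np.full(8, -1.0) for b in fk.BANDS})


class TestGenerateCohort:
    def test_unknown_target_feature_lists_vocabulary(self):
        with pytest.raises(ValueError, match="ratio_<b1>_<b2>_<ch>"):
            generate_cohort(3, EffectSpec(target_features=("ratio_beta_theta_XX",),
                                          slopes=(-10.0,)), seed=0)
        with pytest.raises(ValueError):
            generate_cohort(3, EffectSpec(target_features=("bogus",), slopes=(1.0,)),
                            seed=0)

    def test_effect_spec_invariants(self):
        with pytest.raises(ValueError):
            EffectSpec(target_features=("ratio_beta_theta_C3",), slopes=(1.0, 2.0))
        with pytest.raises(ValueError):
            EffectSpec(noise_sd=-1.0)

    def test_noiseless_planting_gives_near_perfect_correlation(
            self, noiseless_cohort, noiseless_matrix):
        from fatiguekit.modeling import pearson_r_p

        targets = list(noiseless_cohort.effect.target_features)
        r, _ = pearson_r_p(noiseless_matrix.X[targets].to_numpy(),
                           noiseless_matrix.fas.to_numpy())
        assert np.all(np.abs(r) > 0.999)
        assert np.all(r < 0)  # negative slopes plant negative correlations

    def test_negative_slope_sign_propagates(self):
        cohort = generate_cohort(
            8, EffectSpec(target_features=("ratio_gamma_delta_P8",),
                          slopes=(8.0,), noise_sd=0.0), seed=33)
        from fatiguekit.modeling import pearson_r_p

        fm = fk.assemble_feature_matrix(dict(cohort.measured_features),
                                        cohort.fas_by_subject)
        r, _ = pearson_r_p(fm.X[["ratio_gamma_delta_P8"]].to_numpy(),
                           fm.fas.to_numpy())
        assert r[0] > 0.999

    def test_noisy_correlation_matches_direct_bivariate_oracle(self):
        # plant a single feature at a noise level chosen for r ~ 0.8 and
        # compare with directly simulated (feature, FAS) pairs
        # noise_sd chosen so the planted correlation is ~0.8 in magnitude
        slope, noise_sd, n = -10.0, 5.5, 50
        rng = np.random.default_rng(77)
        class_dists = [(19.0, 2.0), (27.0, 3.0), (37.0, 3.0)]
        weights = np.array([3, 8, 6]) / 17
        r_direct = []
        for _ in range(200):
            which = rng.choice(3, size=n, p=weights)
            intended = np.array([rng.normal(*class_dists[w]) for w in which])
            f = 1.5 + (intended - 30.0) / slope
            fas = (30.0 - slope * 1.5) + slope * f + rng.normal(0, noise_sd, n)
            r_direct.append(np.corrcoef(f, fas)[0, 1])
        effect = EffectSpec(target_features=("ratio_beta_theta_C3",),
                            slopes=(slope,), noise_sd=noise_sd)
        cohort = generate_cohort(n, effect, seed=55)
        fm = fk.assemble_feature_matrix(dict(cohort.measured_features),
                                        cohort.fas_by_subject)
        r_pipeline = np.corrcoef(fm.X["ratio_beta_theta_C3"], fm.fas)[0, 1]
        assert r_pipeline == pytest.approx(np.mean(r_direct), abs=0.1)

    def test_ground_truth_recorded(self, noiseless_cohort):
        assert len(noiseless_cohort.bundles) == 14
        assert len(noiseless_cohort.profiles) == 14
        for sid, truth in noiseless_cohort.target_truth.items():
            for name, vals in truth.items():
                assert vals["measured"] == pytest.approx(vals["intended"], rel=0.1)
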