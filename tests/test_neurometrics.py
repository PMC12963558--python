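"""IAF estimation, band anchoring, GFP band power, WL and AW indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neuroload as nl
from neuroload.recording import EpochSet

from conftest import make_tone_recording
from oracles import band_power_oracle


class TestBandEdges:
    @pytest.mark.parametrize("iaf, theta, alpha", [
        (10.0, (4.0, 8.0), (8.0, 12.0)),
        (8.0, (2.0, 6.0), (6.0, 10.0)),
        (11.5, (5.5, 9.5), (9.5, 13.5)),
    ])
    def test_anchoring(self, iaf, theta, alpha):
        scheme = nl.band_edges(iaf)
        assert scheme.theta_band == theta
        assert scheme.alpha_band == alpha

    def test_bands_are_adjacent_without_gap(self):
        for iaf in np.linspace(7.0, 13.0, 13):
            scheme = nl.band_edges(iaf)
            assert scheme.theta_band[1] == scheme.alpha_band[0]

    def test_out_of_range_iaf_rejected(self):
        with pytest.raises(ValueError):
            nl.band_edges(6.5)


class TestEstimateIaf:
    def test_pure_parietal_tone_hits_exact_bin(self):
        rec = make_tone_recording({"Pz": 9.0, "P3": 9.0, "P4": 9.0},
                                  fs=128.0, duration=40.0, amplitude=5.0)
        assert nl.estimate_iaf(rec) == 9.0

    def test_white_noise_falls_back_with_flag(self, rng):
        rec = nl.Recording(rng.standard_normal((8, 40 * 128)), 128.0)
        iaf, found = nl.estimate_iaf(rec, return_found=True)
        assert iaf == 10.0 and not found

    def test_genuine_10hz_peak_not_mistaken_for_fallback(self):
        rec = make_tone_recording({"Pz": 10.0, "P3": 10.0, "P4": 10.0},
                                  fs=128.0, duration=40.0, amplitude=5.0)
        iaf, found = nl.estimate_iaf(rec, return_found=True)
        assert iaf == 10.0 and found

    def test_short_rest_rejected(self):
        rec = make_tone_recording({"Pz": 10.0}, fs=128.0, duration=10.0)
        with pytest.raises(ValueError):
            nl.estimate_iaf(rec)

    def test_empty_subset_rejected(self):
        rec = make_tone_recording({"Pz": 10.0}, fs=128.0, duration=40.0)
        with pytest.raises(ValueError):
            nl.estimate_iaf(rec, subset=())


def tone_epochs(freq_by_channel, fs=128.0, n_epochs=8, amplitude=1.0):
    montage = nl.default_montage()
    n = int(fs)
    t = np.arange(n) / fs
    epoch = np.zeros((montage.n_channels, n))
    for ch, freq in freq_by_channel.items():
        epoch[montage.index(ch)] = amplitude * np.sin(2 * np.pi * freq * t)
    return EpochSet(np.tile(epoch, (n_epochs, 1, 1)), fs, montage)


class TestBandGfp:
    def test_unit_tone_power_is_half(self):
        epochs = tone_epochs({"Pz": 10.0})
        power = nl.band_gfp(epochs, (8.0, 12.0), ("Pz",))
        assert power.mean() == pytest.approx(0.5, rel=0.01)

    def test_quadratic_amplitude_scaling(self, rng):
        epochs = EpochSet(rng.standard_normal((6, 8, 128)), 128.0,
                          nl.default_montage())
        scaled = EpochSet(3.0 * epochs.epochs, 128.0, epochs.montage)
        a = nl.band_gfp(epochs, (4.0, 8.0), ("AFz", "AF3"))
        b = nl.band_gfp(scaled, (4.0, 8.0), ("AFz", "AF3"))
        np.testing.assert_allclose(b.values, 9.0 * a.values, rtol=1e-10)

    def test_matches_fft_oracle_on_random_epochs(self, rng):
        montage = nl.default_montage()
        data = rng.standard_normal((50, 8, 128)) * 10
        epochs = EpochSet(data, 128.0, montage)
        power = nl.band_gfp(epochs, (6.0, 11.0), montage.frontal)
        idx = montage.indices(montage.frontal)
        for e in range(50):
            oracle = band_power_oracle(data[e], 128.0, (6.0, 11.0), idx)
            assert power.values[e] == pytest.approx(oracle, rel=0.01)

    def test_rejected_epochs_carry_no_value(self, rng):
        epochs = EpochSet(rng.standard_normal((5, 8, 128)), 128.0,
                          nl.default_montage(),
                          artifact_mask=np.array([0, 1, 0, 1, 0], bool))
        power = nl.band_gfp(epochs, (8.0, 12.0), ("Pz",))
        assert np.isnan(power.values[[1, 3]]).all()
        assert np.isfinite(power.values[[0, 2, 4]]).all()

    def test_spatial_variance_mode_zero_for_uniform_signal(self):
        # identical signal on every subset channel has zero spatial variance
        epochs = tone_epochs({"Pz": 10.0, "P3": 10.0, "P4": 10.0})
        power = nl.band_gfp(epochs, (8.0, 12.0), ("Pz", "P3", "P4"),
                            mode="spatial-variance")
        assert power.mean() == pytest.approx(0.0, abs=1e-12)

    def test_empty_subset_rejected(self, rng):
        epochs = EpochSet(rng.standard_normal((2, 8, 128)), 128.0,
                          nl.default_montage())
        with pytest.raises(ValueError):
            nl.band_gfp(epochs, (8.0, 12.0), ())


class TestWorkloadIndex:
    def test_equal_band_powers_give_unity(self):
        epochs = tone_epochs({ch: 6.0 for ch in
                              ("AFz", "AF3", "AF4", "AF7", "AF8")}
                             | {ch: 10.0 for ch in ("Pz", "P3", "P4")})
        wl = nl.workload_index(epochs, nl.band_edges(10.0))
        assert wl == pytest.approx(1.0, rel=1e-3)

    def test_doubling_theta_amplitude_quadruples_wl(self):
        frontal = {ch: 6.0 for ch in ("AFz", "AF3", "AF4", "AF7", "AF8")}
        parietal = {ch: 10.0 for ch in ("Pz", "P3", "P4")}
        base = tone_epochs(frontal | parietal)
        scheme = nl.band_edges(10.0)
        doubled = base.copy()
        idx = base.montage.indices(base.montage.frontal)
        doubled.epochs[:, idx, :] *= 2.0
        ratio = nl.workload_index(doubled, scheme) \
            / nl.workload_index(base, scheme)
        assert ratio == pytest.approx(4.0, rel=0.05)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.01, 100.0))
    def test_scale_invariance(self, seed, gain):
        rng = np.random.default_rng(seed)
        epochs = EpochSet(rng.standard_normal((4, 8, 128)) * 5, 128.0,
                          nl.default_montage())
        scaled = EpochSet(gain * epochs.epochs, 128.0, epochs.montage)
        scheme = nl.band_edges(10.0)
        assert nl.workload_index(scaled, scheme) == pytest.approx(
            nl.workload_index(epochs, scheme), rel=1e-9)

    def test_all_rejected_epochs_is_an_error(self, rng):
        epochs = EpochSet(rng.standard_normal((3, 8, 128)), 128.0,
                          nl.default_montage(),
                          artifact_mask=np.ones(3, bool))
        with pytest.raises(ValueError):
            nl.workload_index(epochs, nl.band_edges(10.0))


class TestApproachWithdrawal:
    def test_hemispherically_symmetric_signal_gives_zero(self):
        epochs = tone_epochs({ch: 10.0 for ch in
                              ("AF3", "AF7", "AF4", "AF8")})
        aw = nl.approach_withdrawal_index(epochs, nl.band_edges(10.0))
        assert aw == pytest.approx(0.0, abs=1e-9)

    def test_swapping_hemispheres_negates_exactly(self, rng):
        epochs = EpochSet(rng.standard_normal((6, 8, 128)) * 5, 128.0,
                          nl.default_montage())
        scheme = nl.band_edges(10.0)
        swapped = nl.ChannelMontage(frontal_left=("AF4", "AF8"),
                                    frontal_right=("AF3", "AF7"))
        aw = nl.approach_withdrawal_index(epochs, scheme)
        aw_swapped = nl.approach_withdrawal_index(epochs, scheme,
                                                  montage=swapped)
        assert aw_swapped == pytest.approx(-aw, rel=1e-12)

    def test_programmed_right_shift_detected_across_subjects(self):
        # subject-level Monte-Carlo: with the programmed right-frontal
        # alpha shift, AW is positive for the vast majority of subjects
        profiles = nl.make_profiles(0, 25, seed=31)
        effects = nl.EffectSpec()       # students get +0.5 uV under HM
        positive = 0
        for i, profile in enumerate(profiles):
            rec = nl.synthesize_recording(profile, "HM", effects,
                                          duration=120.0, fs=128.0,
                                          seed=400 + i)
            result = nl.preprocess(rec)
            scheme = nl.band_edges(profile.true_iaf)
            positive += nl.approach_withdrawal_index(result.epochs,
                                                     scheme) > 0
        assert positive >= 23          # >= 90% of 25 subjects


class TestAggregateStudy:
    def test_one_record_per_subject_condition(self, small_study_neurometrics):
        assert len(small_study_neurometrics) == 42
        assert small_study_neurometrics["n_clean_epochs"].min() >= 1
        assert (small_study_neurometrics["wl"] > 0).all()

    def test_epoch_order_permutation_invariance(self, rng):
        montage = nl.default_montage()
        data = rng.standard_normal((10, 8, 128)) * 5
        scheme = nl.band_edges(10.0)
        a = EpochSet(data, 128.0, montage, meta={"group": "expert"})
        perm = rng.permutation(10)
        b = EpochSet(data[perm], 128.0, montage, meta={"group": "expert"})
        out_a = nl.aggregate_study({("s", "BB"): a}, {"s": scheme})
        out_b = nl.aggregate_study({("s", "BB"): b}, {"s": scheme})
        assert out_a["wl"].iloc[0] == pytest.approx(out_b["wl"].iloc[0],
                                                    rel=1e-12)
        assert out_a["aw"].iloc[0] == pytest.approx(out_b["aw"].iloc[0],
                                                    rel=1e-12)

    def test_zero_clean_epoch_records_excluded(self, rng):
        montage = nl.default_montage()
        good = EpochSet(rng.standard_normal((4, 8, 128)), 128.0, montage)
        bad = EpochSet(rng.standard_normal((4, 8, 128)), 128.0, montage,
                       artifact_mask=np.ones(4, bool))
        out = nl.aggregate_study(
            {("s", "BB"): good, ("s", "HM"): bad},
            {"s": nl.band_edges(10.0)})
        assert len(out) == 1
        assert out["condition"].iloc[0] == "BB"
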