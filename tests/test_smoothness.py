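import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itug.errors import SpectrumError
from itug.smoothness import (
    ALL_PHASES,
    CHANNELS,
    SmoothnessConfig,
    SpectralProfile,
    analyze_recording,
    average_trials,
    band_power,
    frequency_ratio,
    frequency_ratio_from_band_powers,
    normalized_psd,
    sparc,
    sparc_of_segment,
    tile_segment,
)

FS = 100.0


def arc_length_oracle(freq, psd, f_low=0.0, f_high=10.0):
    """Brute-force arc-length summation, independent of the implementation."""
    total = 0.0
    for i in range(len(freq) - 1):
        dw = (freq[i + 1] - freq[i]) / (f_high - f_low)
        dp = psd[i + 1] - psd[i]
        total += np.sqrt(dw**2 + dp**2)
    return -total


def spike_profile(n_bins, spike_positions):
    freq = np.linspace(0, 10, n_bins)
    psd = np.zeros(n_bins)
    psd[list(spike_positions)] = 1.0
    return SpectralProfile(freq, psd)


class TestTileSegment:
    def test_factor_one_is_identity_after_dc_removal(self):
        x = np.sin(2 * np.pi * 2 * np.arange(100) / FS)
        np.testing.assert_allclose(tile_segment(x, 1), x - x.mean(), atol=1e-12)

    def test_tiling_repeats_the_segment(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        tiled = tile_segment(x, 4)
        assert tiled.shape == (400,)
        np.testing.assert_allclose(tiled[100:200], tiled[:100], atol=1e-12)

    def test_tiling_sharpens_a_sinusoid_peak(self):
        """Tiling an integer-period sinusoid concentrates spectral power."""
        t = np.arange(100) / FS  # exactly 2 periods of 2 Hz
        x = np.sin(2 * np.pi * 2 * t)
        cfg = SmoothnessConfig(zero_pad=4096)
        p1 = normalized_psd(x, FS, cfg)
        p4 = normalized_psd(tile_segment(x, 4), FS, cfg)

        def near_peak_mass(prof):
            sel = np.abs(prof.freq - 2.0) < 0.3
            return prof.norm_psd[sel].sum() / prof.norm_psd.sum()

        assert near_peak_mass(p4) > near_peak_mass(p1)

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            tile_segment(np.ones(10), 0)


class TestNormalizedPsd:
    def test_pure_tone_peaks_at_its_frequency(self):
        t = np.arange(1000) / FS
        prof = normalized_psd(np.sin(2 * np.pi * 2 * t), FS)
        assert prof.freq[np.argmax(prof.norm_psd)] == pytest.approx(2.0, abs=0.05)
        assert prof.norm_psd.max() == pytest.approx(1.0)
        assert prof.freq[0] >= 0 and prof.freq[-1] <= 10.0

    def test_stride_and_step_peaks(self):
        """Equal 2 Hz and 4 Hz components give two near-unit peaks."""
        t = np.arange(1000) / FS
        x = np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 4 * t)
        prof = normalized_psd(x, FS)
        for f in (2.0, 4.0):
            sel = np.abs(prof.freq - f) < 0.1
            assert prof.norm_psd[sel].max() > 0.9

    def test_white_noise_is_broadband(self):
        rng = np.random.default_rng(3)
        prof = normalized_psd(rng.normal(size=2000), FS)
        # many bins carry non-negligible power, unlike a tonal spectrum
        assert (prof.norm_psd > 0.1).sum() > 50

    def test_all_zero_series_is_error(self):
        with pytest.raises(SpectrumError):
            normalized_psd(np.zeros(100), FS)


class TestSparc:
    def test_flat_unit_spectrum_gives_exactly_minus_one(self):
        prof = SpectralProfile(np.linspace(0, 10, 101), np.ones(101))
        assert sparc(prof) == pytest.approx(-1.0, abs=1e-12)

    def test_single_spike_is_about_minus_three(self):
        prof = spike_profile(1001, [500])
        val = sparc(prof)
        assert val == pytest.approx(arc_length_oracle(prof.freq, prof.norm_psd), abs=1e-9)
        assert val == pytest.approx(-3.0, abs=0.01)

    def test_each_added_spike_costs_about_two(self):
        prev = None
        for spikes in ([300], [300, 600], [300, 600, 900]):
            val = sparc(spike_profile(1001, spikes))
            if prev is not None:
                assert val == pytest.approx(prev - 2.0, abs=0.01)
                assert val < prev
            prev = val

    def test_matches_oracle_on_random_profiles(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            freq = np.linspace(0, 10, 400)
            psd = rng.uniform(0, 1, 400)
            psd[rng.integers(0, 400)] = 1.0
            prof = SpectralProfile(freq, psd)
            assert sparc(prof) == pytest.approx(
                arc_length_oracle(freq, psd), abs=1e-9
            )

    def test_grid_refinement_converges(self):
        """Halving the grid spacing of a smooth profile barely moves SPARC."""
        def smooth_profile(n):
            freq = np.linspace(0, 10, n)
            psd = np.exp(-((freq - 3.0) ** 2) / 2.0)
            psd /= psd.max()
            return SpectralProfile(freq, psd)

        coarse = sparc(smooth_profile(2001))
        fine = sparc(smooth_profile(4001))
        assert abs(fine - coarse) < 1e-3

    def test_fewer_than_two_bins_is_error(self):
        with pytest.raises(ValueError):
            sparc(SpectralProfile(np.array([5.0]), np.array([1.0])))


class TestSparcOfSegment:
    def test_noise_reduces_smoothness(self):
        t = np.arange(300) / FS
        clean = np.sin(2 * np.pi * 2 * t)
        rng = np.random.default_rng(0)
        noisy = clean + 0.5 * rng.normal(size=t.size)
        assert sparc_of_segment(clean, FS) > sparc_of_segment(noisy, FS)

    @settings(max_examples=15, deadline=None)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 1000))
    def test_amplitude_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=256) + np.sin(2 * np.pi * 2 * np.arange(256) / FS)
        assert sparc_of_segment(scale * x, FS) == pytest.approx(
            sparc_of_segment(x, FS), abs=1e-9
        )

    def test_always_at_most_minus_one(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(64, 1024))
            x = rng.normal(size=n)
            for kind in ("phase", "full"):
                assert sparc_of_segment(x, FS, kind) <= -1.0


class TestFrequencyRatio:
    def test_equal_band_powers_give_exactly_one(self):
        assert frequency_ratio_from_band_powers(0.42, 0.42) == 1.0

    def test_band_power_oracle(self):
        freq = np.linspace(0, 10, 1001)
        psd = np.ones(1001)
        # locomotor band [0.5, 3] width 2.5; freeze band (3, 8] width ~5
        assert band_power(freq, psd, (0.5, 3.0)) == pytest.approx(2.5, abs=0.02)
        assert band_power(freq, psd, (3.0, 8.0), closed_low=False) == pytest.approx(
            5.0, abs=0.02
        )

    def test_pure_locomotor_tone_gives_near_zero(self):
        t = np.arange(1000) / FS
        fr = frequency_ratio(np.sin(2 * np.pi * 2 * t), FS)
        assert fr < 0.01

    def test_freeze_burst_raises_fr(self):
        t = np.arange(1000) / FS
        base = np.sin(2 * np.pi * 2 * t)
        burst = base.copy()
        burst[400:700] += 1.5 * np.sin(2 * np.pi * 5.5 * t[400:700])
        assert frequency_ratio(burst, FS) > frequency_ratio(base, FS)

    @settings(max_examples=10, deadline=None)
    @given(scale=st.floats(1e-2, 1e3), seed=st.integers(0, 1000))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=500) + np.sin(2 * np.pi * 2 * np.arange(500) / FS)
        assert frequency_ratio(scale * x, FS) == pytest.approx(
            frequency_ratio(x, FS), rel=1e-9
        )

    def test_zero_locomotor_power_is_error(self):
        with pytest.raises(SpectrumError, match="locomotor"):
            frequency_ratio_from_band_powers(1.0, 0.0)

    def test_too_short_signal(self):
        with pytest.raises(ValueError, match="2 s"):
            frequency_ratio(np.ones(100), FS)


class TestAnalyzeRecording:
    def test_full_grid_of_values(self, control_trial):
        rec, truth = control_trial
        res = analyze_recording(rec, truth)
        assert res.sparc.shape == (8, 6)
        assert set(res.sparc.index) == set(CHANNELS)
        assert set(res.sparc.columns) == set(ALL_PHASES)
        assert (res.sparc.to_numpy() <= -1.0).all()
        assert res.fr >= 0

    def test_acc_axis_permutation_permutes_output(self, control_trial):
        import dataclasses

        rec, truth = control_trial
        base = analyze_recording(rec, truth)
        permuted = dataclasses.replace(rec, acc=rec.acc[:, [1, 2, 0]])
        res = analyze_recording(permuted, truth)
        # V<-ML, ML<-AP, AP<-V; totals unchanged
        np.testing.assert_allclose(
            res.sparc.loc["AccL_V"], base.sparc.loc["AccL_ML"], atol=1e-9
        )
        np.testing.assert_allclose(
            res.sparc.loc["AccL_total"], base.sparc.loc["AccL_total"], atol=1e-9
        )

    def test_trial_averaging_matches_direct_mean(self, control_trial):
        rec, truth = control_trial
        res = analyze_recording(rec, truth)
        import copy

        r2, r3 = copy.deepcopy(res), copy.deepcopy(res)
        r2.sparc = res.sparc - 1.0
        r3.sparc = res.sparc + 1.0
        avg = average_trials([res, r2, r3])
        np.testing.assert_allclose(avg.sparc, res.sparc, atol=1e-12)
        assert avg.trial_index == "mean of 3"

    def test_mean_of_minus_3_4_5_is_minus_4(self, control_trial):
        rec, truth = control_trial
        res = analyze_recording(rec, truth)
        import copy

        rs = []
        for v in (-3.0, -4.0, -5.0):
            r = copy.deepcopy(res)
            r.sparc = res.sparc * 0 + v
            rs.append(r)
        avg = average_trials(rs)
        assert np.allclose(avg.sparc, -4.0)

    def test_mixed_subjects_rejected(self, control_trial, pd_trial):
        ra = analyze_recording(*control_trial)
        rb = analyze_recording(*pd_trial)
        with pytest.raises(ValueError, match="subject"):
            average_trials([ra, rb])
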