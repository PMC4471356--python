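import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegclean.model import Recording
from eegclean.noisy import (
    detect_correlation_dropout,
    detect_deviation,
    detect_hf_noise,
    detect_nan_nodata,
    detect_ransac,
    find_noisy_channels,
    mad,
    robust_sd,
    robust_z,
)
from eegclean.params import NoisyChannelParams

from conftest import make_field_recording

FS = 200.0


def _sorted_quantile_oracle(x, q):
    """Brute-force linear-interpolation quantile on sorted order statistics."""
    s = np.sort(np.asarray(x, dtype=float))
    h = (len(s) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


class TestRobustStats:
    def test_constant_vector(self):
        assert robust_sd(np.full(50, 3.3)) == 0.0

    def test_against_quantile_oracle(self):
        x = np.arange(1.0, 101.0)
        expected = 0.7413 * (
            _sorted_quantile_oracle(x, 0.75) - _sorted_quantile_oracle(x, 0.25)
        )
        assert robust_sd(x) == pytest.approx(expected, abs=1e-12)

    def test_standard_normal_consistency(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        assert robust_sd(x) == pytest.approx(1.0, rel=0.02)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            robust_sd([1.0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=200))
    def test_matches_oracle_property(self, values):
        x = np.array(values)
        expected = 0.7413 * (
            _sorted_quantile_oracle(x, 0.75) - _sorted_quantile_oracle(x, 0.25)
        )
        assert robust_sd(x) == pytest.approx(expected, abs=1e-9 * max(1, np.abs(x).max()))

    def test_robust_z_median_element(self):
        z, degenerate = robust_z([1.0, 2.0, 3.0, 4.0, 5.0])
        assert not degenerate
        assert z[2] == 0.0

    def test_robust_z_outlier(self):
        v = np.array([1.0, 1.1, 0.9, 1.0, 101.0])
        z, _ = robust_z(v)
        med = np.median(v)
        expected = (101.0 - med) / robust_sd(v)
        assert z[-1] == pytest.approx(expected, rel=1e-12)
        assert z[-1] > 100

    def test_robust_z_degenerate(self):
        z, degenerate = robust_z(np.ones(10))
        assert degenerate
        np.testing.assert_array_equal(z, 0.0)

    def test_mad(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        assert mad(x) == np.median(np.abs(x - 3.0))


class TestNanNoData:
    def test_nan_channel(self, field_recording):
        data = field_recording.data.copy()
        data[4, 1000] = np.nan
        rec = field_recording.with_data(data)
        sets = detect_nan_nodata(rec)
        assert sets["nan"] == {field_recording.montage.labels[4]}

    def test_all_zero_channel(self, field_recording):
        data = field_recording.data.copy()
        data[6] = 0.0
        sets = detect_nan_nodata(field_recording.with_data(data))
        assert sets["nodata"] == {field_recording.montage.labels[6]}

    def test_partially_flat_channel(self, field_recording):
        data = field_recording.data.copy()
        data[2, : data.shape[1] // 2] = 7.0  # half the windows exactly constant
        sets = detect_nan_nodata(field_recording.with_data(data))
        assert field_recording.montage.labels[2] in sets["nodata"]

    def test_clean_channels_pass(self, field_recording):
        sets = detect_nan_nodata(field_recording)
        assert not sets["nan"] and not sets["nodata"]


class TestDeviation:
    def test_high_amplitude_channel_flagged(self, cap32, rng):
        data = 10.0 * rng.standard_normal((32, 4000))
        data[9] *= 8.0
        rec = Recording(data, FS, cap32)
        bad, wz, info = detect_deviation(rec)
        assert bad == {cap32.labels[9]}
        assert info["z"][9] > 5.0
        assert wz.shape == (32, 20)

    def test_identical_variance_channels_empty(self, cap32, rng):
        rec = Recording(10.0 * rng.standard_normal((32, 4000)), FS, cap32)
        bad, _, _ = detect_deviation(rec)
        assert bad == frozenset()

    def test_degenerate_spread_flagged_not_bad(self, cap32):
        t = np.arange(4000) / FS
        data = np.tile(np.sin(2 * np.pi * 3 * t), (32, 1))
        bad, _, info = detect_deviation(Recording(data, FS, cap32))
        assert bad == frozenset()
        assert info["degenerate"]

    def test_default_threshold_is_five(self):
        assert NoisyChannelParams().robust_deviation_threshold == 5.0


class TestCorrelationDropout:
    def test_shuffled_channel_flagged(self, cap32):
        rec = make_field_recording(cap32, n_samples=8000, seed=5)
        data = rec.data.copy()
        data[11] = np.random.default_rng(0).permutation(data[11])
        bad, _, maxcorr, _ = detect_correlation_dropout(rec.with_data(data))
        assert cap32.labels[11] in bad
        assert maxcorr.shape == (32, 40)
        assert np.all((maxcorr >= 0) & (maxcorr <= 1))

    def test_common_signal_high_correlation(self, cap32, rng):
        t = np.arange(4000) / FS
        common = np.sin(2 * np.pi * 7 * t)
        data = np.outer(np.linspace(5, 10, 32), common)
        data += 0.01 * rng.standard_normal(data.shape)
        bad, _, maxcorr, _ = detect_correlation_dropout(Recording(data, FS, cap32))
        assert bad == frozenset()
        assert np.nanmean(maxcorr) > 0.99

    def test_boundary_fraction_not_flagged(self, cap32, rng):
        # bad in exactly 1% of windows -> strict > comparison keeps it clean
        rec = make_field_recording(cap32, n_samples=20_000, seed=6)  # 100 windows
        data = rec.data.copy()
        data[3, :200] = 30.0 * rng.standard_normal(200)  # 1 window decorrelated
        bad, _, maxcorr, _ = detect_correlation_dropout(rec.with_data(data))
        assert np.sum(maxcorr[3] < 0.4) == 1
        assert cap32.labels[3] not in bad
        # two bad windows (2%) -> flagged
        data[3, 200:400] = 30.0 * rng.standard_normal(200)
        bad2, _, mc2, _ = detect_correlation_dropout(rec.with_data(data))
        assert np.sum(mc2[3] < 0.4) == 2
        assert cap32.labels[3] in bad2

    def test_dropout_windows(self, cap32):
        rec = make_field_recording(cap32, n_samples=8000, seed=8)
        data = rec.data.copy()
        data[7, 1000:2000] = 0.0  # 5 of 40 windows dead
        bad_corr, bad_drop, _, flags = detect_correlation_dropout(
            rec.with_data(data), lowpassed=True
        )
        assert cap32.labels[7] in bad_drop
        assert flags[7].sum() == 5

    def test_single_channel_error(self, cap32):
        rec = Recording(np.random.default_rng(0).standard_normal((32, 400)), FS, cap32,
                        evaluation_channels=("Cz",))
        with pytest.raises(ValueError, match="2 channels"):
            detect_correlation_dropout(rec)


class TestHFNoise:
    def test_noisy_channel_flagged(self, cap32):
        rec = make_field_recording(cap32, n_samples=8000, seed=9)
        data = rec.data.copy()
        rng = np.random.default_rng(1)
        hf = rng.standard_normal(8000)
        hf = hf - np.convolve(hf, np.ones(9) / 9, "same")  # crude high-pass
        data[13] += 8.0 * data[13].std() * hf / hf.std()
        bad, wz, info = detect_hf_noise(rec.with_data(data))
        assert cap32.labels[13] in bad
        assert info["z"][13] > 5.0
        assert wz.shape == (32, 40)

    def test_identical_spectra_empty(self, cap32):
        rec = make_field_recording(cap32, n_samples=8000, seed=10)
        bad, _, _ = detect_hf_noise(rec)
        assert bad == frozenset()

    def test_low_fs_error(self, cap32):
        rec = Recording(np.random.default_rng(0).standard_normal((32, 400)), 100.0, cap32)
        with pytest.raises(ValueError, match="50"):
            detect_hf_noise(rec)

    def test_default_threshold_is_five(self):
        assert NoisyChannelParams().hf_noise_threshold == 5.0


class TestRansac:
    def test_alien_channel_flagged(self, cap32):
        rec = make_field_recording(cap32, n_samples=10_000, seed=12)
        data = rec.data.copy()
        data[20] = data[20].std() * np.random.default_rng(3).standard_normal(10_000)
        bad, corr, info = detect_ransac(rec.with_data(data), rng=0)
        assert cap32.labels[20] in bad
        assert not info["terminated"]

    def test_spline_consistent_channel_passes(self, cap32):
        from eegclean.interpolation import SplineModel, build_interpolation_matrix

        rec = make_field_recording(cap32, n_samples=10_000, seed=13)
        data = rec.data.copy()
        mont = cap32.normalized()
        others = [i for i in range(32) if i != 5]
        w = build_interpolation_matrix(
            SplineModel(mont.positions[others], mont.positions[[5]])
        )
        data[5] = (w @ data[others])[0]
        bad, corr, _ = detect_ransac(rec.with_data(data), rng=0)
        assert cap32.labels[5] not in bad
        assert np.nanmin(corr[5]) > 0.95

    def test_deterministic_given_seed(self, cap32):
        rec = make_field_recording(cap32, n_samples=6000, seed=14)
        a = detect_ransac(rec, rng=42)
        b = detect_ransac(rec, rng=42)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])

    def test_termination_with_too_few_channels(self, cap32):
        rec = make_field_recording(cap32, n_samples=6000, seed=15)
        keep = cap32.labels[:6]
        small = Recording(rec.data, FS, cap32, evaluation_channels=keep)
        bad, _, info = detect_ransac(small, exclude=set(keep[:4]), rng=0)
        assert bad == frozenset()
        assert info["terminated"]


class TestFindNoisyChannels:
    def test_clean_recording_all_empty(self, cap32):
        rec = make_field_recording(cap32, n_samples=12_000, seed=16)
        result = find_noisy_channels(rec, rng=0)
        assert result.all_bad == frozenset()
        w = 12_000 // int(FS)
        assert result.stats.max_correlation.shape == (32, w)
        assert result.stats.deviation_z.shape == (32, w)
        assert result.stats.noise_z.shape == (32, w)

    def test_low_amplitude_channel_detected(self, cap32):
        rec = make_field_recording(cap32, n_samples=12_000, seed=17)
        data = rec.data.copy()
        data[8] = 0.1 * data[8]
        result = find_noisy_channels(rec.with_data(data), rng=0)
        label = cap32.labels[8]
        assert label in result.all_bad
        # pure rescaling leaves correlation and HF ratio invariant, so the
        # catch is the (two-sided) deviation criterion
        assert label in result.bad_by["deviation"]

    def test_white_noise_channel_becomes_low_snr(self, cap32):
        rec = make_field_recording(cap32, n_samples=12_000, seed=18)
        data = rec.data.copy()
        # low-amplitude broadband noise: uncorrelated AND noisy -> lowSNR
        data[25] = 0.5 * np.random.default_rng(4).standard_normal(12_000)
        result = find_noisy_channels(rec.with_data(data), rng=0)
        label = cap32.labels[25]
        assert label in result.bad_by["correlation"]
        assert label in result.bad_by["hf_noise"]
        assert label in result.bad_by["low_snr"]
        assert label in result.unusable

    def test_low_snr_subset_invariant(self, cap32):
        rec = make_field_recording(cap32, n_samples=12_000, seed=19)
        data = rec.data.copy()
        data[1] = 0.3 * np.random.default_rng(5).standard_normal(12_000)
        result = find_noisy_channels(rec.with_data(data), rng=0)
        assert result.bad_by["low_snr"] <= (
            result.bad_by["correlation"] & result.bad_by["hf_noise"]
        )

    def test_category_sets_within_evaluation_channels(self, cap32):
        rec = make_field_recording(cap32, n_samples=8000, seed=20)
        eval_ch = cap32.labels[:20]
        rec = Recording(rec.data, FS, cap32, evaluation_channels=eval_ch)
        result = find_noisy_channels(rec, rng=0)
        for chans in result.bad_by.values():
            assert chans <= set(eval_ch)

    def test_determinism(self, cap32):
        rec = make_field_recording(cap32, n_samples=8000, seed=21)
        data = rec.data.copy()
        data[3] *= 9.0
        a = find_noisy_channels(rec.with_data(data), rng=7)
        b = find_noisy_channels(rec.with_data(data), rng=7)
        assert a.bad_by == b.bad_by

    def test_monotone_in_artifact_amplitude(self, cap32):
        rec = make_field_recording(cap32, n_samples=8000, seed=22)
        noise = np.random.default_rng(6).standard_normal(8000)
        flagged = []
        for mult in (4.0, 8.0, 16.0):
            data = rec.data.copy()
            data[10] = data[10] + mult * data[10].std() * noise
            result = find_noisy_channels(rec.with_data(data), rng=0)
            flagged.append(cap32.labels[10] in result.all_bad)
        assert flagged == sorted(flagged)  # never un-flags as amplitude grows
        assert flagged[-1]

    def test_nan_channel_excluded_from_later_criteria(self, cap32):
        rec = make_field_recording(cap32, n_samples=8000, seed=23)
        data = rec.data.copy()
        data[0, 5] = np.nan
        result = find_noisy_channels(rec, rng=0)
        result_nan = find_noisy_channels(rec.with_data(data), rng=0)
        label = cap32.labels[0]
        assert label in result_nan.bad_by["nan"]
        assert label in result_nan.unusable
        for cat in ("deviation", "correlation", "hf_noise", "ransac", "low_snr"):
            assert label not in result_nan.bad_by[cat]
        assert np.all(np.isnan(result_nan.stats.max_correlation[0]))
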