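import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import fft_band_ratios, sampen_bruteforce, sampen_matrix

from eegattn._wpd import leaf_energies, wavelet_filters
from eegattn.features import (
    SampEnParams,
    WpdParams,
    extract_features,
    sample_entropy,
    time_domain_features,
    wpd_band_ratios,
)
from eegattn.preprocess import Epoch

FS = 512.0


class TestTimeDomain:
    def test_printed_formulas_on_small_vector(self):
        f1, f2, f3, f4, f5, f6 = time_domain_features(np.array([1.0, -1.0, 2.0, -2.0]))
        assert f1 == 1.5
        assert f2 == 2.0
        assert f3 == 4.0
        assert f4 == pytest.approx(math.sqrt(2.5))
        assert f5 == pytest.approx(math.sqrt(2.5))
        expected_f6 = 2.0 / ((1 + 1 + math.sqrt(2) + math.sqrt(2)) / 4) ** 2
        assert f6 == pytest.approx(expected_f6)

    def test_constant_vector(self):
        c = 3.0
        f1, f2, f3, f4, f5, f6 = time_domain_features(np.full(4, c))
        assert (f1, f2, f3, f4, f5) == (c, c, 0.0, c, 0.0)
        assert f6 == pytest.approx(1.0)

    def test_all_zero_margin_factor_nan(self):
        f6 = time_domain_features(np.zeros(8))[5]
        assert math.isnan(f6)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_variance_identity(self, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        _, _, _, f4, f5, _ = time_domain_features(x)
        assert f4**2 == pytest.approx(f5**2 + x.mean() ** 2, rel=1e-9)

    def test_too_short(self):
        with pytest.raises(ValueError):
            time_domain_features(np.array([1.0]))


class TestSampleEntropy:
    def test_matches_bruteforce_oracle_many_windows(self):
        # exact count agreement, not tolerance: 50 random windows
        params = SampEnParams(m=2, r_factor=0.2)
        rng = np.random.default_rng(42)
        for _ in range(50):
            x = rng.standard_normal(120)
            r = params.r_factor * x.std()
            expected = sampen_bruteforce(x, params.m, r)
            assert sample_entropy(x, params) == pytest.approx(
                expected, abs=0.0, rel=1e-12
            )

    def test_matches_matrix_oracle_full_window(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(2048)
        params = SampEnParams(m=2, r_factor=0.2)
        expected = sampen_matrix(x, 2, 0.2 * x.std())
        assert sample_entropy(x, params) == expected

    @pytest.mark.parametrize("m", [1, 3])
    def test_other_embedding_dimensions(self, m):
        rng = np.random.default_rng(m)
        x = rng.standard_normal(100)
        params = SampEnParams(m=m, r_factor=0.25)
        expected = sampen_bruteforce(x, m, 0.25 * x.std())
        assert sample_entropy(x, params) == pytest.approx(expected, rel=1e-12)

    def test_all_templates_match_gives_zero(self):
        rng = np.random.default_rng(0)
        x = 1.0 + 1e-6 * rng.standard_normal(64)
        # huge tolerance: every template pair matches at both lengths
        assert sample_entropy(x, SampEnParams(m=2, r_factor=1e6)) == 0.0

    def test_white_noise_more_complex_than_tone(self):
        t = np.arange(512) / FS
        tone = np.sin(2 * np.pi * 10.0 * t)
        params = SampEnParams()
        for seed in range(20):
            noise = np.random.default_rng(seed).standard_normal(512)
            assert sample_entropy(noise, params) > sample_entropy(tone, params)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            sample_entropy(np.ones(64))

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, 2.0, 3.0]), SampEnParams(m=2))


class TestWpd:
    def test_filters_are_orthonormal(self):
        for name in ("db1", "db2", "db4", "db8"):
            h, g = wavelet_filters(name)
            assert np.dot(h, h) == pytest.approx(1.0, abs=1e-12)
            assert np.dot(g, g) == pytest.approx(1.0, abs=1e-12)
            assert np.dot(h, g) == pytest.approx(0.0, abs=1e-12)

    def test_energy_conservation(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.standard_normal(2048)
            energies = leaf_energies(x, 7, "db8")
            assert energies.sum() == pytest.approx(np.sum(x * x), rel=1e-8)

    def test_tone_lands_in_expected_leaf(self):
        t = np.arange(2048) / FS
        for freq in (5.0, 11.0, 21.0, 29.0):
            energies = leaf_energies(np.sin(2 * np.pi * freq * t), 7, "db8")
            assert energies.argmax() == int(freq // 2.0)  # 2 Hz leaves

    def test_alpha_tone_ratios(self):
        t = np.arange(2048) / FS
        theta, alpha, beta = wpd_band_ratios(np.sin(2 * np.pi * 10.0 * t), FS)
        assert alpha == max(theta, alpha, beta)
        assert alpha >= 0.8

    def test_beta_tone_ratios(self):
        t = np.arange(2048) / FS
        theta, alpha, beta = wpd_band_ratios(np.sin(2 * np.pi * 20.0 * t), FS)
        assert beta == max(theta, alpha, beta)

    def test_agreement_with_fft_oracle(self):
        t = np.arange(2048) / FS
        for freq in (5.0, 6.0, 10.0, 11.0, 20.0, 25.0):
            x = np.sin(2 * np.pi * freq * t)
            wpd = wpd_band_ratios(x, FS)
            fft = fft_band_ratios(x, FS)
            for got, expected in zip(wpd, fft):
                assert got == pytest.approx(expected, abs=0.1), freq

    def test_zero_energy_errors(self):
        with pytest.raises(ValueError):
            wpd_band_ratios(np.zeros(2048), FS)

    def test_short_signal_errors(self):
        with pytest.raises(ValueError):
            wpd_band_ratios(np.ones(64), FS, WpdParams(level=7, fs=FS))

    def test_band_map_validation(self):
        with pytest.raises(ValueError):
            WpdParams(level=3, fs=FS, band_map={"theta": (1,), "alpha": (1,)})
        with pytest.raises(ValueError):
            WpdParams(level=3, fs=FS, band_map={"theta": (99,), "alpha": (), "beta": ()})


def make_epoch(data, labels=None, label=1):
    labels = labels or tuple(f"ch{i}" for i in range(data.shape[0]))
    return Epoch(
        data=data,
        fs=FS,
        channel_labels=labels,
        label=label,
        subject_id="S01",
        session_id=1,
        start_index=0,
    )


@pytest.fixture(scope="module")
def epoch10():
    rng = np.random.default_rng(5)
    return make_epoch(10.0 * rng.standard_normal((10, 2048)))


class TestExtractFeatures:
    def test_vector_length_100(self, epoch10):
        vec = extract_features(epoch10)
        assert vec.values.shape == (100,)
        assert np.all(np.isfinite(vec.values))

    def test_feature_major_layout_and_ranges(self, epoch10):
        vec = extract_features(epoch10)
        per = vec.values.reshape(10, 10)  # features x channels
        assert np.all(per[2] >= 0)  # F3 peak difference
        assert np.all(per[3] >= 0)  # F4 rms
        assert np.all(per[4] >= 0)  # F5 std
        ratios = per[7] + per[8] + per[9]
        assert np.all(per[7:10] >= 0) and np.all(per[7:10] <= 1)
        assert np.all(ratios <= 1.0)

    def test_duplicated_channel_duplicates_entries(self):
        rng = np.random.default_rng(6)
        x = 10.0 * rng.standard_normal(2048)
        data = np.stack([x, x.copy()])
        vec = extract_features(make_epoch(data, labels=("a", "b")))
        per = vec.values.reshape(10, 2)
        np.testing.assert_array_equal(per[:, 0], per[:, 1])

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        data = 10.0 * rng.standard_normal((3, 2048))
        vec = extract_features(make_epoch(data, labels=("a", "b", "c")))
        perm = extract_features(make_epoch(data[::-1].copy(), labels=("c", "b", "a")))
        np.testing.assert_array_equal(
            vec.values.reshape(10, 3)[:, ::-1], perm.values.reshape(10, 3)
        )

    def test_scaling_invariances(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((1, 2048))
        c = 4.0  # power of two: exact float scaling
        base = extract_features(make_epoch(x)).values.reshape(10, 1)[:, 0]
        scaled = extract_features(make_epoch(c * x)).values.reshape(10, 1)[:, 0]
        for k in (0, 1, 2, 3, 4):  # F1..F5 scale linearly
            assert scaled[k] == pytest.approx(c * base[k], rel=1e-12)
        for k in (5, 6, 7, 8, 9):  # F6, SampEn, band ratios invariant
            assert scaled[k] == pytest.approx(base[k], rel=1e-9)

    def test_determinism(self, epoch10):
        a = extract_features(epoch10).values
        b = extract_features(epoch10).values
        np.testing.assert_array_equal(a, b)

    def test_error_names_channel(self):
        data = np.vstack([np.random.default_rng(0).standard_normal((1, 2048)),
                          np.zeros((1, 2048))])
        with pytest.raises(ValueError, match="bad_ch"):
            extract_features(make_epoch(data, labels=("ok", "bad_ch")))

    def test_monotone_beta_ratio_across_states(self, cohort_features):
        f10_cols = [c for c in cohort_features.columns if c.startswith("F10_")]
        means = cohort_features.groupby("label")[f10_cols].mean().mean(axis=1)
        per_state = cohort_features.groupby("label").size()
        assert (per_state >= 100).all()
        assert means[1] > means[2] > means[3] > means[4]
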