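"""Per-window characteristics against closed forms and a brute-force DFT oracle."""

import numpy as np
import pytest

from ovinesense.features import (
    BASE_FEATURE_NAMES,
    FEATURE_NAMES,
    FeatureConfig,
    compute_spectrum,
    dominant_and_harmonic_frequencies,
    extract_features,
    harmonic_ratio,
    signal_area,
    spectral_area,
    spectral_entropy,
    time_domain_stats,
    zero_crossings,
)
from ovinesense.preprocess import AnnotatedWindow

F_S = 16.0


def brute_force_spectrum(x, f_s):
    """Independent O(n²) DFT oracle: explicit correlation sums per bin."""
    x = np.asarray(x, float)
    n = len(x)
    n_bins = n // 2 + 1
    amps = np.zeros(n_bins)
    for k in range(n_bins):
        re = sum(x[m] * np.cos(-2 * np.pi * k * m / n) for m in range(n))
        im = sum(x[m] * np.sin(-2 * np.pi * k * m / n) for m in range(n))
        amps[k] = np.hypot(re, im)
    psd = amps**2 / (n * f_s)
    return amps, psd, f_s / n


def make_window(accel, gyro=None):
    accel = np.asarray(accel, float)
    gyro = accel.copy() if gyro is None else np.asarray(gyro, float)
    return AnnotatedWindow(
        sheep_id="s", window_index=0, samples_accel_diff=accel,
        samples_gyro_diff=gyro, activity="walking", lame=False, lameness_score=0,
    )


class TestTimeDomain:
    def test_hand_computed_quartet(self):
        stats = time_domain_stats(np.array([1.0, 2, 3, 4]))
        assert stats["mean"] == 2.5
        assert stats["min"] == 1 and stats["max"] == 4
        assert stats["interquantile_range"] == pytest.approx(1.5)
        assert stats["median"] == 2.5

    def test_constant_window_degenerate_conventions(self):
        stats = time_domain_stats(np.full(10, 3.3))
        assert stats["std"] == 0 and stats["skewness"] == 0 and stats["kurtosis"] == 0

    def test_symmetric_window_has_zero_skewness(self):
        assert time_domain_stats(np.array([-2.0, -1, 1, 2]))["skewness"] == pytest.approx(0)

    def test_population_moments_match_direct_formula(self, rng):
        x = rng.normal(size=50)
        stats = time_domain_stats(x)
        c = x - x.mean()
        assert stats["std"] == pytest.approx(np.sqrt(np.mean(c**2)))
        assert stats["skewness"] == pytest.approx(np.mean(c**3) / np.mean(c**2) ** 1.5)
        assert stats["kurtosis"] == pytest.approx(np.mean(c**4) / np.mean(c**2) ** 2 - 3)


class TestZeroCrossings:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, -1, 1, -1], 3),
            ([5, 5, 5, 5], 0),
            ([1, 0, -1], 1),  # exact zero carries the previous sign
        ],
    )
    def test_known_patterns(self, values, expected):
        assert zero_crossings(np.array(values, float)) == expected

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            x = rng.integers(-3, 4, size=30).astype(float)
            centred = x - x.mean()
            signs = [s for s in np.sign(centred) if s != 0]
            oracle = sum(a != b for a, b in zip(signs, signs[1:]))
            assert zero_crossings(x) == oracle


class TestSignalArea:
    def test_constant_window(self):
        assert signal_area(np.full(112, 0.5), F_S) == pytest.approx(3.5)

    def test_null_signal(self):
        assert signal_area(np.zeros(10), F_S) == 0

    def test_alternating_signs_use_absolute_value(self):
        assert signal_area(np.array([1.0, -1, 1, -1]), F_S) == pytest.approx(0.25)

    def test_signed_variant_behind_config(self):
        cfg = FeatureConfig(signal_area_absolute=False)
        assert signal_area(np.array([1.0, -1, 1, -1]), F_S, cfg) == pytest.approx(0.0)


class TestSpectrum:
    def test_pure_cosine_concentrates_in_its_bin(self):
        n, k = 112, 14
        x = np.cos(2 * np.pi * k * np.arange(n) / n)
        sp = compute_spectrum(x, F_S)
        peak = sp.psd[k]
        others = np.delete(sp.psd, k)
        assert others.max() <= 1e-10 * peak

    def test_parseval_against_time_domain_power(self, rng):
        x = rng.normal(size=112)
        sp = compute_spectrum(x, F_S)
        one_sided = sp.psd.copy()
        one_sided[1:-1] *= 2  # interior doubling; DC and Nyquist once (even n)
        assert np.sum(one_sided) * sp.delta_f == pytest.approx(np.mean(x**2), rel=1e-6)

    def test_bin_layout_for_7s_window(self, rng):
        sp = compute_spectrum(rng.normal(size=112), F_S)
        assert sp.delta_f == pytest.approx(1 / 7)
        assert sp.n_bins == 57
        assert sp.frequencies[-1] == pytest.approx(8.0)

    def test_psd_norm_sums_to_one(self, rng):
        sp = compute_spectrum(rng.normal(size=112), F_S)
        assert sp.psd_norm.sum() == pytest.approx(1.0, abs=1e-9)


class TestSpectralEntropy:
    def test_single_bin_spectrum_is_zero(self):
        n, k = 112, 10
        x = np.cos(2 * np.pi * k * np.arange(n) / n)
        assert spectral_entropy(compute_spectrum(x, F_S)) == pytest.approx(0, abs=1e-9)

    def test_flat_psd_reaches_log_n(self):
        sp = compute_spectrum(np.zeros(112), F_S)
        sp.degenerate = False
        sp.psd_norm = np.full(sp.n_bins, 1 / sp.n_bins)
        assert spectral_entropy(sp) == pytest.approx(np.log(sp.n_bins))

    def test_two_equal_bins_give_log_two(self):
        sp = compute_spectrum(np.zeros(112), F_S)
        sp.degenerate = False
        p = np.zeros(sp.n_bins)
        p[[3, 9]] = 0.5
        sp.psd_norm = p
        assert spectral_entropy(sp) == pytest.approx(np.log(2))

    def test_amplitude_scaling_invariance(self, rng):
        x = rng.normal(size=112)
        se1 = spectral_entropy(compute_spectrum(x, F_S))
        se2 = spectral_entropy(compute_spectrum(7.3 * x, F_S))
        assert se1 == pytest.approx(se2)


class TestDominantFrequencies:
    def test_cosine_at_2hz(self):
        n = 112
        t = np.arange(n) / F_S
        x = np.cos(2 * np.pi * 2.0 * t)
        dom = dominant_and_harmonic_frequencies(compute_spectrum(x, F_S))
        assert dom[0] == pytest.approx(2.0)

    def test_three_cosines_ordered_by_amplitude(self):
        n = 112
        m = np.arange(n)
        x = (
            3 * np.cos(2 * np.pi * 14 * m / n)
            + 2 * np.cos(2 * np.pi * 7 * m / n)
            + 1 * np.cos(2 * np.pi * 21 * m / n)
        )
        dom = dominant_and_harmonic_frequencies(compute_spectrum(x, F_S))
        assert dom == pytest.approx((2.0, 1.0, 3.0))

    def test_flat_spectrum_tie_breaks_toward_low_frequency(self):
        sp = compute_spectrum(np.zeros(112), F_S)
        sp.degenerate = False
        sp.psd = np.ones(sp.n_bins)
        dom = dominant_and_harmonic_frequencies(sp)
        assert dom == pytest.approx((sp.delta_f, 2 * sp.delta_f, 3 * sp.delta_f))

    def test_degenerate_spectrum_returns_zeros(self):
        assert dominant_and_harmonic_frequencies(compute_spectrum(np.zeros(112), F_S)) == (0, 0, 0)


class TestSpectralArea:
    def test_null_window(self):
        assert spectral_area(compute_spectrum(np.zeros(112), F_S)) == 0

    def test_white_noise_spa_approximates_variance(self, rng):
        spas, var = [], 0.7**2
        for _ in range(200):
            x = rng.normal(0, 0.7, size=112)
            spas.append(spectral_area(compute_spectrum(x, F_S)))
        assert np.mean(spas) == pytest.approx(var, rel=0.1)

    def test_doubling_amplitude_quadruples_spa(self, rng):
        x = rng.normal(size=112)
        a = spectral_area(compute_spectrum(x, F_S))
        b = spectral_area(compute_spectrum(2 * x, F_S))
        assert b == pytest.approx(4 * a)


class TestHarmonicRatio:
    def test_even_bin_cosine_gives_large_ratio(self):
        n = 112
        x = np.cos(2 * np.pi * 14 * np.arange(n) / n)  # bin 14, even index
        assert harmonic_ratio(compute_spectrum(x, F_S)) > 100

    def test_odd_bin_cosine_gives_small_ratio(self):
        n = 112
        x = np.cos(2 * np.pi * 13 * np.arange(n) / n)
        assert harmonic_ratio(compute_spectrum(x, F_S)) < 0.01

    def test_all_zero_window_is_zero(self):
        assert harmonic_ratio(compute_spectrum(np.zeros(112), F_S)) == 0

    def test_dominant_multiple_variant_behind_config(self):
        n = 112
        m = np.arange(n)
        # fundamental at bin 13 (odd) plus second harmonic at bin 26
        x = 2 * np.cos(2 * np.pi * 13 * m / n) + 1 * np.cos(2 * np.pi * 26 * m / n)
        cfg = FeatureConfig(harmonic_ratio_bins=False)
        hr = harmonic_ratio(compute_spectrum(x, F_S), cfg)
        assert hr == pytest.approx(0.5, abs=0.01)


class TestExtractFeatures:
    def test_vector_has_32_finite_entries(self, rng):
        w = make_window(rng.normal(size=112), rng.normal(size=112))
        feats = extract_features(w, F_S)
        assert list(feats) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in feats.values())

    def test_modalities_are_independent(self, rng):
        gyro = rng.normal(size=112)
        w = make_window(np.zeros(112), gyro)
        feats = extract_features(w, F_S)
        assert all(feats[f"accel_{n}"] == 0 for n in BASE_FEATURE_NAMES)
        normal = extract_features(make_window(gyro, gyro), F_S)
        assert all(feats[f"gyro_{n}"] == normal[f"gyro_{n}"] for n in BASE_FEATURE_NAMES)

    def test_identical_windows_identical_vectors(self, rng):
        x = rng.normal(size=112)
        assert extract_features(make_window(x), F_S) == extract_features(make_window(x.copy()), F_S)

    def test_signal_area_linear_in_amplitude(self, rng):
        x = rng.normal(size=112)
        f1 = extract_features(make_window(x), F_S)
        f3 = extract_features(make_window(3 * x), F_S)
        assert f3["accel_signal_area"] == pytest.approx(3 * f1["accel_signal_area"])
        assert f3["accel_spectral_area"] == pytest.approx(9 * f1["accel_spectral_area"])
        assert f3["accel_spectral_entropy"] == pytest.approx(f1["accel_spectral_entropy"])


class TestBruteForceOracle:
    """Spectral features recomputed from an explicit O(n²) DFT."""

    def oracle_features(self, x, f_s):
        amps, psd, delta_f = brute_force_spectrum(x, f_s)
        total = psd.sum()
        p = psd / total
        p = p[p > 0]
        se = -np.sum(p * np.log(p))
        power = psd[1:]
        freqs = np.arange(1, len(psd)) * delta_f
        order = np.lexsort((freqs, -power))[:3]
        dom = tuple(freqs[i] for i in order)
        spa = 2 * delta_f * psd[1:].sum()
        hr = amps[2::2].sum() / amps[1::2].sum()
        return se, dom, spa, hr

    def test_sinusoid_mixture_agrees_to_1e8(self, rng):
        n = 112
        m = np.arange(n)
        x = (
            1.3 * np.cos(2 * np.pi * 9 * m / n + 0.4)
            + 0.7 * np.sin(2 * np.pi * 23 * m / n)
            + 0.1 * rng.normal(size=n)
        )
        sp = compute_spectrum(x, F_S)
        se, dom, spa, hr = self.oracle_features(x, F_S)
        assert spectral_entropy(sp) == pytest.approx(se, rel=1e-8)
        assert dominant_and_harmonic_frequencies(sp) == pytest.approx(dom, rel=1e-8)
        assert spectral_area(sp) == pytest.approx(spa, rel=1e-8)
        assert harmonic_ratio(sp) == pytest.approx(hr, rel=1e-8)
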