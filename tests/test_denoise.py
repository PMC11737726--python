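"""Haar/db1 wavelet transform: hand-derived cases, perfect reconstruction,
orthonormality, brute-force oracle equivalence, thresholding, denoising."""

import numpy as np
import pytest
import pywt
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import coopvox as cv
from coopvox.denoise import ThresholdPolicy, WaveletCoeffs

SQRT2 = np.sqrt(2.0)


def brute_force_haar_level(x):
    """Evaluate the two summation equations directly, with periodic
    indexing and no filter-bank shortcuts."""
    h = np.array([1.0, 1.0]) / SQRT2
    g = np.array([1.0, -1.0]) / SQRT2
    n = len(x)
    a = np.array([sum(h[k] * x[(2 * m + k) % n] for k in range(2))
                  for m in range(n // 2)])
    d = np.array([sum(g[k] * x[(2 * m + k) % n] for k in range(2))
                  for m in range(n // 2)])
    return a, d


class TestDecompose:
    def test_hand_case_1234(self):
        c = cv.dwt_decompose([1, 2, 3, 4], "db1", levels=1)
        np.testing.assert_allclose(c.approx, [3 / SQRT2, 7 / SQRT2])
        np.testing.assert_allclose(c.details[0], [-1 / SQRT2, -1 / SQRT2])

    @pytest.mark.parametrize("levels", [1, 2, 3])
    def test_constant_signal_has_zero_details(self, levels):
        c = cv.dwt_decompose(np.full(32, 3.7), "db1", levels=levels)
        for d in c.details:
            np.testing.assert_allclose(d, 0, atol=1e-12)

    @pytest.mark.parametrize("n,levels", [(8, 1), (16, 2), (64, 3), (1024, 4)])
    def test_energy_conservation(self, n, levels, rng):
        x = rng.standard_normal(n)
        c = cv.dwt_decompose(x, "db1", levels=levels)
        energy = np.sum(c.approx ** 2) + sum(np.sum(d ** 2) for d in c.details)
        assert energy == pytest.approx(np.sum(x ** 2), rel=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        for n in (4, 6, 8, 16, 32, 64):
            x = rng.standard_normal(n)
            a_ref, d_ref = brute_force_haar_level(x)
            c = cv.dwt_decompose(x, "db1", levels=1)
            np.testing.assert_allclose(c.approx, a_ref, atol=1e-12)
            np.testing.assert_allclose(c.details[0], d_ref, atol=1e-12)

    def test_matches_pywt_periodization(self, rng):
        # independent implementation cross-check (pywt's db1 convolution
        # realizes the same Haar difference, so coefficients match exactly)
        x = rng.standard_normal(256)
        ours = cv.dwt_decompose(x, "db1", levels=3)
        ref = pywt.wavedec(x, "db1", mode="periodization", level=3)
        np.testing.assert_allclose(ours.approx, ref[0], atol=1e-10)
        for our_d, ref_d in zip(ours.details, ref[:0:-1]):
            np.testing.assert_allclose(our_d, ref_d, atol=1e-10)

    def test_too_deep_raises_with_max_level(self):
        with pytest.raises(ValueError, match="maximum level is 3"):
            cv.dwt_decompose(np.arange(10.0), "db1", levels=4)
        with pytest.raises(ValueError):
            cv.dwt_decompose(np.arange(8.0), "db1", levels=0)

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ValueError, match="wavelet"):
            cv.dwt_decompose(np.arange(8.0), "sym4", levels=1)


class TestReconstruct:
    @pytest.mark.parametrize("n,levels", [(4, 1), (10, 2), (37, 3), (1024, 4)])
    def test_perfect_reconstruction(self, n, levels, rng):
        x = rng.standard_normal(n)
        back = cv.dwt_reconstruct(cv.dwt_decompose(x, "db1", levels=levels))
        assert len(back) == n
        np.testing.assert_allclose(back, x, rtol=1e-9, atol=1e-12)

    def test_zeroed_detail_hand_case(self):
        c = cv.dwt_decompose([1, 2, 3, 4], "db1", levels=1)
        c.details[0] = np.zeros(2)
        np.testing.assert_allclose(cv.dwt_reconstruct(c),
                                   [1.5, 1.5, 3.5, 3.5])

    def test_level_size_mismatch_raises(self):
        c = cv.dwt_decompose(np.arange(16.0), "db1", levels=2)
        c.details[0] = c.details[0][:-1]
        with pytest.raises(ValueError, match="length"):
            cv.dwt_reconstruct(c)


class TestSigma:
    def test_definition_cases(self):
        assert cv.estimate_sigma(np.zeros(5)) == 0.0
        assert cv.estimate_sigma([-0.6745, 0.6745]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            cv.estimate_sigma([])

    def test_gaussian_consistency(self):
        d = np.random.default_rng(1).normal(0, 2.0, size=100_000)
        assert cv.estimate_sigma(d) == pytest.approx(2.0, rel=0.02)


class TestThreshold:
    def _coeffs(self, details):
        return WaveletCoeffs(approx=np.array([5.0]),
                             details=[np.asarray(details, dtype=float)],
                             levels=1, wavelet_name="db1", original_length=8,
                             pad_flags=[False])

    def test_hard_and_soft_definitions(self):
        c = self._coeffs([0.5, -2.0, 1.5])
        hard = cv.apply_threshold(c, ThresholdPolicy(
            mode="hard", rule="fixed", fixed_value=1.0))
        np.testing.assert_allclose(hard.details[0], [0.0, -2.0, 1.5])
        soft = cv.apply_threshold(c, ThresholdPolicy(
            mode="soft", rule="fixed", fixed_value=1.0))
        np.testing.assert_allclose(soft.details[0], [0.0, -1.0, 0.5])

    def test_zero_threshold_is_identity(self):
        c = self._coeffs([0.5, -2.0, 1.5])
        for mode in ("hard", "soft"):
            out = cv.apply_threshold(c, ThresholdPolicy(
                mode=mode, rule="fixed", fixed_value=0.0))
            np.testing.assert_allclose(out.details[0], c.details[0])

    def test_approximation_band_never_touched(self, rng):
        x = rng.standard_normal(64)
        c = cv.dwt_decompose(x, "db1", levels=3)
        out = cv.apply_threshold(c, ThresholdPolicy())
        np.testing.assert_array_equal(out.approx, c.approx)

    def test_invalid_policy_combinations(self):
        with pytest.raises(ValueError):
            ThresholdPolicy(rule="fixed")            # missing fixed_value
        with pytest.raises(ValueError):
            ThresholdPolicy(mode="clip")

    @given(hnp.arrays(np.float64, st.integers(2, 32).map(lambda n: 2 * n),
                      elements=st.floats(-100, 100)))
    def test_soft_shrinkage_never_grows_coefficients(self, x):
        c = cv.dwt_decompose(x, "db1", levels=1)
        out = cv.apply_threshold(c, ThresholdPolicy(mode="soft"))
        assert np.all(np.abs(out.details[0]) <= np.abs(c.details[0]) + 1e-12)


class TestDenoise:
    def test_improves_snr_on_noisy_tone(self):
        # low-frequency tone (inside the level-4 approximation band) plus
        # white noise at 0 dB; known clean component is the oracle
        rng = np.random.default_rng(3)
        t = np.arange(16384) / 16000
        tone = np.sin(2 * np.pi * 250 * t)
        noise = rng.standard_normal(len(t))
        noise *= np.sqrt(np.mean(tone ** 2) / np.mean(noise ** 2))
        out = cv.denoise(tone + noise)

        def snr(x):
            return 10 * np.log10(np.mean(tone ** 2)
                                 / np.mean((x - tone) ** 2))

        assert snr(tone + noise) == pytest.approx(0.0, abs=0.1)
        assert snr(out) - snr(tone + noise) > 3.0

    def test_clean_low_frequency_signal_barely_distorted(self):
        t = np.arange(4096) / 16000
        x = np.sin(2 * np.pi * 100 * t)
        out = cv.denoise(x, policy=ThresholdPolicy(mode="soft"))
        assert np.linalg.norm(out - x) / np.linalg.norm(x) < 0.10

    def test_zero_in_zero_out_and_length(self, rng):
        np.testing.assert_array_equal(cv.denoise(np.zeros(64)), np.zeros(64))
        x = rng.standard_normal(1000)
        assert len(cv.denoise(x)) == 1000

    def test_energy_non_expansive(self, rng):
        for mode in ("hard", "soft"):
            x = rng.standard_normal(512)
            out = cv.denoise(x, policy=ThresholdPolicy(mode=mode))
            assert np.sum(out ** 2) <= np.sum(x ** 2) + 1e-9
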