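"""Synthetic vocalization generator: determinism, spectral contracts,
SNR control, dataset manifests and WAV round-trips."""

import numpy as np
import pytest

import coopvox as cv
from coopvox.synth import (CLASS_ORDER, MANIFEST_COLUMNS, VocalClass,
                           _CALLSPEC_TABLE)


def _spectral_centroid(x, sample_rate):
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1 / sample_rate)
    return np.sum(freqs * power) / np.sum(power)


class TestCallSpecs:
    def test_table_is_deterministic_and_complete(self):
        for vc in CLASS_ORDER:
            assert cv.default_callspec(vc) is cv.default_callspec(vc)
        with pytest.raises(ValueError):
            cv.default_callspec("C7")

    def test_qualitative_contracts(self):
        c1, c2 = cv.default_callspec(VocalClass.C1), cv.default_callspec(VocalClass.C2)
        assert c2.f0_range[0] >= 2000 and c1.f0_range[1] <= 700
        assert c2.syllable_duration < c1.syllable_duration
        c3 = cv.default_callspec(VocalClass.C3)
        assert c3.amplitude_db < c1.amplitude_db  # quiet peeping
        assert cv.default_callspec(VocalClass.C4).n_harmonics == 0  # broadband
        assert cv.default_callspec(VocalClass.C5).fm_sweep > 0      # long sweep

    def test_class_mean_fundamentals_separated(self):
        # pairwise >= 150 Hz except the broadband (C4) and swept (C5) calls
        tonal = [vc for vc in CLASS_ORDER
                 if vc not in (VocalClass.C4, VocalClass.C5)]
        means = {vc: np.mean(_CALLSPEC_TABLE[vc].f0_range) for vc in tonal}
        for i, a in enumerate(tonal):
            for b in tonal[i + 1:]:
                assert abs(means[a] - means[b]) >= 150


class TestSynthCall:
    def test_bit_identical_for_same_seed(self):
        spec = cv.default_callspec(VocalClass.C1)
        a = cv.synth_call(spec, seed=7)
        b = cv.synth_call(spec, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, cv.synth_call(spec, seed=8).samples)

    def test_pure_tone_peaks_at_f0(self):
        # FFT oracle: degenerate f0 band, no AM/FM, single partial
        spec = cv.CallSpec(f0_range=(1000.0, 1000.0), syllable_duration=0.1,
                           repetition_rate=4.0, n_harmonics=1,
                           am_depth=0.0, fm_sweep=0.0)
        clip = cv.synth_call(spec, duration=2.0, sample_rate=16000, seed=0)
        power = np.abs(np.fft.rfft(clip.samples)) ** 2
        freqs = np.fft.rfftfreq(len(clip.samples), 1 / 16000)
        assert abs(freqs[np.argmax(power)] - 1000.0) <= freqs[1] - freqs[0]

    def test_crow_sweep_raises_centroid(self):
        clip = cv.synth_call(cv.default_callspec(VocalClass.C5), seed=3)
        half = len(clip.samples) // 2
        c_first = _spectral_centroid(clip.samples[:half], clip.sample_rate)
        c_second = _spectral_centroid(clip.samples[half:], clip.sample_rate)
        assert c_second > c_first

    def test_two_second_default_duration_and_peak_level(self):
        clip = cv.synth_call(cv.default_callspec(VocalClass.C2), seed=1)
        assert clip.duration == pytest.approx(2.0)
        spec = cv.default_callspec(VocalClass.C2)
        assert np.max(np.abs(clip.samples)) == pytest.approx(
            10 ** (spec.amplitude_db / 20))

    def test_harmonics_above_nyquist_warn_and_mute(self):
        spec = cv.CallSpec(f0_range=(3000.0, 3000.0), syllable_duration=0.1,
                           repetition_rate=4.0, n_harmonics=5)
        with pytest.warns(UserWarning, match="Nyquist"):
            clip = cv.synth_call(spec, seed=0)
        power = np.abs(np.fft.rfft(clip.samples)) ** 2
        freqs = np.fft.rfftfreq(len(clip.samples), 1 / clip.sample_rate)
        # energy above Nyquist-folding region only from windowing leakage
        assert power[freqs > 7500].sum() < 1e-3 * power.sum()


class TestBarnNoise:
    @pytest.mark.parametrize("snr_db", [-5.0, 0.0, 10.0, 30.0])
    @pytest.mark.parametrize("vc", list(CLASS_ORDER))
    def test_realized_snr_within_tenth_db(self, vc, snr_db):
        clip = cv.synth_call(cv.default_callspec(vc), seed=21)
        noisy, sig_part, noise_part = cv.add_barn_noise(
            clip, cv.NoiseSpec(snr_db=snr_db), seed=22, return_components=True)
        np.testing.assert_allclose(sig_part + noise_part, noisy.samples)
        realized = 10 * np.log10(np.mean(sig_part ** 2)
                                 / np.mean(noise_part ** 2))
        assert realized == pytest.approx(snr_db, abs=0.1)

    def test_high_snr_is_near_identity(self):
        clip = cv.synth_call(cv.default_callspec(VocalClass.C1), seed=4)
        noisy = cv.add_barn_noise(clip, cv.NoiseSpec(snr_db=60.0), seed=5)
        rms = np.sqrt(np.mean(clip.samples ** 2))
        assert np.sqrt(np.mean((noisy.samples - clip.samples) ** 2)) < 0.002 * rms

    def test_same_seed_same_noise(self):
        clip = cv.synth_call(cv.default_callspec(VocalClass.C3), seed=6,
                             label=VocalClass.C3)
        a = cv.add_barn_noise(clip, cv.NoiseSpec(), seed=9)
        b = cv.add_barn_noise(clip, cv.NoiseSpec(), seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.label is VocalClass.C3

    def test_zero_power_clip_rejected(self):
        silent = cv.AudioClip(samples=np.zeros(1000), sample_rate=16000)
        with pytest.raises(ValueError, match="SNR"):
            cv.add_barn_noise(silent, cv.NoiseSpec(), seed=0)


class TestDataset:
    def test_split_ratio_and_manifest(self, tmp_path):
        manifest = cv.generate_dataset({VocalClass.C1: 10}, tmp_path, seed=0)
        assert list(manifest.columns) == MANIFEST_COLUMNS
        assert (manifest["split"] == "train").sum() == 8
        assert (manifest["split"] == "val").sum() == 2
        assert manifest["file"].is_unique
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "dataset_config.yaml").exists()

    def test_empty_composition(self, tmp_path):
        manifest = cv.generate_dataset({}, tmp_path / "empty", seed=0)
        assert manifest.empty
        assert not list((tmp_path / "empty").glob("*.wav"))

    def test_paper_composition_counts(self):
        # manifest carries the full study's class mix (short clips keep
        # this fast; counts and splits do not depend on duration)
        _, manifest = cv.generate_clips(cv.PAPER_COMPOSITION, seed=0,
                                        duration=0.05)
        counts = manifest["label"].value_counts()
        assert counts["C1"] == 1200 and counts["C6"] == 240
        assert len(manifest) == 3600
        per_class = manifest.groupby("label")["split"].value_counts()
        assert per_class["C2", "val"] == 480 // 5

    def test_generation_is_seed_deterministic(self):
        clips_a, man_a = cv.generate_clips({VocalClass.C2: 4}, seed=33)
        clips_b, man_b = cv.generate_clips({VocalClass.C2: 4}, seed=33)
        assert man_a.equals(man_b)
        for a, b in zip(clips_a, clips_b):
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_wav_roundtrip_bit_exact(self, tmp_path):
        clip = cv.synth_call(cv.default_callspec(VocalClass.C5), seed=12)
        path = tmp_path / "c5.wav"
        cv.write_wav(path, clip)
        back = cv.read_wav(path)
        expected = np.round(np.clip(clip.samples, -1, 1) * 32767).astype(np.int16)
        np.testing.assert_array_equal(
            np.round(back.samples * 32767).astype(np.int16), expected)
        assert back.sample_rate == clip.sample_rate


class TestSeparability:
    def test_nearest_mean_oracle_above_80pct(self, mini_clean):
        """A trivial nearest-class-mean classifier on time-averaged mel
        spectra must already solve the clean task: the synthetic classes
        are learnable by construction."""
        from coopvox.pipeline import nearest_mean_baseline
        d = mini_clean
        acc = nearest_mean_baseline(d["x"], d["labels"], d["is_train"])
        assert acc > 0.80
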