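"""STFT power spectra and log mel-filter-bank energy (MFE) features.

The chain is: frame the signal into overlapping windows, take the DFT
X[k] = sum_n x[n] e^{-j 2 pi k n / N} per frame and keep the power
|X[k]|^2, weight the power spectrum with triangular filters whose centers
are equispaced on the mel scale m = 2595 log10(1 + f / mel_break), sum to
per-filter energies E_m = sum_k |X[k]|^2 H_m[k], and log-compress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import AudioClip

DEFAULT_MEL_BREAK = 700.0


@dataclass(frozen=True)
class FrameParams:
    """Framing/window parameters. Durations are in seconds; ``fft_size``
    defaults to the next power of two >= the frame length in samples."""

    frame_length: float = 0.025
    hop: float = 0.010
    window: str = "hamming"
    fft_size: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.hop <= self.frame_length:
            raise ValueError("require 0 < hop <= frame_length")
        if self.window not in ("hamming", "hann", "rect"):
            raise ValueError(f"unknown window {self.window!r}")

    def frame_samples(self, sample_rate: int) -> int:
        return int(round(self.frame_length * sample_rate))

    def hop_samples(self, sample_rate: int) -> int:
        return int(round(self.hop * sample_rate))

    def resolved_fft_size(self, sample_rate: int) -> int:
        n = self.frame_samples(sample_rate)
        if self.fft_size is not None:
            if self.fft_size < n:
                raise ValueError("fft_size must be >= frame length in samples")
            return self.fft_size
        return 1 << int(np.ceil(np.log2(n)))


@dataclass(frozen=True)
class MelBankParams:
    """Triangular mel filter-bank parameters. ``mel_break`` is the constant
    inside the log of the hz->mel map (700 Hz is the canonical pairing with
    the 2595 coefficient)."""

    n_filters: int = 40
    f_min: float = 0.0
    f_max: float | None = None   # None -> Nyquist
    sample_rate: int = 16000
    mel_break: float = DEFAULT_MEL_BREAK

    def __post_init__(self) -> None:
        fmax = self.sample_rate / 2 if self.f_max is None else self.f_max
        if not 0 <= self.f_min < fmax <= self.sample_rate / 2:
            raise ValueError("require 0 <= f_min < f_max <= Nyquist")
        if self.n_filters < 2:
            raise ValueError("n_filters must be >= 2")

    @property
    def resolved_f_max(self) -> float:
        return self.sample_rate / 2 if self.f_max is None else self.f_max


@dataclass
class MelSpectrogram:
    """frames x n_filters matrix of log mel-band energies, with frame
    center times and the parameters that produced it."""

    values: np.ndarray
    frame_times: np.ndarray
    frame_params: FrameParams
    bank_params: MelBankParams


def hz_to_mel(f, mel_break: float = DEFAULT_MEL_BREAK):
    """m = 2595 * log10(1 + f / mel_break); strictly increasing in f."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    out = 2595.0 * np.log10(1.0 + f / mel_break)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m, mel_break: float = DEFAULT_MEL_BREAK):
    """Inverse of :func:`hz_to_mel`."""
    m = np.asarray(m, dtype=float)
    out = mel_break * (10.0 ** (m / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


_WINDOWS = {
    "hamming": np.hamming,
    "hann": np.hanning,
    "rect": np.ones,
}


def frame_count(n_samples: int, frame: FrameParams, sample_rate: int) -> int:
    """floor((n - frame) / hop) + 1; the tail is not padded."""
    n_frame = frame.frame_samples(sample_rate)
    if n_samples < n_frame:
        raise ValueError(
            f"signal of {n_samples} samples is shorter than one "
            f"{n_frame}-sample frame")
    return (n_samples - n_frame) // frame.hop_samples(sample_rate) + 1


def stft_power(signal: np.ndarray, sample_rate: int,
               frame: FrameParams = FrameParams()) -> np.ndarray:
    """Per-frame power spectrum |X[k]|^2, k = 0 .. fft_size/2."""
    x = np.asarray(signal, dtype=float)
    n_frame = frame.frame_samples(sample_rate)
    hop = frame.hop_samples(sample_rate)
    n_frames = frame_count(len(x), frame, sample_rate)
    nfft = frame.resolved_fft_size(sample_rate)
    win = _WINDOWS[frame.window](n_frame)
    idx = np.arange(n_frames)[:, None] * hop + np.arange(n_frame)[None, :]
    frames = x[idx] * win
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    return np.abs(spec) ** 2


def mel_filter_centers(params: MelBankParams) -> np.ndarray:
    """Center frequencies (Hz) of the triangular filters: equispaced on
    the mel scale between f_min and f_max."""
    mel_edges = np.linspace(hz_to_mel(params.f_min, params.mel_break),
                            hz_to_mel(params.resolved_f_max, params.mel_break),
                            params.n_filters + 2)
    return mel_to_hz(mel_edges[1:-1], params.mel_break)


def mel_filterbank(params: MelBankParams, fft_size: int) -> np.ndarray:
    """n_filters x (fft_size/2 + 1) triangular weight matrix.

    Filter centers are equispaced in mel between f_min and f_max; each
    triangle rises from the previous center to its own and falls to the
    next. Weights are nonnegative and adjacent filters overlap.
    """
    n_bins = fft_size // 2 + 1
    mel_edges = np.linspace(hz_to_mel(params.f_min, params.mel_break),
                            hz_to_mel(params.resolved_f_max, params.mel_break),
                            params.n_filters + 2)
    hz_edges = mel_to_hz(mel_edges, params.mel_break)
    bin_freqs = np.arange(n_bins) * params.sample_rate / fft_size
    bank = np.zeros((params.n_filters, n_bins))
    for m in range(params.n_filters):
        f_lo, f_c, f_hi = hz_edges[m], hz_edges[m + 1], hz_edges[m + 2]
        rising = (bin_freqs - f_lo) / (f_c - f_lo)
        falling = (f_hi - bin_freqs) / (f_hi - f_c)
        bank[m] = np.maximum(0.0, np.minimum(rising, falling))
    if np.any(bank.sum(axis=1) == 0):
        raise ValueError(
            f"{params.n_filters} filters exceed the resolution of "
            f"{n_bins} FFT bins (some filters cover no bin)")
    return bank


def mel_energies(power: np.ndarray, bank: np.ndarray) -> np.ndarray:
    """E_m = sum_k |X[k]|^2 * H_m[k] per frame (a matrix product)."""
    power = np.asarray(power, dtype=float)
    bank = np.asarray(bank, dtype=float)
    if power.shape[1] != bank.shape[1]:
        raise ValueError(
            f"power has {power.shape[1]} bins but bank expects {bank.shape[1]}")
    return power @ bank.T


def log_compress(energies: np.ndarray, floor_eps: float = 1e-10) -> np.ndarray:
    """Elementwise log(E + floor_eps)."""
    e = np.asarray(energies, dtype=float)
    if np.any(e < 0):
        raise ValueError("energies must be nonnegative")
    return np.log(e + floor_eps)


def extract_mfe(clip: AudioClip,
                frame: FrameParams = FrameParams(),
                bank: MelBankParams | None = None,
                floor_eps: float = 1e-10) -> MelSpectrogram:
    """Full MFE extraction: stft_power -> mel_energies -> log_compress."""
    if bank is None:
        bank = MelBankParams(sample_rate=clip.sample_rate)
    elif bank.sample_rate != clip.sample_rate:
        raise ValueError("bank sample_rate does not match clip sample_rate")
    power = stft_power(clip.samples, clip.sample_rate, frame)
    weights = mel_filterbank(bank, frame.resolved_fft_size(clip.sample_rate))
    values = log_compress(mel_energies(power, weights), floor_eps)
    hop = frame.hop_samples(clip.sample_rate)
    n_frame = frame.frame_samples(clip.sample_rate)
    times = (np.arange(values.shape[0]) * hop + n_frame / 2) / clip.sample_rate
    return MelSpectrogram(values=values, frame_times=times,
                          frame_params=frame, bank_params=bank)
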