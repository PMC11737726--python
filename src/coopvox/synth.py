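"""Synthetic chicken-vocalization generator.

Produces labeled 2-second mono clips for six call classes — contentment
clucks, hunger piping, exploratory peeping, prelaying crackles, rooster
crowing, and alarm/distress calls — with the qualitative acoustic character
of each call type (fundamental-frequency band, syllable rhythm, harmonic
richness, loudness), plus configurable barn-noise contamination
(ventilation-fan hum and pink broadband noise) at a requested SNR.

Every sample value is a deterministic function of the generator seed, so a
dataset is fully reproducible from its manifest.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps
from scipy.io import wavfile


class VocalClass(enum.Enum):
    """The six vocalization classes, coded C1..C6."""

    C1 = "contentment_cluck"
    C2 = "hunger_piping"
    C3 = "exploratory_peeping"
    C4 = "prelaying_crackle"
    C5 = "rooster_crow"
    C6 = "alarm_distress"

    @classmethod
    def from_code(cls, code: str) -> "VocalClass":
        try:
            return cls[code]
        except KeyError:
            raise ValueError(f"unknown vocalization class code: {code!r}") from None


CLASS_ORDER: tuple[VocalClass, ...] = tuple(VocalClass)


@dataclass(frozen=True)
class CallSpec:
    """Parametric realization of one call type.

    ``f0_range`` is the per-syllable fundamental band in Hz; syllables of
    ``syllable_duration`` seconds repeat at ``repetition_rate`` Hz. A
    harmonic stack of ``n_harmonics`` partials rides on f0 (``n_harmonics
    == 0`` selects band-limited noise bursts instead — broadband calls with
    no fundamental). ``fm_sweep`` is a linear within-syllable frequency
    ramp in Hz/s, ``am_depth`` in [0, 1] sets how deeply the syllable gate
    modulates the carrier (0 = continuous tone), and ``amplitude_db`` is
    the peak level in dBFS.
    """

    f0_range: tuple[float, float]
    syllable_duration: float
    repetition_rate: float
    n_harmonics: int
    amplitude_db: float = -6.0
    fm_sweep: float = 0.0
    am_depth: float = 1.0

    def validate(self, sample_rate: float) -> None:
        lo, hi = self.f0_range
        if not (0 < lo <= hi < sample_rate / 2):
            raise ValueError(f"f0_range {self.f0_range} outside (0, Nyquist)")
        if self.syllable_duration <= 0:
            raise ValueError("syllable_duration must be > 0")
        if self.amplitude_db > 0:
            raise ValueError("amplitude_db must be <= 0 dBFS")
        if not 0 <= self.am_depth <= 1:
            raise ValueError("am_depth must be in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Barn-noise model: ventilation-fan hum plus broadband noise.

    The hum is a harmonic series at ``hum_freq`` with ``hum_harmonics``
    partials at 1/k amplitude; the broadband component is white or pink.
    The mixture is scaled so the realized signal-to-noise ratio equals
    ``snr_db``.
    """

    hum_freq: float = 120.0
    hum_harmonics: int = 5
    broadband_color: str = "pink"
    snr_db: float = 10.0

    def validate(self, sample_rate: float) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if not 0 < self.hum_freq < sample_rate / 2:
            raise ValueError("hum_freq must lie below Nyquist")
        if self.broadband_color not in ("white", "pink"):
            raise ValueError(f"unknown broadband color {self.broadband_color!r}")


@dataclass
class AudioClip:
    """A fixed-rate mono clip with label and generator provenance."""

    samples: np.ndarray
    sample_rate: int
    label: VocalClass | None = None
    seed: int | None = None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


# ---------------------------------------------------------------------------
# Built-in call-spec table
#
# Only the qualitative contracts are normative: C1 low and steady, C2 high
# and repeated, C3 quiet quizzical peeps, C4 broadband pulse train (no f0),
# C5 one long loud FM-swept crow, C6 loud harsh repetitive calls. Class-mean
# fundamentals (C1 450, C6 1200, C3 1750, C2 3000 Hz) are pairwise separated
# by >= 150 Hz; C4 and C5 are exempt (broadband / swept).
# ---------------------------------------------------------------------------

_CALLSPEC_TABLE: dict[VocalClass, CallSpec] = {
    VocalClass.C1: CallSpec(
        f0_range=(300.0, 600.0), syllable_duration=0.12, repetition_rate=4.0,
        n_harmonics=5, amplitude_db=-6.0),
    VocalClass.C2: CallSpec(
        f0_range=(2500.0, 3500.0), syllable_duration=0.06, repetition_rate=8.0,
        n_harmonics=2, amplitude_db=-6.0),
    VocalClass.C3: CallSpec(
        f0_range=(1550.0, 1950.0), syllable_duration=0.08, repetition_rate=3.0,
        n_harmonics=2, amplitude_db=-18.0, fm_sweep=600.0),
    VocalClass.C4: CallSpec(
        f0_range=(500.0, 4000.0), syllable_duration=0.03, repetition_rate=10.0,
        n_harmonics=0, amplitude_db=-8.0),
    VocalClass.C5: CallSpec(
        f0_range=(550.0, 700.0), syllable_duration=1.2, repetition_rate=0.5,
        n_harmonics=4, amplitude_db=-3.0, fm_sweep=900.0),
    VocalClass.C6: CallSpec(
        f0_range=(1050.0, 1350.0), syllable_duration=0.10, repetition_rate=6.0,
        n_harmonics=5, amplitude_db=-3.0),
}

#: Class composition of the full study dataset (clip counts per class).
PAPER_COMPOSITION: dict[VocalClass, int] = {
    VocalClass.C1: 1200, VocalClass.C2: 480, VocalClass.C3: 360,
    VocalClass.C4: 720, VocalClass.C5: 600, VocalClass.C6: 240,
}

#: Desk-scale preset: the full composition scaled down by 12.
MINI_COMPOSITION: dict[VocalClass, int] = {
    c: n // 12 for c, n in PAPER_COMPOSITION.items()
}

DEFAULT_SAMPLE_RATE = 16000
DEFAULT_DURATION = 2.0


def default_callspec(vocal_class: VocalClass) -> CallSpec:
    """Return the built-in CallSpec for a vocalization class."""
    if not isinstance(vocal_class, VocalClass):
        vocal_class = VocalClass.from_code(str(vocal_class))
    return _CALLSPEC_TABLE[vocal_class]


def _syllable_gate(n: int, sample_rate: float, spec: CallSpec) -> np.ndarray:
    """0/1-ish envelope: Hann-windowed syllables at the repetition rate."""
    gate = np.zeros(n)
    period = 1.0 / spec.repetition_rate
    syl_len = max(2, min(int(round(spec.syllable_duration * sample_rate)),
                         int(round(period * sample_rate))))
    win = np.hanning(syl_len)
    onset = 0
    while onset < n:
        end = min(onset + syl_len, n)
        gate[onset:end] = np.maximum(gate[onset:end], win[: end - onset])
        onset += int(round(period * sample_rate))
    return gate


def synth_call(spec: CallSpec, duration: float = DEFAULT_DURATION,
               sample_rate: int = DEFAULT_SAMPLE_RATE, seed: int = 0,
               label: VocalClass | None = None) -> AudioClip:
    """Synthesize one clip from a CallSpec, bit-reproducibly from ``seed``.

    The carrier is a phase-continuous harmonic stack whose fundamental is
    re-drawn uniformly from ``f0_range`` at each syllable period and swept
    at ``fm_sweep`` Hz/s within the syllable; partials above Nyquist are
    muted (with a warning). ``n_harmonics == 0`` substitutes band-limited
    noise bursts. The syllable gate modulates amplitude with depth
    ``am_depth``, and the result is peak-normalized to ``amplitude_db``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    spec.validate(sample_rate)
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    period_samps = max(1, int(round(sample_rate / spec.repetition_rate)))

    # per-sample instantaneous fundamental: jittered per syllable period,
    # linearly swept within it
    n_periods = int(np.ceil(n / period_samps))
    f0s = rng.uniform(spec.f0_range[0], spec.f0_range[1], size=n_periods)
    f_inst = np.empty(n)
    for p in range(n_periods):
        s, e = p * period_samps, min((p + 1) * period_samps, n)
        local_t = (np.arange(s, e) - s) / sample_rate
        # the sweep runs within the syllable and holds past its end
        f_inst[s:e] = f0s[p] + spec.fm_sweep * np.minimum(
            local_t, spec.syllable_duration)

    if spec.n_harmonics == 0:
        # broadband pulse train: band-limited noise, no fundamental
        lo, hi = spec.f0_range
        sos = sps.butter(4, [lo, hi], btype="band", fs=sample_rate, output="sos")
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
    else:
        phase = 2 * np.pi * np.cumsum(f_inst) / sample_rate
        carrier = np.zeros(n)
        clipped = False
        for h in range(1, spec.n_harmonics + 1):
            audible = h * f_inst < sample_rate / 2
            if not audible.all():
                clipped = True
            carrier += np.where(audible, np.sin(h * phase) / h, 0.0)
        if clipped:
            warnings.warn("harmonics above Nyquist were muted", stacklevel=2)

    gate = _syllable_gate(n, sample_rate, spec)
    env = (1.0 - spec.am_depth) + spec.am_depth * gate
    x = carrier * env
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x * (10 ** (spec.amplitude_db / 20) / peak)
    return AudioClip(samples=x, sample_rate=sample_rate, label=label, seed=seed)


def _broadband(color: str, n: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    if color == "white":
        return white
    # pink: 1/sqrt(f) spectral shaping in the frequency domain
    spec_ = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = 1.0 / np.sqrt(np.maximum(f, f[1] if n > 1 else 1.0))
    return np.fft.irfft(spec_ * scale, n=n)


def add_barn_noise(clip: AudioClip, noise: NoiseSpec, seed: int = 0,
                   return_components: bool = False):
    """Mix fan hum + broadband noise into a clip at ``noise.snr_db``.

    Hum and broadband components are power-balanced, then the mixture is
    scaled so 10*log10(P_signal / P_noise) equals the requested SNR. If the
    sum exceeds full scale the whole clip is renormalized (which preserves
    the SNR). The label is preserved.
    """
    noise.validate(clip.sample_rate)
    x = np.asarray(clip.samples, dtype=float)
    p_sig = float(np.mean(x ** 2))
    if p_sig == 0:
        raise ValueError("clip has zero power; SNR is undefined")
    rng = np.random.default_rng(seed)
    n = len(x)
    t = np.arange(n) / clip.sample_rate

    hum = np.zeros(n)
    for k in range(1, noise.hum_harmonics + 1):
        fk = k * noise.hum_freq
        if fk >= clip.sample_rate / 2:
            break
        hum += np.sin(2 * np.pi * fk * t + rng.uniform(0, 2 * np.pi)) / k
    bb = _broadband(noise.broadband_color, n, rng)

    def _unit_power(v: np.ndarray) -> np.ndarray:
        p = np.mean(v ** 2)
        return v / np.sqrt(p) if p > 0 else v

    mix = (_unit_power(hum) + _unit_power(bb)) / np.sqrt(2)
    p_noise = np.mean(mix ** 2)
    target_p_noise = p_sig / (10 ** (noise.snr_db / 10))
    mix *= np.sqrt(target_p_noise / p_noise)

    y = x + mix
    peak = np.max(np.abs(y))
    if peak > 1.0:
        y, x, mix = y / peak, x / peak, mix / peak
    out = AudioClip(samples=y, sample_rate=clip.sample_rate,
                    label=clip.label, seed=clip.seed)
    if return_components:
        return out, x, mix
    return out


# ---------------------------------------------------------------------------
# WAV I/O and dataset generation
# ---------------------------------------------------------------------------

def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM mono WAV."""
    x = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), clip.sample_rate, pcm)


def read_wav(path: str | Path) -> AudioClip:
    """Read a 16-bit PCM mono WAV back into an AudioClip (floats in [-1, 1])."""
    sr, pcm = wavfile.read(str(path))
    if pcm.ndim != 1:
        raise ValueError(f"{path}: expected mono audio")
    return AudioClip(samples=pcm.astype(float) / 32767.0, sample_rate=int(sr))


MANIFEST_COLUMNS = ["file", "label", "split", "seed", "snr_db"]


def generate_dataset(composition: dict[VocalClass, int] | None = None,
                     out_dir: str | Path = "dataset",
                     sample_rate: int = DEFAULT_SAMPLE_RATE,
                     noise: NoiseSpec | None = None,
                     seed: int = 0,
                     duration: float = DEFAULT_DURATION) -> pd.DataFrame:
    """Generate a labeled WAV dataset plus a train/val manifest CSV.

    Each class's clips are shuffled (seeded) and split train:val at 4:1
    with ``floor(n/5)`` clips on the validation side. The manifest
    (``file,label,split,seed,snr_db``) and the generator parameters are
    written alongside the audio; ``(composition, seed)`` fully determine
    every sample value.
    """
    if composition is None:
        composition = PAPER_COMPOSITION
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    clips, manifest = generate_clips(composition, sample_rate=sample_rate,
                                     noise=noise, seed=seed, duration=duration)
    for clip, fname in zip(clips, manifest["file"]):
        write_wav(out_dir / fname, clip)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    params = {
        "sample_rate": sample_rate, "duration": duration, "seed": seed,
        "composition": {vc.name: int(composition.get(vc, 0)) for vc in CLASS_ORDER},
        "noise": None if noise is None else {
            "hum_freq": noise.hum_freq, "hum_harmonics": noise.hum_harmonics,
            "broadband_color": noise.broadband_color, "snr_db": noise.snr_db},
    }
    with open(out_dir / "dataset_config.yaml", "w") as fh:
        yaml.safe_dump(params, fh)
    return manifest


def generate_clips(composition: dict[VocalClass, int],
                   sample_rate: int = DEFAULT_SAMPLE_RATE,
                   noise: NoiseSpec | None = None,
                   seed: int = 0,
                   duration: float = DEFAULT_DURATION
                   ) -> tuple[list[AudioClip], pd.DataFrame]:
    """In-memory variant of :func:`generate_dataset` (same seeds, same
    splits, no files). Returns (clips, manifest) with manifest rows in clip
    order."""
    if any(n < 0 for n in composition.values()):
        raise ValueError("class counts must be >= 0")
    rng = np.random.default_rng(seed)
    clips: list[AudioClip] = []
    rows = []
    for vc in CLASS_ORDER:
        count = composition.get(vc, 0)
        if count == 0:
            continue
        spec = default_callspec(vc)
        clip_seeds = rng.integers(0, 2 ** 31 - 1, size=count)
        noise_seeds = rng.integers(0, 2 ** 31 - 1, size=count)
        n_val = count // 5
        order = rng.permutation(count)
        splits = np.empty(count, dtype=object)
        splits[order[:n_val]] = "val"
        splits[order[n_val:]] = "train"
        for i in range(count):
            clip = synth_call(spec, duration=duration, sample_rate=sample_rate,
                              seed=int(clip_seeds[i]), label=vc)
            if noise is not None:
                clip = add_barn_noise(clip, noise, seed=int(noise_seeds[i]))
            clips.append(clip)
            rows.append({"file": f"{vc.name}_{i:05d}.wav", "label": vc.name,
                         "split": splits[i], "seed": int(clip_seeds[i]),
                         "snr_db": noise.snr_db if noise is not None else np.inf})
    return clips, pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
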