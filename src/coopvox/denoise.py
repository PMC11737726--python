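"""Multilevel discrete wavelet transform denoising with the db1 (Haar) wavelet.

The analysis step evaluates, with periodic boundary extension,

    a_{j+1}[n] = sum_k h[k] * a_j[(2n + k) mod N]
    d_{j+1}[n] = sum_k g[k] * a_j[(2n + k) mod N]

with a_0 the input signal and, for db1, h = [1/sqrt(2), 1/sqrt(2)] and
g = [1/sqrt(2), -1/sqrt(2)]. Periodization keeps the filter bank exactly
orthonormal, so coefficient counts halve per level, energy is conserved,
and the synthesis step (the adjoint) is an exact inverse.

Denoising shrinks the detail bands — hard or soft thresholding, with the
universal threshold T = sigma * sqrt(2 ln N) and sigma estimated as
MAD/0.6745 of the finest detail band by default — and reconstructs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_SQRT2 = np.sqrt(2.0)

# analysis low/high-pass filter pairs (orthonormal)
_FILTERS: dict[str, tuple[np.ndarray, np.ndarray]] = {
    "db1": (np.array([1.0, 1.0]) / _SQRT2, np.array([1.0, -1.0]) / _SQRT2),
}
_FILTERS["haar"] = _FILTERS["db1"]


@dataclass
class WaveletCoeffs:
    """Multilevel DWT decomposition.

    ``details`` is ordered finest to coarsest (d_1 .. d_J); ``approx`` is
    the coarsest approximation band a_J. ``pad_flags[j]`` records whether
    the level-j input was zero-padded by one sample to even length, so
    reconstruction can trim back to ``original_length``.
    """

    approx: np.ndarray
    details: list[np.ndarray]
    levels: int
    wavelet_name: str
    original_length: int
    pad_flags: list[bool] = field(default_factory=list)


@dataclass(frozen=True)
class ThresholdPolicy:
    """How to shrink detail coefficients.

    mode: 'hard' (zero below T) or 'soft' (shrink all toward zero by T).
    rule: 'universal' (T = sigma*sqrt(2 ln N)) or 'fixed' (T = fixed_value).
    sigma_estimator: 'mad_finest' (one sigma from d_1) or 'per_level_mad'.
    """

    mode: str = "soft"
    rule: str = "universal"
    fixed_value: float | None = None
    sigma_estimator: str = "mad_finest"

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.rule not in ("universal", "fixed"):
            raise ValueError(f"unknown threshold rule {self.rule!r}")
        if self.rule == "fixed":
            if self.fixed_value is None or self.fixed_value < 0:
                raise ValueError("rule='fixed' requires fixed_value >= 0")
        if self.sigma_estimator not in ("mad_finest", "per_level_mad"):
            raise ValueError(f"unknown sigma estimator {self.sigma_estimator!r}")


def _get_filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        return _FILTERS[wavelet]
    except KeyError:
        raise ValueError(f"unsupported wavelet {wavelet!r}; "
                         f"available: {sorted(_FILTERS)}") from None


def _analyze_level(x: np.ndarray, h: np.ndarray, g: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, bool]:
    padded = len(x) % 2 == 1
    if padded:
        x = np.concatenate([x, [0.0]])
    n = len(x)
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(len(h))[None, :]) % n
    windows = x[idx]
    return windows @ h, windows @ g, padded


def _synthesize_level(a: np.ndarray, d: np.ndarray, h: np.ndarray,
                      g: np.ndarray, padded: bool) -> np.ndarray:
    n = 2 * len(a)
    idx = (2 * np.arange(len(a))[:, None] + np.arange(len(h))[None, :]) % n
    x = np.zeros(n)
    np.add.at(x, idx, np.outer(a, h) + np.outer(d, g))
    return x[:-1] if padded else x


def max_decomposition_level(n_samples: int) -> int:
    """Deepest level J with len(signal) >= 2**J."""
    if n_samples < 2:
        return 0
    return int(np.floor(np.log2(n_samples)))


def dwt_decompose(signal: np.ndarray, wavelet: str = "db1",
                  levels: int = 4) -> WaveletCoeffs:
    """Multilevel periodized DWT of a 1-D signal."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    max_lvl = max_decomposition_level(len(x))
    if levels > max_lvl:
        raise ValueError(
            f"levels={levels} too deep for signal of length {len(x)}; "
            f"maximum level is {max_lvl}")
    h, g = _get_filters(wavelet)
    details: list[np.ndarray] = []
    pad_flags: list[bool] = []
    a = x
    for _ in range(levels):
        a, d, padded = _analyze_level(a, h, g)
        details.append(d)
        pad_flags.append(padded)
    return WaveletCoeffs(approx=a, details=details, levels=levels,
                         wavelet_name=wavelet, original_length=len(x),
                         pad_flags=pad_flags)


def dwt_reconstruct(coeffs: WaveletCoeffs) -> np.ndarray:
    """Exact inverse of :func:`dwt_decompose` (adjoint of the orthonormal
    periodized analysis bank), trimmed to the original length."""
    h, g = _get_filters(coeffs.wavelet_name)
    if len(coeffs.details) != coeffs.levels:
        raise ValueError("levels does not match number of detail bands")
    a = np.asarray(coeffs.approx, dtype=float)
    for j in range(coeffs.levels - 1, -1, -1):
        d = np.asarray(coeffs.details[j], dtype=float)
        if len(d) != len(a):
            raise ValueError(
                f"detail band {j + 1} has length {len(d)}, expected {len(a)}")
        padded = coeffs.pad_flags[j] if j < len(coeffs.pad_flags) else False
        a = _synthesize_level(a, d, h, g, padded)
    return a[: coeffs.original_length]


def estimate_sigma(detail: np.ndarray) -> float:
    """Robust noise-level estimate: median(|d|) / 0.6745."""
    d = np.asarray(detail, dtype=float)
    if d.size == 0:
        raise ValueError("detail sequence is empty")
    return float(np.median(np.abs(d)) / 0.6745)


def _shrink(d: np.ndarray, t: float, mode: str) -> np.ndarray:
    if mode == "hard":
        return np.where(np.abs(d) > t, d, 0.0)
    return np.sign(d) * np.maximum(np.abs(d) - t, 0.0)


def apply_threshold(coeffs: WaveletCoeffs,
                    policy: ThresholdPolicy = ThresholdPolicy()) -> WaveletCoeffs:
    """Threshold the detail bands; the approximation band is never touched."""
    n = coeffs.original_length
    if policy.rule == "fixed":
        thresholds = [float(policy.fixed_value)] * coeffs.levels
    elif policy.sigma_estimator == "per_level_mad":
        thresholds = [estimate_sigma(d) * np.sqrt(2 * np.log(n))
                      for d in coeffs.details]
    else:
        sigma = estimate_sigma(coeffs.details[0])
        thresholds = [sigma * np.sqrt(2 * np.log(n))] * coeffs.levels
    new_details = [_shrink(np.asarray(d, dtype=float), t, policy.mode)
                   for d, t in zip(coeffs.details, thresholds)]
    return replace(coeffs, details=new_details,
                   approx=np.asarray(coeffs.approx, dtype=float).copy())


def denoise(signal: np.ndarray, wavelet: str = "db1",
            levels: int | None = None,
            policy: ThresholdPolicy = ThresholdPolicy()) -> np.ndarray:
    """Wavelet-shrinkage denoising: decompose, threshold details, reconstruct.

    ``levels`` defaults to min(4, deepest level the length permits).
    Output has the same length as the input; because thresholding only
    shrinks coefficients of an orthonormal transform, output energy never
    exceeds input energy.
    """
    x = np.asarray(signal, dtype=float)
    if levels is None:
        levels = min(4, max_decomposition_level(len(x)))
        if levels < 1:
            raise ValueError("signal too short to decompose")
    coeffs = dwt_decompose(x, wavelet=wavelet, levels=levels)
    return dwt_reconstruct(apply_threshold(coeffs, policy))
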