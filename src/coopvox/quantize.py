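"""Deployment-readiness transforms: int8 post-training quantization and
unstructured magnitude pruning, with accuracy-delta reporting.

Quantization is simulated ("fake quantization"): weights are stored as
symmetric per-tensor int8 (scale only, w -> round(w/s) clipped to
[-127, 127]) and dequantized for inference; activations are quantized
affinely per layer (scale + zero point) with ranges calibrated from
min/max over a calibration set. The contract under test is accuracy after
quantization, not integer-kernel runtime; on-device deployment is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import CNN1D
from .evaluate import ClassMetrics, build_confusion, class_metrics


@dataclass(frozen=True)
class QuantScheme:
    bit_width: int = 8
    weight_mode: str = "symmetric"       # per-tensor, scale only
    activation_mode: str = "affine"      # per-tensor, scale + zero point


@dataclass(frozen=True)
class PruneSpec:
    sparsity: float = 0.5                # fraction of weights zeroed
    granularity: str = "per_weight"      # unstructured

    def __post_init__(self) -> None:
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must lie in [0, 1)")


def quantize_weight(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Symmetric per-tensor int8: (int8 array, scale). An all-zero tensor
    gets a guard scale of 1 so zeros round-trip exactly."""
    peak = float(np.max(np.abs(w))) if w.size else 0.0
    scale = peak / 127.0 if peak > 0 else 1.0
    q = np.clip(np.round(w / scale), -127, 127).astype(np.int8)
    return q, scale


@dataclass
class QuantizedModel:
    """A model with int8 weights + per-layer activation ranges; inference
    dequantizes weights and fake-quantizes every layer activation."""

    model: CNN1D                                  # holds dequantized weights
    int_weights: dict[str, np.ndarray]
    weight_scales: dict[str, float]
    act_params: dict[int, tuple[float, int]]      # layer idx -> (scale, zero)
    scheme: QuantScheme

    def _act_hook(self, idx: int, a: np.ndarray) -> np.ndarray:
        if idx not in self.act_params:
            return a
        scale, zero = self.act_params[idx]
        q = np.clip(np.round(a / scale) + zero, -128, 127)
        return (q - zero) * scale

    def predict(self, x: np.ndarray):
        return self.model.predict(x, activation_hook=self._act_hook)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(x, activation_hook=self._act_hook)


def _affine_params(lo: float, hi: float) -> tuple[float, int]:
    lo, hi = min(lo, 0.0), max(hi, 0.0)      # range must include zero
    scale = (hi - lo) / 255.0
    if scale == 0:
        return 1.0, 0
    zero = int(np.clip(np.round(-128 - lo / scale), -128, 127))
    return scale, zero


def quantize_ptq(model: CNN1D, calibration_features: np.ndarray,
                 scheme: QuantScheme = QuantScheme()) -> QuantizedModel:
    """Post-training quantization with min/max activation calibration."""
    if len(calibration_features) == 0:
        raise ValueError("calibration set is empty")
    qmodel = model.copy()
    int_weights: dict[str, np.ndarray] = {}
    scales: dict[str, float] = {}
    for i, name, w in qmodel.weight_tensors():
        q, s = quantize_weight(w)
        key = f"{i}/{name}"
        int_weights[key] = q
        scales[key] = s
        qmodel.layers[i].params[name] = q.astype(float) * s

    ranges: dict[int, list[float]] = {}

    def observe(idx: int, a: np.ndarray) -> np.ndarray:
        lo, hi = float(a.min()), float(a.max())
        if idx in ranges:
            ranges[idx][0] = min(ranges[idx][0], lo)
            ranges[idx][1] = max(ranges[idx][1], hi)
        else:
            ranges[idx] = [lo, hi]
        return a

    qmodel.forward(calibration_features, train=False, activation_hook=observe)
    act_params = {idx: _affine_params(lo, hi) for idx, (lo, hi) in ranges.items()}
    return QuantizedModel(model=qmodel, int_weights=int_weights,
                          weight_scales=scales, act_params=act_params,
                          scheme=scheme)


def prune_magnitude(model: CNN1D, spec: PruneSpec = PruneSpec()) -> CNN1D:
    """Zero the smallest-magnitude fraction of weights within each weight
    tensor (biases are untouched); realized per-tensor sparsity is within
    1/tensor_size of requested."""
    pruned = model.copy()
    for i, name, w in pruned.weight_tensors():
        if name != "W":
            continue
        k = int(np.floor(spec.sparsity * w.size))
        if k == 0:
            continue
        flat = np.abs(w).ravel()
        cutoff = np.partition(flat, k - 1)[k - 1]
        mask = np.abs(w) > cutoff
        # ties at the cutoff: keep just enough to zero exactly k weights
        n_extra = int(w.size - k - mask.sum())
        if n_extra > 0:
            tie_idx = np.flatnonzero(np.abs(w).ravel() == cutoff)[:n_extra]
            mask = mask.ravel()
            mask[tie_idx] = True
            mask = mask.reshape(w.shape)
        pruned.layers[i].params[name] = w * mask
    return pruned


def accuracy_report(before, after, x_eval: np.ndarray, y_eval,
                    class_order) -> pd.DataFrame:
    """CSV-ready (metric, before, after, delta) table; metrics computed by
    the evaluate module on argmax predictions of both models."""
    def _metrics(m) -> ClassMetrics:
        _, labels = m.predict(x_eval)
        return class_metrics(build_confusion(y_eval, labels, class_order))

    mb, ma = _metrics(before), _metrics(after)
    rows = []
    for metric in ("accuracy", "macro_precision", "macro_recall", "macro_f1"):
        b, a = getattr(mb, metric), getattr(ma, metric)
        rows.append({"metric": metric, "before": b, "after": a,
                     "delta": a - b})
    return pd.DataFrame(rows)
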