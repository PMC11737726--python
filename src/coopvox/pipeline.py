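"""End-to-end experiment orchestration.

A run generates one synthetic dataset, then executes two arms on the
identical clips, split and training seed: "raw" (MFE features straight
from the audio) and "denoised" (db1 wavelet shrinkage before feature
extraction). Each arm trains the 1D CNN and is scored on the validation
split; the report carries both arms' metrics and their deltas
(denoised - raw). Everything is a deterministic function of the config
and its seed, and a run directory (when requested) receives the config
echo, manifest, per-arm confusion matrices, metric tables, training
histories and model archives.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier, evaluate, features, synth
from .denoise import ThresholdPolicy, denoise as wavelet_denoise

logger = logging.getLogger("coopvox")

COMPOSITION_PRESETS = {
    "paper": synth.PAPER_COMPOSITION,
    "mini": synth.MINI_COMPOSITION,
}

#: class-balanced desk-scale composition, used for chance-level controls
#: (with balanced classes the six-class chance accuracy is exactly 1/6)
BALANCED_MINI_COMPOSITION: dict[synth.VocalClass, int] = {
    c: 50 for c in synth.CLASS_ORDER
}


@dataclass(frozen=True)
class RunConfig:
    """One experiment: dataset, denoising, feature, model and training
    settings. ``composition`` is a preset name ('mini', 'paper') or a
    {class code: count} mapping; ``snr_db = None`` means clean audio."""

    composition: str | dict = "mini"
    snr_db: float | None = 0.0
    sample_rate: int = synth.DEFAULT_SAMPLE_RATE
    seed: int = 0

    wavelet: str = "db1"
    denoise_levels: int = 4
    threshold_mode: str = "soft"
    threshold_rule: str = "universal"

    n_mel_filters: int = 40
    frame_length: float = 0.025
    hop: float = 0.010

    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stop_patience: int = 5

    output_dir: str | None = None

    def resolve_composition(self) -> dict[synth.VocalClass, int]:
        if isinstance(self.composition, str):
            try:
                return dict(COMPOSITION_PRESETS[self.composition])
            except KeyError:
                raise ValueError(
                    f"unknown composition preset {self.composition!r}") from None
        return {synth.VocalClass.from_code(k) if not isinstance(k, synth.VocalClass)
                else k: int(v) for k, v in self.composition.items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["composition"], dict):
            d["composition"] = {getattr(k, "name", k): v
                                for k, v in d["composition"].items()}
        return d


@dataclass
class RunReport:
    config: RunConfig
    manifest: pd.DataFrame
    metrics: dict[str, evaluate.ClassMetrics]          # arm -> metrics
    confusions: dict[str, evaluate.ConfusionMatrix]
    histories: dict[str, dict[str, list[float]]]
    deltas: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = []
        for arm in ("raw", "denoised"):
            m = self.metrics[arm]
            lines.append(f"{arm:9s} accuracy={m.accuracy:.3f} "
                         f"macro_f1={m.macro_f1:.3f}")
        lines.append("deltas (denoised - raw): " + ", ".join(
            f"{k}={v:+.3f}" for k, v in self.deltas.items()))
        return "\n".join(lines)


def featurize_clips(clips: list[synth.AudioClip], config: RunConfig,
                    apply_denoise: bool) -> np.ndarray:
    """Stack per-clip MFE matrices into (n_clips, frames, bands)."""
    frame = features.FrameParams(frame_length=config.frame_length,
                                 hop=config.hop)
    bank = features.MelBankParams(n_filters=config.n_mel_filters,
                                  sample_rate=config.sample_rate)
    policy = ThresholdPolicy(mode=config.threshold_mode,
                             rule=config.threshold_rule)
    mats = []
    for clip in clips:
        if apply_denoise:
            clean = wavelet_denoise(clip.samples, wavelet=config.wavelet,
                                    levels=config.denoise_levels, policy=policy)
            clip = synth.AudioClip(samples=clean, sample_rate=clip.sample_rate,
                                   label=clip.label, seed=clip.seed)
        mats.append(features.extract_mfe(clip, frame=frame, bank=bank).values)
    return np.stack(mats)


def _train_and_score(x: np.ndarray, labels: list[str], manifest: pd.DataFrame,
                     config: RunConfig
                     ) -> tuple[classifier.CNN1D, evaluate.ConfusionMatrix,
                                evaluate.ClassMetrics]:
    is_train = (manifest["split"] == "train").to_numpy()
    if not is_train.any() or is_train.all():
        raise ValueError("manifest must contain both train and val rows")
    y = np.asarray(labels)
    model = classifier.build_model(
        classifier.ModelConfig(input_shape=tuple(x.shape[1:])),
        seed=config.seed)
    tc = classifier.TrainConfig(epochs=config.epochs,
                                batch_size=config.batch_size,
                                learning_rate=config.learning_rate,
                                early_stop_patience=config.early_stop_patience,
                                seed=config.seed)
    model = classifier.train(model, x[is_train], y[is_train],
                             x[~is_train], y[~is_train], tc)
    _, predicted = model.predict(x[~is_train])
    cm = evaluate.build_confusion(y[~is_train], predicted)
    return model, cm, evaluate.class_metrics(cm)


def run_experiment(config: RunConfig) -> RunReport:
    """Execute both arms (raw and denoised) on one shared dataset."""
    t0 = time.time()
    composition = config.resolve_composition()
    noise = (None if config.snr_db is None
             else synth.NoiseSpec(snr_db=config.snr_db))
    logger.info("stage=synth composition=%s snr_db=%s seed=%d",
                config.composition, config.snr_db, config.seed)
    clips, manifest = synth.generate_clips(
        composition, sample_rate=config.sample_rate, noise=noise,
        seed=config.seed)
    labels = list(manifest["label"])

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh)
        manifest.to_csv(out_dir / "manifest.csv", index=False)

    metrics, confusions, histories = {}, {}, {}
    for arm, use_dwt in (("raw", False), ("denoised", True)):
        t_arm = time.time()
        logger.info("stage=features arm=%s denoise=%s", arm, use_dwt)
        x = featurize_clips(clips, config, apply_denoise=use_dwt)
        logger.info("stage=train arm=%s n=%d", arm, len(x))
        model, cm, m = _train_and_score(x, labels, manifest, config)
        metrics[arm], confusions[arm] = m, cm
        histories[arm] = model.history
        logger.info("stage=score arm=%s macro_f1=%.3f elapsed=%.1fs",
                    arm, m.macro_f1, time.time() - t_arm)
        if out_dir is not None:
            cm.to_frame().to_csv(out_dir / f"confusion_{arm}.csv")
            m.per_class.to_csv(out_dir / f"metrics_{arm}.csv")
            pd.DataFrame(model.history).to_csv(
                out_dir / f"history_{arm}.csv", index=False)
            model.save(out_dir / f"model_{arm}.npz")

    deltas = {k: getattr(metrics["denoised"], k) - getattr(metrics["raw"], k)
              for k in ("accuracy", "macro_precision", "macro_recall",
                        "macro_f1")}
    report = RunReport(config=config, manifest=manifest, metrics=metrics,
                       confusions=confusions, histories=histories,
                       deltas=deltas)
    if out_dir is not None:
        summary = {arm: {"accuracy": metrics[arm].accuracy,
                         "macro_f1": metrics[arm].macro_f1}
                   for arm in metrics} | {"deltas": deltas}
        with open(out_dir / "report.yaml", "w") as fh:
            yaml.safe_dump(summary, fh)
    logger.info("stage=done elapsed=%.1fs", time.time() - t0)
    return report


def nearest_mean_baseline(x: np.ndarray, labels, is_train: np.ndarray) -> float:
    """Validation accuracy of a trivial nearest-class-mean classifier on
    time-averaged mel spectra. A floor well above chance certifies that
    the synthetic task is learnable at all."""
    profiles = np.asarray(x).mean(axis=1)            # (n_clips, bands)
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    means = np.stack([profiles[is_train & (labels == c)].mean(axis=0)
                      for c in classes])
    dists = np.linalg.norm(profiles[~is_train][:, None, :] - means[None], axis=2)
    predicted = np.array(classes)[dists.argmin(axis=1)]
    return float((predicted == labels[~is_train]).mean())


def null_control(seed: int = 0, epochs: int = 10) -> float:
    """Validation accuracy after training on randomly shuffled labels.

    Uses the class-balanced desk-scale composition (clean audio) so the
    chance level is exactly 1/6; a sound training pipeline should land
    near it. With the study's imbalanced class mix a label-shuffled model
    can still learn the majority class (~1/3 of clips), so balance is a
    precondition for the 1/6 reference point.
    """
    config = RunConfig(composition="mini", snr_db=None, seed=seed,
                       epochs=epochs)
    clips, manifest = synth.generate_clips(
        BALANCED_MINI_COMPOSITION, sample_rate=config.sample_rate,
        noise=None, seed=seed)
    x = featurize_clips(clips, config, apply_denoise=False)
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(manifest["label"].to_numpy())
    is_train = (manifest["split"] == "train").to_numpy()
    model = classifier.build_model(
        classifier.ModelConfig(input_shape=tuple(x.shape[1:])), seed=seed)
    tc = classifier.TrainConfig(epochs=epochs, seed=seed)
    model = classifier.train(model, x[is_train], shuffled[is_train],
                             x[~is_train], shuffled[~is_train], tc)
    _, predicted = model.predict(x[~is_train])
    return float((np.asarray(predicted) == shuffled[~is_train]).mean())
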