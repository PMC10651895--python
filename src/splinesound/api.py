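"""High-level model/results interface.

`SiameseVAEClassifier` bundles a labelled dataset manifest with the
feature-extraction, architecture, split and training configurations;
``fit()`` runs the whole pipeline (split, featurize, train, fit
centroids, evaluate on the held-out test split) and returns a
:class:`FitResult` carrying the trained network, the per-epoch loss
history, the class centroids and the test confusion matrix, with a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeaturizeConfig
from .model import EncoderConfig, SNNVAE, classify
from .synthetic import DatasetManifest
from .train_eval import (
    ConfusionMatrix,
    MetricsReport,
    SplitConfig,
    TrainConfig,
    evaluate_features,
    featurize_manifest,
    fit_centroids,
    split_dataset,
    train_on_features,
)

__all__ = ["SiameseVAEClassifier", "FitResult"]


@dataclass
class SiameseVAEClassifier:
    """Siamese triplet-loss VAE classifier over a labelled WAV manifest."""

    manifest: DatasetManifest
    features: FeaturizeConfig = field(default_factory=FeaturizeConfig)
    encoder: EncoderConfig | None = None
    split: SplitConfig = field(default_factory=SplitConfig)
    training: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_directory(cls, dataset_dir: str | Path, **kwargs) -> "SiameseVAEClassifier":
        """Build from a dataset directory containing ``manifest.csv``."""
        manifest = DatasetManifest.from_csv(Path(dataset_dir) / "manifest.csv")
        return cls(manifest=manifest, **kwargs)

    def fit(self, seed: int | None = None) -> "FitResult":
        """Split, featurize, train and evaluate; returns a FitResult."""
        if seed is not None:
            self.split = replace(self.split, seed=seed)
            self.training = replace(self.training, seed=seed)
        enc_cfg = self.encoder or EncoderConfig(image_size=self.features.image_size)
        if enc_cfg.image_size != self.features.image_size:
            raise ValueError("encoder image_size must match the feature image_size")
        train_m, val_m, test_m = split_dataset(self.manifest, self.split)
        X, y = featurize_manifest(train_m, self.features)
        X_val, y_val = featurize_manifest(val_m, self.features)
        model = SNNVAE(enc_cfg, seed=self.training.seed)
        model, history = train_on_features(model, X, y, X_val, y_val, self.training)
        centroids = fit_centroids(np.atleast_2d(model.embed(X)), y)
        X_test, y_test = featurize_manifest(test_m, self.features)
        cm, metrics = evaluate_features(model, X_test, y_test, centroids)
        return FitResult(
            spec=self,
            model=model,
            history=history,
            centroids=centroids,
            confusion=cm,
            metrics=metrics,
            splits=(train_m, val_m, test_m),
        )


@dataclass
class FitResult:
    """Trained model plus diagnostics from one fit."""

    spec: SiameseVAEClassifier
    model: SNNVAE
    history: pd.DataFrame
    centroids: dict[str, np.ndarray]
    confusion: ConfusionMatrix
    metrics: MetricsReport
    splits: tuple[DatasetManifest, DatasetManifest, DatasetManifest]

    @property
    def test_accuracy(self) -> float:
        return self.metrics.accuracy

    def predict(self, X) -> list[tuple[str, float]]:
        """Nearest-centroid label and similarity score per featurized image."""
        emb = np.atleast_2d(self.model.embed(X))
        return [classify(e, self.centroids) for e in emb]

    def evaluate(self, manifest: DatasetManifest) -> tuple[ConfusionMatrix, MetricsReport]:
        from .train_eval import evaluate

        return evaluate(self.model, manifest, self.centroids, self.spec.features)

    def summary(self) -> str:
        """Plain-text summary of the fit, statsmodels-style."""
        last = self.history.iloc[-1] if len(self.history) else None
        lines = [
            "Siamese triplet-loss VAE classification results",
            "=" * 55,
            f"classes:            {', '.join(self.confusion.class_names)}",
            f"records (tr/va/te): {len(self.splits[0])}/{len(self.splits[1])}/{len(self.splits[2])}",
            f"latent dim:         {self.model.cfg.latent_dim}",
            f"image size:         {self.model.cfg.image_size}",
            f"epochs:             {len(self.history)}",
        ]
        if last is not None:
            lines += [
                f"final loss total:   {last['total']:.4f} "
                f"(triplet {last['triplet']:.4f}, recon {last['reconstruction']:.4f}, "
                f"kl {last['kl']:.4f})",
                f"final val accuracy: {last['val_accuracy']:.3f}",
            ]
        lines.append(f"test accuracy:      {self.metrics.accuracy:.3f}")
        lines.append("-" * 55)
        lines.append("per-class precision / recall:")
        for name in self.confusion.class_names:
            lines.append(
                f"  {name:<16} {self.metrics.precision.get(name, 0.0):.3f} / "
                f"{self.metrics.recall.get(name, 0.0):.3f}"
            )
        return "\n".join(lines)
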