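"""End-to-end workflow: redundancy filter -> split -> encode -> PCA -> ensemble.

:class:`RunConfig` captures every knob of a run and serializes to YAML so a
run's config echo plus its seed reproduce the outputs.  :class:`AcpPipeline`
holds the training-fitted state (encoder settings, PCA model, ensemble) and
guards against train/test leakage when evaluating.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import yaml

from .classify import EnsembleModel, KNNModel, SVMConfig, fit_ensemble, train_knn, train_nb, train_rf, train_svm
from .encoders import ENCODER_NAMES, FeatureMatrix, IPseAACConfig, encode_dataset
from .evaluate import ConfusionMatrix, MetricsReport, evaluate_predictions
from .feature_select import PCAModel, fit_pca, transform_pca
from .properties import PropertyTable, load_property_table
from .redundancy import DEFAULT_IDENTITY_THRESHOLD, reduce_redundancy
from .sequence_io import Dataset, split_dataset

__all__ = ["RunConfig", "AcpPipeline", "run_experiment", "ablation_table", "ABLATION_ROWS"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one full run; defaults reproduce the
    headline configuration: all four encoders fused, lambda=1, PCA at 95%
    retained variance, equal-weight SVM+RF+NB ensemble, 70/30 split."""

    encoders: tuple[str, ...] = ENCODER_NAMES
    lam: int = 1
    pse_weight: float = 0.05
    tier_mode: str = "canonical"
    pca: bool = True
    pca_retention: float = 0.95
    pca_k: int | None = None
    classifier: str = "ensemble"  # ensemble | svm | rf | nb | knn
    weight_mode: str = "equal"
    tie_break: str = "svm"
    knn_k: int = 5
    n_trees: int = 100
    svm_c_grid: tuple[float, ...] = SVMConfig().c_grid
    svm_gamma_grid: tuple[float, ...] = SVMConfig().gamma_grid
    cv_folds: int = 5
    class_weight: str | None = None
    train_fraction: float = 0.7
    stratified: bool = True
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    apply_redundancy: bool = True
    property_table_path: str | None = None
    seed: int = 0

    def ipseaac_config(self) -> IPseAACConfig:
        return IPseAACConfig(lam=self.lam, weight=self.pse_weight, tier_mode=self.tier_mode)

    def svm_config(self) -> SVMConfig:
        return SVMConfig(
            c_grid=tuple(self.svm_c_grid),
            gamma_grid=tuple(self.svm_gamma_grid),
            cv_folds=self.cv_folds,
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["encoders"] = list(self.encoders)
        payload["svm_c_grid"] = list(self.svm_c_grid)
        payload["svm_gamma_grid"] = list(self.svm_gamma_grid)
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        for key in ("encoders", "svm_c_grid", "svm_gamma_grid"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class AcpPipeline:
    """Training-fitted state of the workflow."""

    config: RunConfig
    property_table: PropertyTable
    pca_model: PCAModel | None = None
    model: EnsembleModel | KNNModel | object | None = None
    train_ids: frozenset[str] = frozenset()

    def encode(self, dataset: Dataset) -> FeatureMatrix:
        features = encode_dataset(
            dataset,
            encoder_names=self.config.encoders,
            config=self.config.ipseaac_config(),
            table=self.property_table,
        )
        if self.pca_model is not None:
            features = transform_pca(self.pca_model, features)
        return features

    def fit(self, train: Dataset) -> "AcpPipeline":
        cfg = self.config
        labels = [r.label for r in train]
        if any(l is None for l in labels):
            raise ValueError("training dataset must be fully labeled")
        features = encode_dataset(
            train, encoder_names=cfg.encoders, config=cfg.ipseaac_config(), table=self.property_table
        )
        if cfg.pca:
            self.pca_model = fit_pca(features, retention=cfg.pca_retention, k=cfg.pca_k)
            features = transform_pca(self.pca_model, features)
        y = np.asarray(labels)
        if cfg.classifier == "ensemble":
            self.model = fit_ensemble(
                features, y,
                svm_config=cfg.svm_config(),
                n_trees=cfg.n_trees,
                weight_mode=cfg.weight_mode,
                tie_break=cfg.tie_break,
                seed=cfg.seed,
                class_weight=cfg.class_weight,
            )
        elif cfg.classifier == "svm":
            self.model = train_svm(features, y, cfg.svm_config(), seed=cfg.seed, class_weight=cfg.class_weight)
        elif cfg.classifier == "rf":
            self.model = train_rf(features, y, n_trees=cfg.n_trees, seed=cfg.seed, class_weight=cfg.class_weight)
        elif cfg.classifier == "nb":
            self.model = train_nb(features, y)
        elif cfg.classifier == "knn":
            self.model = train_knn(features, y, k=cfg.knn_k)
        else:
            raise ValueError(f"unknown classifier {cfg.classifier!r}")
        self.train_ids = frozenset(train.ids)
        return self

    def predict(self, dataset: Dataset) -> np.ndarray:
        if self.model is None:
            raise ValueError("pipeline is not fitted")
        features = self.encode(dataset)
        return np.asarray(self.model.predict(features))

    def evaluate(self, test: Dataset) -> tuple[MetricsReport, ConfusionMatrix]:
        """Evaluate on a held-out dataset; refuses train/test id overlap."""
        if len(test) == 0:
            raise ValueError("cannot evaluate on an empty test set")
        overlap = self.train_ids & set(test.ids)
        if overlap:
            raise ValueError(f"train/test leakage: shared ids {sorted(overlap)[:5]}")
        labels = [r.label for r in test]
        if any(l is None for l in labels):
            raise ValueError("test dataset must be fully labeled")
        predicted = self.predict(test)
        return evaluate_predictions(np.asarray(labels), predicted)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump(self, path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "AcpPipeline":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a fitted pipeline")
        return obj


def run_experiment(
    dataset: Dataset, config: RunConfig | None = None
) -> tuple[AcpPipeline, MetricsReport, ConfusionMatrix, Dataset, Dataset]:
    """Full workflow on one labeled dataset: redundancy filter, stratified
    70/30 split, fit, evaluate.  Returns the fitted pipeline, the test-set
    metrics and confusion matrix, and the two partitions."""
    config = config or RunConfig()
    if config.apply_redundancy:
        dataset = reduce_redundancy(dataset, threshold=config.identity_threshold)
    train, test = split_dataset(
        dataset,
        train_fraction=config.train_fraction,
        stratified=config.stratified,
        seed=config.seed,
    )
    table = load_property_table(config.property_table_path)
    pipeline = AcpPipeline(config=config, property_table=table).fit(train)
    report, cm = pipeline.evaluate(test)
    return pipeline, report, cm, train, test


# The 13-row ablation design: four single encoders, six pairwise fusions,
# and the all-four fusion + PCA at lambda = 1, 2, 3.
ABLATION_ROWS: tuple[tuple[str, tuple[str, ...], bool, int], ...] = (
    ("AAC", ("AAC",), False, 1),
    ("DPC", ("DPC",), False, 1),
    ("TPC", ("TPC",), False, 1),
    ("IPseAAC", ("IPseAAC",), False, 1),
    ("AAC+DPC", ("AAC", "DPC"), False, 1),
    ("AAC+TPC", ("AAC", "TPC"), False, 1),
    ("AAC+IPseAAC", ("AAC", "IPseAAC"), False, 1),
    ("DPC+TPC", ("DPC", "TPC"), False, 1),
    ("DPC+IPseAAC", ("DPC", "IPseAAC"), False, 1),
    ("TPC+IPseAAC", ("TPC", "IPseAAC"), False, 1),
    ("fused+PCA (lam=1)", ENCODER_NAMES, True, 1),
    ("fused+PCA (lam=2)", ENCODER_NAMES, True, 2),
    ("fused+PCA (lam=3)", ENCODER_NAMES, True, 3),
)


def ablation_table(dataset: Dataset, config: RunConfig | None = None):
    """Evaluate the 13-model ablation design on one dataset.

    Returns a DataFrame with one row per model (accuracy, sensitivity,
    specificity, MCC, F1 as fractions) plus the feature width used.
    """
    import pandas as pd

    base = config or RunConfig()
    if base.apply_redundancy:
        dataset = reduce_redundancy(dataset, threshold=base.identity_threshold)
    train, test = split_dataset(
        dataset, train_fraction=base.train_fraction, stratified=base.stratified, seed=base.seed
    )
    table = load_property_table(base.property_table_path)

    rows = []
    for name, encoders, use_pca, lam in ABLATION_ROWS:
        cfg = replace(base, encoders=encoders, pca=use_pca, lam=lam, apply_redundancy=False)
        pipe = AcpPipeline(config=cfg, property_table=table).fit(train)
        report, _ = pipe.evaluate(test)
        raw_width = sum({"AAC": 20, "DPC": 400, "TPC": 8000, "IPseAAC": 20 + lam}[e] for e in encoders)
        rows.append(
            {
                "model": name,
                "n_features": raw_width,
                "n_retained": pipe.pca_model.retained_dim if pipe.pca_model else raw_width,
                "accuracy": report.accuracy,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
                "mcc": report.mcc,
                "f1": report.f1,
            }
        )
    return pd.DataFrame(rows)
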