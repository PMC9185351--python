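"""Base classifiers and the weighted-voting ensemble.

The ensemble combines an RBF-kernel SVM (hyperparameters picked by
grid-searched cross-validation), a 100-tree random forest, and Gaussian
naive Bayes.  Each fitted base casts one vote per test peptide; a class's
score is the summed weight of the bases voting for it and the argmax wins.
Exact weight ties fall back to the SVM's vote (the strongest individual
learner) or to the training majority class, per configuration.  KNN is
provided as an optional standalone learner for ablations; it is never part
of the default ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .encoders import FeatureMatrix

__all__ = [
    "SVMConfig",
    "EnsembleModel",
    "KNNModel",
    "train_svm",
    "train_rf",
    "train_nb",
    "train_knn",
    "fit_ensemble",
    "ensemble_predict",
]

# canonical RBF-SVM search grid: C in 2^-5..2^15, gamma in 2^-15..2^3, step 2^2
DEFAULT_C_GRID = tuple(float(2.0**e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0**e) for e in range(-15, 4, 2))


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM grid-search settings; ties prefer smaller C, then smaller gamma."""

    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("SVM grids must be non-empty")
        if any(v <= 0 for v in self.c_grid) or any(v <= 0 for v in self.gamma_grid):
            raise ValueError("C and gamma must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _as_array(data: FeatureMatrix | np.ndarray) -> np.ndarray:
    return data.values if isinstance(data, FeatureMatrix) else np.asarray(data, dtype=float)


def _check_labels(y: Sequence[str]) -> np.ndarray:
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    return y


def train_svm(
    train: FeatureMatrix | np.ndarray,
    labels: Sequence[str],
    config: SVMConfig | None = None,
    seed: int = 0,
    class_weight: str | None = None,
) -> SVC:
    """Grid-search (C, gamma) by stratified cross-validated accuracy and
    refit on the full training set with the winner."""
    config = config or SVMConfig()
    X = _as_array(train)
    y = _check_labels(labels)
    folds = min(config.cv_folds, int(np.unique(y, return_counts=True)[1].min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    best: tuple[float, float, float] | None = None  # (-score, C, gamma)
    for C in sorted(config.c_grid):
        for gamma in sorted(config.gamma_grid):
            clf = SVC(C=C, gamma=gamma, kernel="rbf", class_weight=class_weight)
            score = cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean()
            key = (-score, C, gamma)
            if best is None or key < best:
                best = key
    assert best is not None
    final = SVC(C=best[1], gamma=best[2], kernel="rbf", class_weight=class_weight)
    final.fit(X, y)
    return final


def train_rf(
    train: FeatureMatrix | np.ndarray,
    labels: Sequence[str],
    n_trees: int = 100,
    seed: int = 0,
    class_weight: str | None = None,
) -> RandomForestClassifier:
    """Bootstrap-bagged forest with random feature subsetting per split."""
    X = _as_array(train)
    y = _check_labels(labels)
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, bootstrap=True, class_weight=class_weight
    )
    clf.fit(X, y)
    return clf


def train_nb(train: FeatureMatrix | np.ndarray, labels: Sequence[str]) -> GaussianNB:
    """Gaussian class-conditional naive Bayes with floored variances."""
    X = _as_array(train)
    y = _check_labels(labels)
    clf = GaussianNB(var_smoothing=1e-9)
    clf.fit(X, y)
    return clf


@dataclass(frozen=True)
class KNNModel:
    """k-nearest-neighbour classifier with deterministic tie handling:
    distance ties prefer the lower training-row index (odd k rules out
    vote ties)."""

    X: np.ndarray
    y: np.ndarray
    k: int

    def predict(self, data: FeatureMatrix | np.ndarray) -> np.ndarray:
        Q = _as_array(data)
        d = cdist(Q, self.X)  # Euclidean
        # stable sort => equal distances resolved by lower row index
        nearest = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        out = []
        for row in nearest:
            votes, counts = np.unique(self.y[row], return_counts=True)
            out.append(votes[np.argmax(counts)])
        return np.asarray(out)


def train_knn(train: FeatureMatrix | np.ndarray, labels: Sequence[str], k: int = 5) -> KNNModel:
    X = _as_array(train)
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("training labels are empty")
    if k % 2 == 0:
        raise ValueError("k must be odd to rule out vote ties")
    if k > len(y):
        raise ValueError(f"k={k} exceeds training size {len(y)}")
    return KNNModel(X=X, y=y, k=k)


@dataclass(frozen=True)
class EnsembleModel:
    """Fitted (SVM, RF, NB) triple with voting weights."""

    svm: SVC
    rf: RandomForestClassifier
    nb: GaussianNB
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tie_break: str = "svm"
    majority_class: str | None = None
    base_cv_accuracy: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights) or not any(w > 0 for w in self.weights):
            raise ValueError("weights must be non-negative with at least one positive")
        if self.tie_break not in ("svm", "majority_class"):
            raise ValueError("tie_break must be 'svm' or 'majority_class'")

    @property
    def base_models(self):
        return (self.svm, self.rf, self.nb)

    def predict(self, data: FeatureMatrix | np.ndarray) -> np.ndarray:
        return ensemble_predict(self, data)

    def base_votes(self, data: FeatureMatrix | np.ndarray) -> np.ndarray:
        X = _as_array(data)
        return np.stack([m.predict(X) for m in self.base_models], axis=1)


def ensemble_predict(model: EnsembleModel, data: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Weighted majority vote over the three base predictions, row by row."""
    X = _as_array(data)
    if X.shape[1] != model.svm.shape_fit_[1]:
        raise ValueError(
            f"data has {X.shape[1]} columns; ensemble was fitted on {model.svm.shape_fit_[1]}"
        )
    votes = np.stack([m.predict(X) for m in model.base_models], axis=1)  # (n, 3)
    out = np.empty(X.shape[0], dtype=votes.dtype)
    for i, row in enumerate(votes):
        scores: dict[str, float] = {}
        for label, w in zip(row, model.weights):
            scores[label] = scores.get(label, 0.0) + w
        top = max(scores.values())
        winners = sorted(c for c, s in scores.items() if s == top)
        if len(winners) == 1:
            out[i] = winners[0]
        elif model.tie_break == "svm":
            out[i] = row[0]
        else:
            out[i] = model.majority_class if model.majority_class is not None else row[0]
    return out


def fit_ensemble(
    train: FeatureMatrix | np.ndarray,
    labels: Sequence[str],
    svm_config: SVMConfig | None = None,
    n_trees: int = 100,
    weight_mode: str = "equal",
    tie_break: str = "svm",
    seed: int = 0,
    class_weight: str | None = None,
) -> EnsembleModel:
    """Train the three bases and set voting weights.

    ``weight_mode='equal'`` gives unit weights; ``'cv_accuracy'`` weights
    each base by its stratified cross-validated training accuracy.
    """
    if weight_mode not in ("equal", "cv_accuracy"):
        raise ValueError("weight_mode must be 'equal' or 'cv_accuracy'")
    X = _as_array(train)
    y = _check_labels(labels)
    svm_config = svm_config or SVMConfig()

    svm = train_svm(X, y, svm_config, seed=seed, class_weight=class_weight)
    rf = train_rf(X, y, n_trees=n_trees, seed=seed, class_weight=class_weight)
    nb = train_nb(X, y)

    classes, counts = np.unique(y, return_counts=True)
    majority = str(classes[np.argmax(counts)])

    cv_acc = None
    if weight_mode == "cv_accuracy":
        folds = min(svm_config.cv_folds, int(counts.min()))
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        accs = []
        for proto in (
            SVC(C=svm.C, gamma=svm.gamma, kernel="rbf", class_weight=class_weight),
            RandomForestClassifier(n_estimators=n_trees, random_state=seed, class_weight=class_weight),
            GaussianNB(var_smoothing=1e-9),
        ):
            accs.append(float(cross_val_score(proto, X, y, cv=cv, scoring="accuracy").mean()))
        cv_acc = tuple(accs)
        weights = tuple(accs)
    else:
        weights = (1.0, 1.0, 1.0)

    return EnsembleModel(
        svm=svm,
        rf=rf,
        nb=nb,
        weights=weights,  # type: ignore[arg-type]
        tie_break=tie_break,
        majority_class=majority,
        base_cv_accuracy=cv_acc,
    )
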