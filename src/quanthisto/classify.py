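"""Cell-type recognition with RBF-SVM classifiers.

Five cell-type categories are distinguished across all sections and time
points: xylem vessels/parenchyma, xylem fibers, cambium, phloem bundle
cells (companion cells and sieve elements), and parenchymatic phloem cells.
One classifier is built per genotype and time point from manually labeled
cells: the labeled table is split into a learning set (two thirds) and a
held-out test set, features are standardized on the learning portion only,
hyperparameters and the feature subset are chosen by V-fold cross
validation (five randomly permuted train/test reiterations), and the
feature subset comes from a greedy forward search over the 16 descriptors
preferring few features, low fold-to-fold variation and high accuracy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .descriptors import FEATURE_NAMES


class CellClass(str, Enum):
    """The five vascular cell-type categories."""

    XYLEM_VESSEL_PARENCHYMA = "xylem_vessel_parenchyma"
    XYLEM_FIBER = "xylem_fiber"
    CAMBIUM = "cambium"
    PHLOEM_BUNDLE = "phloem_bundle"
    PHLOEM_PARENCHYMA = "phloem_parenchyma"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CLASS_NAMES = [c.value for c in CellClass]

#: default hyperparameter grid searched inside cross-validation
DEFAULT_C_GRID = (1.0, 10.0, 100.0)
DEFAULT_GAMMA_SCALE_GRID = (0.1, 1.0, 10.0)


@dataclass
class TrainingSet:
    """Stratified learn/test split of a labeled feature table."""

    learn: pd.DataFrame
    test: pd.DataFrame
    fraction: float
    seed: int

    @property
    def n_learn(self) -> int:
        return len(self.learn)

    @property
    def n_test(self) -> int:
        return len(self.test)


def split_training(labeled_table: pd.DataFrame, fraction: float = 2 / 3,
                   seed: int = 0, class_column: str = "class") -> TrainingSet:
    """Stratified split into a learning set and a held-out test set.

    Every class must have at least 2 cells and the test set must be
    non-empty (``fraction < 1``).
    """
    if class_column not in labeled_table:
        raise ValueError(f"table lacks a {class_column!r} column")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1): the test set may not be empty")
    counts = labeled_table[class_column].value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(
            f"classes with fewer than 2 cells cannot be split: "
            f"{', '.join(map(str, thin.index))}")
    learn, test = train_test_split(
        labeled_table, train_size=fraction, random_state=seed,
        stratify=labeled_table[class_column])
    return TrainingSet(learn.reset_index(drop=True),
                       test.reset_index(drop=True), fraction, seed)


def _make_svm(C: float, gamma) -> Pipeline:
    # standardization lives inside the pipeline so each CV fold fits its
    # normalization on its own training portion only
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(C=C, gamma=gamma, kernel="rbf")),
    ])


def crossval_svm(data: pd.DataFrame, features: list[str], C: float = 10.0,
                 gamma="scale", V: int = 5, seed: int = 0,
                 class_column: str = "class"):
    """V-fold cross-validated accuracy of an RBF-SVM on a feature subset.

    Folds are stratified with a seeded shuffle (V randomly permuted
    train/test reiterations).  Returns ``(mean_acc, sd_acc, per_fold)``.
    Features without variance in a fold's training portion are dropped for
    that fold with a warning.
    """
    unknown = [f for f in features if f not in data.columns]
    if unknown:
        raise ValueError(f"unknown features: {unknown}")
    if V < 2:
        raise ValueError("V must be >= 2")
    X = data[features].to_numpy(dtype=float)
    y = data[class_column].to_numpy()
    skf = StratifiedKFold(n_splits=V, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        Xtr, Xte = X[train_idx], X[test_idx]
        keep = Xtr.std(axis=0) > 0
        if not keep.all():
            dropped = [f for f, k in zip(features, keep) if not k]
            warnings.warn(f"zero-variance features dropped in a fold: {dropped}")
            if not keep.any():
                accs.append(0.0)
                continue
            Xtr, Xte = Xtr[:, keep], Xte[:, keep]
        model = _make_svm(C, gamma)
        model.fit(Xtr, y[train_idx])
        accs.append(float(model.score(Xte, y[test_idx])))
    accs = np.array(accs)
    return float(accs.mean()), float(accs.std(ddof=1)), accs


def tune_hyperparameters(data: pd.DataFrame, features: list[str], V: int = 5,
                         seed: int = 0, c_grid=DEFAULT_C_GRID,
                         gamma_grid=DEFAULT_GAMMA_SCALE_GRID,
                         class_column: str = "class"):
    """Small log-grid search for (C, gamma) by cross-validated accuracy.

    Gamma values are multiples of sklearn's 'scale' heuristic
    ``1 / (n_features * Var(X))``.
    """
    X = data[features].to_numpy(dtype=float)
    base_gamma = 1.0 / (X.shape[1] * X.var()) if X.var() > 0 else 1.0
    best = None
    for C in c_grid:
        for gm in gamma_grid:
            gamma = base_gamma * gm
            mean, sd, _ = crossval_svm(data, features, C=C, gamma=gamma,
                                       V=V, seed=seed, class_column=class_column)
            key = (mean, -sd)
            if best is None or key > best[0]:
                best = (key, C, gamma, mean, sd)
    _, C, gamma, mean, sd = best
    return C, gamma, mean, sd


def greedy_feature_selection(data: pd.DataFrame,
                             features: list[str] | None = None,
                             max_k: int = 16, V: int = 5, seed: int = 0,
                             C: float = 10.0, gamma="scale",
                             tolerance: float = 0.005,
                             class_column: str = "class"):
    """Greedy forward feature selection under V-fold cross validation.

    At step k the feature that maximizes CV mean accuracy given the k-1
    already selected is added (ties broken by the fixed feature order).
    Returns ``(path, recommended)`` where ``path`` is a list of
    ``(feature_set, mean_acc, sd_acc)`` for sizes 1..max_k and
    ``recommended`` is the entry preferred by the lexicographic criterion:
    accuracy within ``tolerance`` of the best, then fewest features, then
    smallest fold-to-fold standard deviation.
    """
    if features is None:
        features = [f for f in FEATURE_NAMES if f in data.columns]
    classes = data[class_column].unique()
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for feature selection")
    selected: list[str] = []
    remaining = list(features)
    path = []
    while remaining and len(selected) < max_k:
        results = []
        for f in remaining:
            mean, sd, _ = crossval_svm(data, selected + [f], C=C, gamma=gamma,
                                       V=V, seed=seed, class_column=class_column)
            results.append((mean, -remaining.index(f), f, sd))
        mean, _, fbest, sd = max(results)
        selected = selected + [fbest]
        remaining.remove(fbest)
        path.append((tuple(selected), mean, sd))
    best_acc = max(m for _, m, _ in path)
    candidates = [(len(fs), sd, i) for i, (fs, m, sd) in enumerate(path)
                  if m >= best_acc - tolerance]
    _, _, idx = min(candidates)
    return path, path[idx]


@dataclass
class Classifier:
    """A trained per-(genotype, timepoint) cell-type classifier.

    Carries the selected feature subset, the fitted standardization + SVM
    pipeline, and the cross-validation record of the selected model.
    """

    selected_features: list[str]
    C: float
    gamma: float
    model: Pipeline
    cv_mean: float
    cv_sd: float
    cv_folds: list[float]
    classes: list[str] = field(default_factory=lambda: list(CLASS_NAMES))
    genotype: str = "synthetic"
    timepoint: str = "NA"

    @classmethod
    def train(cls, learn: pd.DataFrame, features: list[str], C: float,
              gamma: float, V: int = 5, seed: int = 0,
              class_column: str = "class", genotype: str = "synthetic",
              timepoint: str = "NA") -> "Classifier":
        if not features:
            raise ValueError("selected_features must be non-empty")
        mean, sd, folds = crossval_svm(learn, features, C=C, gamma=gamma,
                                       V=V, seed=seed, class_column=class_column)
        model = _make_svm(C, gamma)
        model.fit(learn[features].to_numpy(dtype=float),
                  learn[class_column].to_numpy())
        return cls(list(features), float(C),
                   float(gamma) if np.isscalar(gamma) and not isinstance(gamma, str)
                   else gamma,
                   model, mean, sd, [float(a) for a in folds],
                   genotype=genotype, timepoint=str(timepoint))

    def predict(self, table: pd.DataFrame) -> pd.Series:
        missing = [f for f in self.selected_features if f not in table.columns]
        if missing:
            raise ValueError(f"feature table lacks columns: {missing}")
        if len(table) == 0:
            return pd.Series([], dtype=object, name="class")
        pred = self.model.predict(
            table[self.selected_features].to_numpy(dtype=float))
        return pd.Series(pred, index=table.index, name="class")

    # -- persistence: params JSON next to a joblib model blob --------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        params = {
            "selected_features": self.selected_features,
            "C": self.C, "gamma": self.gamma,
            "cv_mean": self.cv_mean, "cv_sd": self.cv_sd,
            "cv_folds": self.cv_folds, "classes": self.classes,
            "genotype": self.genotype, "timepoint": self.timepoint,
        }
        (directory / "params.json").write_text(json.dumps(params, indent=2))
        joblib.dump(self.model, directory / "model.joblib")

    @classmethod
    def load(cls, directory) -> "Classifier":
        directory = Path(directory)
        params = json.loads((directory / "params.json").read_text())
        model = joblib.load(directory / "model.joblib")
        return cls(model=model, **params)


def predict_classes(classifier: Classifier, table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the table with a ``class`` column of predictions."""
    out = table.copy()
    out["class"] = classifier.predict(table)
    return out


def accuracy_report(pred, truth):
    """Per-class recall, confusion matrix, and overall mean/median accuracy.

    ``pred`` and ``truth`` are aligned label sequences.  Rows of the
    confusion matrix are true classes, columns predictions; row sums equal
    the true class counts.  Classes present only in the predictions are
    kept as columns and flagged.
    """
    pred = pd.Series(list(pred)).astype(str)
    truth = pd.Series(list(truth)).astype(str)
    if len(pred) != len(truth):
        raise ValueError("prediction and truth lengths differ")
    true_classes = sorted(truth.unique())
    all_classes = sorted(set(true_classes) | set(pred.unique()))
    confusion = pd.crosstab(truth, pred).reindex(
        index=true_classes, columns=all_classes, fill_value=0)
    per_class = pd.Series(
        {c: confusion.loc[c, c] / confusion.loc[c].sum() if c in confusion.columns
         else 0.0 for c in true_classes}, name="recall")
    unseen = sorted(set(pred.unique()) - set(true_classes))
    return {
        "per_class": per_class,
        "confusion": confusion,
        "overall": float((pred == truth).mean()),
        "mean_accuracy": float(per_class.mean()),
        "median_accuracy": float(per_class.median()),
        "unseen_predicted_classes": unseen,
    }
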