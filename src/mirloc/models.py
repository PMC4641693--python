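"""Classifier training, cross-validation, feature ranking, persistence.

Five classifier families are supported (random forest by default, plus SVM
with an RBF kernel, Gaussian naive Bayes, k-nearest neighbours and a single
decision tree), all scoring candidates with the positive-class probability.
Class imbalance is expressed purely through the sampled positive:negative
ratio of the training set; no internal reweighting is applied.

AUC is computed in the Mann-Whitney formulation (ties credit 1/2), which
equals the trapezoidal area under the ROC curve swept over all distinct
scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datasets import LabeledDataset, split_folds
from .errors import (
    CorruptModelFile,
    SchemaMismatch,
    SingleClassDataset,
    TooFewSamples,
    UnknownAlgorithm,
    UnsupportedAlgorithm,
)
from .features import SCHEMA, SCHEMA_VERSION, N_FEATURES

FORMAT_VERSION = 1

#: declared defaults; every hyperparameter can be overridden via ``params``
DEFAULT_PARAMS: dict[str, dict] = {
    "rf": {"n_estimators": 500, "max_features": "sqrt"},
    "svm": {"C": 1.0, "gamma": "scale", "kernel": "rbf"},
    "nb": {},
    "knn": {"n_neighbors": 5},
    "dt": {},
}


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(probability=True, random_state=seed, **params)),
            ]
        )
    if algorithm == "nb":
        return GaussianNB(**params)
    if algorithm == "knn":
        return KNeighborsClassifier(**params)
    if algorithm == "dt":
        return DecisionTreeClassifier(random_state=seed, **params)
    raise UnknownAlgorithm(
        f"unknown algorithm {algorithm!r}; choose from {sorted(DEFAULT_PARAMS)}"
    )


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to refuse stale inputs."""

    algorithm: str
    params: dict
    schema_version: str
    seed: int
    n_pos: int
    n_neg: int
    rpns: int
    estimator: object
    format_version: int = FORMAT_VERSION

    def header(self) -> dict:
        return {
            "format_version": self.format_version,
            "algorithm": self.algorithm,
            "params": self.params,
            "schema_version": self.schema_version,
            "seed": self.seed,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "rpns": self.rpns,
        }

    def predict_scores(
        self, X: np.ndarray, schema_version: str = SCHEMA_VERSION
    ) -> np.ndarray:
        """Positive-class probabilities for schema-aligned feature rows."""
        if schema_version != self.schema_version:
            raise SchemaMismatch(
                f"model trained under schema {self.schema_version!r}, "
                f"features are {schema_version!r}"
            )
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != N_FEATURES:
            raise SchemaMismatch(f"expected {N_FEATURES} columns, got {X.shape[1]}")
        proba = self.estimator.predict_proba(X)
        pos_col = list(self.estimator.classes_).index(1)
        return proba[:, pos_col]


def train(
    dataset: LabeledDataset,
    algorithm: str = "rf",
    params: dict | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit one classifier on a labeled dataset."""
    if dataset.n_pos == 0 or dataset.n_neg == 0:
        raise SingleClassDataset("training requires both positive and negative samples")
    merged = {**DEFAULT_PARAMS.get(algorithm, {}), **(params or {})}
    if algorithm not in DEFAULT_PARAMS:
        raise UnknownAlgorithm(
            f"unknown algorithm {algorithm!r}; choose from {sorted(DEFAULT_PARAMS)}"
        )
    est = _make_estimator(algorithm, merged, seed)
    est.fit(dataset.X, dataset.y)
    return TrainedModel(
        algorithm=algorithm,
        params=merged,
        schema_version=dataset.schema_version,
        seed=seed,
        n_pos=dataset.n_pos,
        n_neg=dataset.n_neg,
        rpns=dataset.rpns,
        estimator=est,
    )


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney form; ties credit 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassDataset("AUC needs both positive and negative labels")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class CVReport:
    """Per-fold AUCs of a k-fold cross-validation run."""

    fold_aucs: list[float]
    fold_sizes: list[int]
    seed: int
    algorithm: str

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    def to_json(self) -> str:
        return json.dumps(
            {
                "algorithm": self.algorithm,
                "seed": self.seed,
                "fold_aucs": self.fold_aucs,
                "fold_sizes": self.fold_sizes,
                "mean_auc": self.mean_auc,
            },
            indent=2,
        )


def crossval(
    dataset: LabeledDataset,
    k: int = 10,
    algorithm: str = "rf",
    params: dict | None = None,
    seed: int = 0,
) -> CVReport:
    """Grouped, stratified k-fold cross-validation scored by AUC.

    Folds never split a pre-miRNA between train and test, so a positive
    cannot leak information to its sibling negatives.
    """
    folds = split_folds(dataset, k, seed=seed)
    aucs, sizes = [], []
    all_idx = np.arange(len(dataset.y))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        test = dataset.subset(test_idx)
        if test.n_pos == 0 or test.n_neg == 0:
            raise TooFewSamples(f"fold {f} lacks one class; use fewer folds")
        model = train(dataset.subset(train_idx), algorithm, params, seed=seed)
        scores = model.predict_scores(test.X, dataset.schema_version)
        aucs.append(auc(scores, test.y))
        sizes.append(len(test_idx))
    return CVReport(fold_aucs=aucs, fold_sizes=sizes, seed=seed, algorithm=algorithm)


def gini_importance(model: TrainedModel) -> list[tuple[str, float, int]]:
    """(feature name, Gini importance, 1-based rank), sorted descending.

    Importances are sklearn's mean decrease in impurity, normalised to sum
    to 1. Only tree-based models (rf, dt) expose them.
    """
    if model.algorithm not in ("rf", "dt"):
        raise UnsupportedAlgorithm(
            f"Gini importance is undefined for algorithm {model.algorithm!r}"
        )
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = np.argsort(-imp, kind="stable")
    return [(SCHEMA.names[i], float(imp[i]), rank + 1) for rank, i in enumerate(order)]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist the model as a single artifact with an embedded JSON header."""
    joblib.dump({"header": model.header(), "estimator": model.estimator}, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model; fails loudly on corrupt files or stale versions."""
    try:
        payload = joblib.load(path)
        header = payload["header"]
        estimator = payload["estimator"]
    except SchemaMismatch:
        raise
    except Exception as exc:
        raise CorruptModelFile(f"cannot read model file {path}: {exc}") from exc
    if header.get("format_version") != FORMAT_VERSION:
        raise CorruptModelFile(
            f"model format_version {header.get('format_version')} != {FORMAT_VERSION}"
        )
    if header.get("schema_version") != SCHEMA_VERSION:
        raise SchemaMismatch(
            f"model schema {header.get('schema_version')!r} != current {SCHEMA_VERSION!r}"
        )
    return TrainedModel(
        algorithm=header["algorithm"],
        params=header["params"],
        schema_version=header["schema_version"],
        seed=header["seed"],
        n_pos=header["n_pos"],
        n_neg=header["n_neg"],
        rpns=header["rpns"],
        estimator=estimator,
        format_version=header["format_version"],
    )
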