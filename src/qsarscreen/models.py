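"""The four-classifier ensemble: SVM, random forest, XGBoost and kNN.

Each classifier is wrapped to predict over *named* descriptors, with
training reproducible from an explicit seed. Scale-sensitive algorithms
(SVM, kNN) standardize descriptors internally using train-set mean/SD;
tree ensembles consume raw values. The consensus rule is hard-label
unanimity: a compound is consensus-active only when all four models assign
active-probability >= 0.5.

Default hyperparameters: RF 500 trees; XGBoost 300 rounds, depth 6,
learning rate 0.1; SVM radial kernel with Platt-style probability
calibration; kNN k = 5 with inverse-distance-weighted vote fraction as the
probability. All overridable through :class:`ModelConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .containers import DescriptorMatrix, ValidationError

ALGORITHMS = ("svm", "random_forest", "xgboost", "knn")
PROBABILITY_CUTOFF = 0.5  # p >= 0.5 -> active

_DEFAULTS: dict[str, dict] = {
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "random_forest": {"n_estimators": 500, "n_jobs": 1},
    "xgboost": {
        "n_estimators": 300,
        "max_depth": 6,
        "learning_rate": 0.1,
        "n_jobs": 1,
        "eval_metric": "logloss",
    },
    "knn": {"n_neighbors": 5, "weights": "distance"},
}


@dataclass(frozen=True)
class ModelConfig:
    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(
                f"algorithm must be one of {ALGORITHMS}; got {self.algorithm!r}"
            )

    def build(self):
        params = dict(_DEFAULTS[self.algorithm])
        params.update(self.hyperparameters)
        if self.algorithm == "svm":
            # Platt-style sigmoid calibration turns SVM margins into probabilities
            svc = SVC(random_state=self.seed, **params)
            return Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("clf", CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)),
                ]
            )
        if self.algorithm == "knn":
            return Pipeline(
                [("scale", StandardScaler()), ("clf", KNeighborsClassifier(**params))]
            )
        if self.algorithm == "random_forest":
            return RandomForestClassifier(random_state=self.seed, **params)
        return XGBClassifier(random_state=self.seed, **params)


def as_binary_labels(y) -> np.ndarray:
    """Normalize labels to an int vector with 1 = active, 0 = inactive."""
    arr = np.asarray(y)
    if arr.dtype.kind in "USO":
        mapped = np.where(arr == "active", 1, np.where(arr == "inactive", 0, -1))
        if (mapped == -1).any():
            bad = sorted(set(arr[(mapped == -1)].tolist()))
            raise ValidationError(f"unrecognized labels: {bad}")
        return mapped.astype(int)
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1}:
        raise ValidationError(f"binary labels must be 0/1 or active/inactive; got {sorted(uniq)}")
    return arr.astype(int)


@dataclass
class TrainedModel:
    """A fitted classifier bound to the descriptor names it was trained on."""

    config: ModelConfig
    estimator: object
    descriptor_names: list[str]

    def _matrix(self, X: DescriptorMatrix) -> np.ndarray:
        missing = [n for n in self.descriptor_names if n not in X.frame.columns]
        if missing:
            raise ValidationError(f"query is missing trained descriptors: {missing}")
        return X.frame[self.descriptor_names].to_numpy(dtype=float)

    def predict_proba(self, X: DescriptorMatrix) -> np.ndarray:
        """Per-compound probability of the active class, in [0, 1]."""
        proba = self.estimator.predict_proba(self._matrix(X))
        classes = np.asarray(getattr(self.estimator, "classes_", [0, 1]))
        active_col = int(np.flatnonzero(classes == 1)[0])
        return proba[:, active_col]

    def predict(self, X: DescriptorMatrix) -> np.ndarray:
        """Hard labels via the p >= 0.5 rule (1 = active)."""
        return (self.predict_proba(X) >= PROBABILITY_CUTOFF).astype(int)


def train_model(config: ModelConfig, X: DescriptorMatrix, y) -> TrainedModel:
    y = as_binary_labels(y)
    if np.unique(y).size < 2:
        raise ValidationError("training labels contain a single class")
    if len(y) != X.shape[0]:
        raise ValidationError("label vector length does not match descriptor rows")
    est = config.build()
    est.fit(X.values, y)
    return TrainedModel(config=config, estimator=est, descriptor_names=X.descriptor_names)


def _data_hash(X: DescriptorMatrix, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X.values).tobytes())
    h.update(",".join(X.descriptor_names).encode())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


@dataclass
class EnsembleBundle:
    """Four trained models over a common descriptor set and label vector."""

    models: dict[str, TrainedModel]
    descriptor_names: list[str]
    data_hash: str
    seeds: dict[str, int]

    def predict_proba_frame(self, X: DescriptorMatrix) -> pd.DataFrame:
        """Per-model active probabilities plus the unanimity consensus flag."""
        frame = pd.DataFrame(index=X.frame.index)
        for algo in ALGORITHMS:
            frame[f"p_{algo}"] = self.models[algo].predict_proba(X)
        probs = frame[[f"p_{a}" for a in ALGORITHMS]]
        frame["p_mean"] = probs.mean(axis=1)
        frame["consensus_active"] = (probs >= PROBABILITY_CUTOFF).all(axis=1)
        return frame

    def consensus_predict(self, X: DescriptorMatrix) -> np.ndarray:
        """1 where all four models call active, else 0."""
        return self.predict_proba_frame(X)["consensus_active"].to_numpy().astype(int)

    def save(self, directory) -> None:
        import joblib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "algorithms": list(ALGORITHMS),
            "descriptor_names": self.descriptor_names,
            "data_hash": self.data_hash,
            "seeds": self.seeds,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for algo, model in self.models.items():
            joblib.dump(model, directory / f"{algo}.joblib")

    @classmethod
    def load(cls, directory) -> "EnsembleBundle":
        import joblib

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        models = {
            algo: joblib.load(directory / f"{algo}.joblib")
            for algo in manifest["algorithms"]
        }
        return cls(
            models=models,
            descriptor_names=manifest["descriptor_names"],
            data_hash=manifest["data_hash"],
            seeds=manifest["seeds"],
        )


def default_configs(seed: int = 0) -> list[ModelConfig]:
    """One default config per algorithm, seeds offset deterministically."""
    return [
        ModelConfig(algorithm=a, seed=seed + i) for i, a in enumerate(ALGORITHMS)
    ]


def train_ensemble(X: DescriptorMatrix, y, configs: list[ModelConfig] | None = None) -> EnsembleBundle:
    """Train all four classifiers on the same descriptors and labels."""
    y = as_binary_labels(y)
    if configs is None:
        configs = default_configs()
    algos = [c.algorithm for c in configs]
    if sorted(algos) != sorted(ALGORITHMS):
        raise ValidationError(
            f"configs must name each of {ALGORITHMS} exactly once; got {algos}"
        )
    models = {c.algorithm: train_model(c, X, y) for c in configs}
    return EnsembleBundle(
        models=models,
        descriptor_names=X.descriptor_names,
        data_hash=_data_hash(X, y),
        seeds={c.algorithm: c.seed for c in configs},
    )
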