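"""Model-reliability checks: PCA applicability domain and y-randomization.

The applicability domain (AD) is defined in principal-component score
space: descriptors are standardized with training mean/SD, projected onto
the leading components, and a query compound is *inside* the domain when
every component score lies within the [min, max] range of the training
scores (optionally expanded by a fractional margin). An axis-aligned box is
deterministic and margin-controllable; a convex-hull criterion on the first
two components is available as an option.

Y-randomization retrains the model on label-scrambled training draws and
compares the resulting accuracy/AUC distribution with the genuine model: a
real structure-activity relationship must beat every scrambled run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay
from sklearn.decomposition import PCA

from .containers import DescriptorMatrix, ValidationError
from .evaluation import roc_auc
from .models import ModelConfig, as_binary_labels, train_model, PROBABILITY_CUTOFF


@dataclass
class ADModel:
    """PCA-box applicability domain fitted on training descriptors."""

    descriptor_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    z_center: np.ndarray          # residual center of the standardized data
    loadings: np.ndarray          # (n_components, n_descriptors), orthonormal rows
    explained_variance: np.ndarray
    bounds: np.ndarray            # (n_components, 2): training score min/max
    margin: float = 0.0
    dropped_zero_variance: list[str] = field(default_factory=list)
    hull_points: np.ndarray | None = None  # training PC1/PC2 scores (convex-hull option)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, X: DescriptorMatrix) -> np.ndarray:
        missing = [n for n in self.descriptor_names if n not in X.frame.columns]
        if missing:
            raise ValidationError(f"query is missing AD descriptors: {missing}")
        V = X.frame[self.descriptor_names].to_numpy(dtype=float)
        Z = (V - self.means) / self.sds - self.z_center
        return Z @ self.loadings.T

    def expanded_bounds(self, margin: float | None = None) -> np.ndarray:
        m = self.margin if margin is None else margin
        span = self.bounds[:, 1] - self.bounds[:, 0]
        lo = self.bounds[:, 0] - m * span
        hi = self.bounds[:, 1] + m * span
        return np.column_stack([lo, hi])

    def to_json(self, path) -> None:
        payload = {
            "descriptor_names": self.descriptor_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "z_center": self.z_center.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "bounds": self.bounds.tolist(),
            "margin": self.margin,
            "dropped_zero_variance": self.dropped_zero_variance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ADModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            descriptor_names=d["descriptor_names"],
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            z_center=np.array(d["z_center"]),
            loadings=np.array(d["loadings"]),
            explained_variance=np.array(d["explained_variance"]),
            bounds=np.array(d["bounds"]),
            margin=d["margin"],
            dropped_zero_variance=d["dropped_zero_variance"],
        )


def fit_ad(X_train: DescriptorMatrix, n_components: int = 2, margin: float = 0.0) -> ADModel:
    """Fit the PCA applicability domain on training descriptors.

    Zero-variance descriptors are dropped with a warning entry; bounds are
    the per-component min/max of the training scores, expanded by
    ``margin * range`` on each side at query time.
    """
    if X_train.shape[0] < 3:
        raise ValidationError("fit_ad needs at least 3 training compounds")
    frame = X_train.frame
    sd = frame.std(axis=0, ddof=0)
    dropped = [str(c) for c in frame.columns[sd == 0.0]]
    names = [str(c) for c in frame.columns if str(c) not in dropped]
    if not names:
        raise ValidationError("all descriptors have zero variance")
    rank = min(X_train.shape[0] - 1, len(names))
    if n_components > rank:
        raise ValidationError(
            f"n_components={n_components} exceeds data rank {rank}"
        )
    V = frame[names].to_numpy(dtype=float)
    means = V.mean(axis=0)
    sds = V.std(axis=0, ddof=0)
    Z = (V - means) / sds
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(Z)
    # recompute scores through the query path so training bounds contain
    # their defining points bit-for-bit
    scores = (Z - pca.mean_) @ pca.components_.T
    bounds = np.column_stack([scores.min(axis=0), scores.max(axis=0)])
    return ADModel(
        descriptor_names=names,
        means=means,
        sds=sds,
        z_center=pca.mean_,
        loadings=pca.components_,
        explained_variance=pca.explained_variance_,
        bounds=bounds,
        margin=margin,
        dropped_zero_variance=dropped,
        hull_points=scores[:, :2] if n_components >= 2 else None,
    )


def in_ad(
    ad: ADModel,
    X_query: DescriptorMatrix,
    margin: float | None = None,
    criterion: str = "box",
) -> tuple[np.ndarray, np.ndarray]:
    """Flag query compounds inside/outside the applicability domain.

    Returns (inside flags, per-component scores). ``criterion='box'``
    requires every component score within its expanded training bounds;
    ``criterion='hull'`` additionally available for the first two
    components.
    """
    scores = ad.transform(X_query)
    if criterion == "box":
        b = ad.expanded_bounds(margin)
        inside = ((scores >= b[:, 0]) & (scores <= b[:, 1])).all(axis=1)
    elif criterion == "hull":
        if ad.hull_points is None:
            raise ValidationError("convex-hull criterion needs >= 2 components")
        hull = ConvexHull(ad.hull_points)
        tri = Delaunay(ad.hull_points[hull.vertices])
        inside = tri.find_simplex(scores[:, :2]) >= 0
    else:
        raise ValidationError(f"unknown AD criterion: {criterion}")
    return inside, scores


@dataclass
class YRandomizationResult:
    """Accuracy/AUC distribution over label-scrambled retraining runs."""

    n_runs: int
    accuracies: np.ndarray
    aucs: np.ndarray
    reference_accuracy: float
    reference_auc: float
    n_redraws: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def max_accuracy(self) -> float:
        return float(self.accuracies.max())

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"run": np.arange(1, self.n_runs + 1),
             "accuracy": self.accuracies, "auc": self.aucs}
        )


def _run_seed(master_seed: int, counter: int) -> int:
    """Per-run seed: documented counter scheme via SeedSequence(master, counter)."""
    return int(np.random.SeedSequence([master_seed, counter]).generate_state(1)[0] % (2**31 - 1))


def y_randomization(
    X: DescriptorMatrix,
    y,
    config: ModelConfig,
    X_test: DescriptorMatrix,
    y_test,
    n_runs: int = 500,
    resample_fraction: float = 0.5,
    seed: int = 0,
    identity_permutation: bool = False,
) -> YRandomizationResult:
    """Label-scrambling robustness test.

    Each run draws ``ceil(resample_fraction * n)`` training compounds
    without replacement, permutes their labels, retrains the model with
    identical hyperparameters, and records accuracy and AUC on the
    untouched test set with its true labels. The reference model is
    trained once on the unscrambled training data under the same protocol.
    Draws that end up single-class are re-drawn (counted in
    ``n_redraws``). ``identity_permutation`` disables the label scramble
    (degenerate check: with fraction 1 it must reproduce the reference).
    """
    y = as_binary_labels(y)
    y_test = as_binary_labels(y_test)
    if np.unique(y).size < 2:
        raise ValidationError("y_randomization requires both classes in training labels")
    if not (0.0 < resample_fraction <= 1.0):
        raise ValidationError("resample_fraction must be in (0, 1]")
    n = X.shape[0]
    k = math.ceil(resample_fraction * n)

    ref_model = train_model(config, X, y)
    ref_scores = ref_model.predict_proba(X_test)
    ref_acc = float(((ref_scores >= PROBABILITY_CUTOFF).astype(int) == y_test).mean())
    ref_auc, _ = roc_auc(y_test, ref_scores)

    ids = np.asarray(X.compound_ids)
    accs = np.empty(n_runs)
    aucs = np.empty(n_runs)
    n_redraws = 0
    for run in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, run]))
        while True:
            # sorted draw keeps row order canonical, so fraction=1 with the
            # identity permutation reproduces the reference fit exactly
            idx = np.sort(rng.choice(n, size=k, replace=False))
            y_sub = y[idx]
            if np.unique(y_sub).size == 2:
                break
            n_redraws += 1
        y_perm = y_sub if identity_permutation else y_sub[rng.permutation(k)]
        X_sub = X.subset_rows(ids[idx].tolist())
        model = train_model(
            ModelConfig(config.algorithm, dict(config.hyperparameters), seed=config.seed),
            X_sub,
            y_perm,
        )
        scores = model.predict_proba(X_test)
        accs[run] = ((scores >= PROBABILITY_CUTOFF).astype(int) == y_test).mean()
        aucs[run], _ = roc_auc(y_test, scores)
    return YRandomizationResult(
        n_runs=n_runs,
        accuracies=accs,
        aucs=aucs,
        reference_accuracy=ref_acc,
        reference_auc=ref_auc,
        n_redraws=n_redraws,
    )
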