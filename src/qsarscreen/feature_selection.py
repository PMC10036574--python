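"""Two-tier descriptor reduction: correlation pruning then Boruta.

Tier 1 removes redundancy: from every descriptor pair with absolute Pearson
correlation above a threshold (default 0.85), one member — chosen by a
seeded RNG — is dropped. Tier 2 is the Boruta all-relevant selection
algorithm: each iteration appends a shuffled ("shadow") copy of every
candidate descriptor, fits a random forest, and scores a *hit* for every
real descriptor whose importance exceeds the maximum shadow importance.
After ``n_iterations`` rounds, hit counts are compared to Binomial(n, 1/2)
with a two-sided test, Bonferroni-corrected across candidates: descriptors
significantly above expectation are confirmed, significantly below are
rejected, the remainder stay tentative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .containers import DescriptorMatrix, ValidationError


@dataclass
class SelectionResult:
    """Outcome of the two-tier reduction.

    ``kept`` holds the final descriptor names (Boruta-confirmed, plus
    tentatives when requested); the three Boruta sets partition the
    post-correlation candidate set.
    """

    kept: list[str]
    dropped_by_correlation: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_zero_variance: list[str] = field(default_factory=list)
    boruta_confirmed: list[str] = field(default_factory=list)
    boruta_tentative: list[str] = field(default_factory=list)
    boruta_rejected: list[str] = field(default_factory=list)
    hit_counts: dict[str, int] = field(default_factory=dict)
    importance_history: list[dict[str, float]] = field(default_factory=list)
    n_iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "dropped_by_correlation": [
                {"kept": k, "dropped": d, "r": r} for k, d, r in self.dropped_by_correlation
            ],
            "dropped_zero_variance": self.dropped_zero_variance,
            "boruta_confirmed": self.boruta_confirmed,
            "boruta_tentative": self.boruta_tentative,
            "boruta_rejected": self.boruta_rejected,
            "hit_counts": self.hit_counts,
            "n_iterations": self.n_iterations,
            "importance_history": self.importance_history,
        }


def correlation_filter(
    X: DescriptorMatrix, threshold: float = 0.85, seed: int = 0
) -> tuple[DescriptorMatrix, SelectionResult]:
    """Drop one randomly chosen member of each over-correlated pair.

    Pairs are visited over the upper triangle in descriptor-name column
    order and resolved greedily against the correlation matrix of the
    input; redundancy is sign-agnostic (|r| > threshold). Constant
    (zero-variance) descriptors, whose correlation is undefined, are
    dropped first and logged.
    """
    if X.shape[0] < 2:
        raise ValidationError("correlation filter needs at least 2 compounds")
    if not (0.0 < threshold <= 1.0):
        raise ValidationError("threshold must be in (0, 1]")
    rng = np.random.default_rng(seed)
    frame = X.frame

    sd = frame.std(axis=0, ddof=1)
    zero_var = [str(c) for c in frame.columns[sd == 0.0]]
    names = [str(c) for c in frame.columns if str(c) not in zero_var]
    corr = frame[names].corr().to_numpy()

    alive = {n: True for n in names}
    drops: list[tuple[str, str, float]] = []
    for i in range(len(names)):
        if not alive[names[i]]:
            continue
        for j in range(i + 1, len(names)):
            if not alive[names[i]]:
                break
            if not alive[names[j]]:
                continue
            r = corr[i, j]
            if abs(r) > threshold:
                victim_idx = int(rng.integers(0, 2))
                victim, keeper = (names[i], names[j]) if victim_idx == 0 else (names[j], names[i])
                alive[victim] = False
                drops.append((keeper, victim, float(r)))

    kept = [n for n in names if alive[n]]
    reduced = X.select(
        kept, note=f"correlation_filter(threshold={threshold}, seed={seed})"
    )
    result = SelectionResult(
        kept=kept, dropped_by_correlation=drops, dropped_zero_variance=zero_var
    )
    return reduced, result


def _shadow_iteration(
    values: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    estimator_params: dict,
    importance: str,
    seed: int,
) -> tuple[np.ndarray, float]:
    """One Boruta round: returns real-feature importances and max shadow importance."""
    n, d = values.shape
    shadows = values.copy()
    for j in range(d):
        shadows[:, j] = shadows[rng.permutation(n), j]
    Xa = np.hstack([values, shadows])
    rf = RandomForestClassifier(random_state=seed, **estimator_params)
    rf.fit(Xa, y)
    if importance == "permutation":
        imp = permutation_importance(
            rf, Xa, y, n_repeats=5, random_state=seed
        ).importances_mean
    else:
        imp = rf.feature_importances_
    return imp[:d], float(imp[d:].max())


def boruta_select(
    X: DescriptorMatrix,
    y: np.ndarray,
    n_iterations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    estimator_params: dict | None = None,
    importance: str = "impurity",
    include_tentative: bool = False,
    rough_fix: bool = False,
) -> SelectionResult:
    """Boruta all-relevant descriptor selection against shadow features.

    Parameters
    ----------
    n_iterations
        Number of shadow rounds (>= 20 for the binomial test to resolve).
    alpha
        Two-sided significance level, Bonferroni-corrected across the
        candidate descriptors.
    estimator_params
        Random-forest keyword overrides; default 50 trees, depth 5 —
        depth-limited forests give stable impurity importances at modest
        cost.
    importance
        ``"impurity"`` (default) or ``"permutation"``.
    include_tentative, rough_fix
        Tentatives are excluded from ``kept`` by default; ``rough_fix``
        resolves each tentative by comparing its median importance across
        iterations to the median of the per-iteration max shadow
        importances.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("boruta_select requires both classes present")
    if min((y == c).sum() for c in classes) < 2:
        raise ValidationError("need at least 2 compounds per class")
    if n_iterations < 20:
        raise ValidationError("n_iterations must be >= 20")

    params = {"n_estimators": 50, "max_depth": 5, "n_jobs": 1}
    if estimator_params:
        params.update(estimator_params)

    names = X.descriptor_names
    values = X.values
    d = len(names)
    rng = np.random.default_rng(seed)
    hits = np.zeros(d, dtype=int)
    history: list[dict[str, float]] = []
    shadow_maxima: list[float] = []
    imp_records = np.zeros((n_iterations, d))
    for it in range(n_iterations):
        iter_seed = int(rng.integers(0, 2**31 - 1))
        imp, shadow_max = _shadow_iteration(values, y, rng, params, importance, iter_seed)
        hits += imp > shadow_max
        imp_records[it] = imp
        shadow_maxima.append(shadow_max)
        history.append({**dict(zip(names, imp.tolist())), "_max_shadow": shadow_max})

    # two-sided binomial test per candidate, Bonferroni across the d candidates
    level = alpha / d
    confirmed, rejected, tentative = [], [], []
    for j, name in enumerate(names):
        p = stats.binomtest(int(hits[j]), n_iterations, 0.5).pvalue
        if p < level and hits[j] > n_iterations / 2:
            confirmed.append(name)
        elif p < level and hits[j] < n_iterations / 2:
            rejected.append(name)
        else:
            tentative.append(name)

    if rough_fix and tentative:
        shadow_median = float(np.median(shadow_maxima))
        still = []
        for name in tentative:
            j = names.index(name)
            if float(np.median(imp_records[:, j])) > shadow_median:
                confirmed.append(name)
            else:
                rejected.append(name)
        tentative = still

    kept = [n for n in names if n in set(confirmed)]
    if include_tentative:
        kept = [n for n in names if n in set(confirmed) | set(tentative)]
    return SelectionResult(
        kept=kept,
        boruta_confirmed=confirmed,
        boruta_tentative=tentative,
        boruta_rejected=rejected,
        hit_counts=dict(zip(names, hits.tolist())),
        importance_history=history,
        n_iterations=n_iterations,
    )


def select_descriptors(
    X: DescriptorMatrix,
    y: np.ndarray,
    corr_threshold: float = 0.85,
    n_iterations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    **boruta_kwargs,
) -> tuple[DescriptorMatrix, SelectionResult]:
    """Full two-tier reduction: correlation pruning, then Boruta."""
    reduced, corr_result = correlation_filter(X, threshold=corr_threshold, seed=seed)
    boruta = boruta_select(
        reduced, y, n_iterations=n_iterations, alpha=alpha, seed=seed, **boruta_kwargs
    )
    boruta.dropped_by_correlation = corr_result.dropped_by_correlation
    boruta.dropped_zero_variance = corr_result.dropped_zero_variance
    final = reduced.select(
        boruta.kept, note=f"boruta_select(n_iterations={n_iterations}, alpha={alpha}, seed={seed})"
    )
    return final, boruta
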