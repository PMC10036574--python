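"""Consensus virtual screening through a three-filter funnel.

Filter 1 — consensus: all four classifiers call the compound active
(probability >= 0.5 each). Filter 2 — probability: the mean of the four
probabilities reaches a configurable threshold (default 0.5; a stricter
0.6 preset is available via ``probability_rule='per_model_min'`` or a
higher threshold). Filter 3 — applicability domain: the compound falls
inside the training chemical space defined by the PCA box.

Passing compounds are ranked by mean ensemble probability (descending,
ties broken by compound id) and annotated with their maximum Tanimoto
similarity to the training actives; a hit at or below the novelty
threshold (default 0.5) is flagged as structurally novel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DescriptorMatrix, FingerprintSet, ValidationError
from .fingerprints import pairwise_similarity
from .models import ALGORITHMS, EnsembleBundle, PROBABILITY_CUTOFF
from .validation import ADModel, in_ad


@dataclass
class ScreeningReport:
    """Per-library-compound screening annotations and the pass/rank table."""

    table: pd.DataFrame
    probability_threshold: float
    novelty_threshold: float
    warnings: list[str]

    @property
    def hits(self) -> pd.DataFrame:
        return self.table[self.table["final_pass"]].sort_values("rank")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)


def novelty_annotation(
    fps_hits: FingerprintSet,
    fps_train_active: FingerprintSet,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Max Tanimoto similarity of each hit to any training active.

    A hit is *novel* when its closest training active is no more similar
    than the threshold.
    """
    sim = pairwise_similarity(fps_hits, fps_train_active)
    max_tc = sim.max(axis=1)
    return pd.DataFrame(
        {
            "compound_id": fps_hits.compound_ids,
            "max_tanimoto_to_active": max_tc,
            "novel": max_tc <= threshold,
        }
    )


def screen(
    bundle: EnsembleBundle,
    ad: ADModel,
    X_lib: DescriptorMatrix,
    fps_lib: FingerprintSet | None,
    fps_train_active: FingerprintSet | None,
    probability_threshold: float = 0.5,
    novelty_threshold: float = 0.5,
    probability_rule: str = "mean",
) -> ScreeningReport:
    """Run the three-filter funnel over a screening library.

    ``probability_rule='mean'`` applies the threshold to the mean of the
    four probabilities; ``'per_model_min'`` requires every individual
    probability to reach it.
    """
    if X_lib.shape[0] == 0:
        raise ValidationError("screening library is empty")
    for thr, name in ((probability_threshold, "probability_threshold"),
                      (novelty_threshold, "novelty_threshold")):
        if not (0.0 <= thr <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1]")

    warnings_log: list[str] = []
    probs = bundle.predict_proba_frame(X_lib)
    inside, _scores = in_ad(ad, X_lib)

    table = pd.DataFrame({"compound_id": X_lib.compound_ids})
    for algo in ALGORITHMS:
        table[f"p_{algo}"] = probs[f"p_{algo}"].to_numpy()
    table["p_mean"] = probs["p_mean"].to_numpy()
    table["consensus_active"] = probs["consensus_active"].to_numpy()
    if probability_rule == "mean":
        table["probability_pass"] = table["p_mean"] >= probability_threshold
    elif probability_rule == "per_model_min":
        table["probability_pass"] = (
            table[[f"p_{a}" for a in ALGORITHMS]] >= probability_threshold
        ).all(axis=1)
    else:
        raise ValidationError(f"unknown probability_rule: {probability_rule}")
    table["in_ad"] = inside
    table["final_pass"] = (
        table["consensus_active"] & table["probability_pass"] & table["in_ad"]
    )

    # novelty annotation against training actives
    table["max_tanimoto_to_active"] = np.nan
    table["novel"] = pd.array([None] * len(table), dtype="boolean")
    if fps_lib is not None and fps_train_active is not None and len(fps_train_active):
        lib_ids = set(fps_lib.compound_ids)
        have = [cid for cid in table["compound_id"] if cid in lib_ids]
        missing = [cid for cid, ok in zip(table["compound_id"], table["final_pass"])
                   if ok and cid not in lib_ids]
        for cid in missing:
            warnings_log.append(f"no fingerprint for passing compound {cid}; novelty unavailable")
        if have:
            ann = novelty_annotation(
                fps_lib.subset(have), fps_train_active, threshold=novelty_threshold
            ).set_index("compound_id")
            table = table.set_index("compound_id")
            table.loc[ann.index, "max_tanimoto_to_active"] = ann["max_tanimoto_to_active"]
            table.loc[ann.index, "novel"] = ann["novel"].to_numpy()
            table = table.reset_index()
    elif fps_lib is None:
        warnings_log.append("library fingerprints unavailable; novelty not annotated")

    # rank passing compounds by mean probability, ties by id
    table["rank"] = pd.array([None] * len(table), dtype="Int64")
    passing = table[table["final_pass"]].sort_values(
        ["p_mean", "compound_id"], ascending=[False, True]
    )
    table.loc[passing.index, "rank"] = np.arange(1, len(passing) + 1)
    return ScreeningReport(
        table=table,
        probability_threshold=probability_threshold,
        novelty_threshold=novelty_threshold,
        warnings=warnings_log,
    )
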