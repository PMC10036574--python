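from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qsarscreen import (
    ConfusionCounts,
    ValidationError,
    confusion_counts,
    cumulative_gain,
    metrics,
    probability_by_outcome,
    roc_auc,
)


def brute_force_auc(y, s):
    """All-pairs Mann-Whitney evaluation: wins + half-ties over pair count."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = Fraction(0)
    for p in pos:
        for q in neg:
            if p > q:
                total += 1
            elif p == q:
                total += Fraction(1, 2)
    return total / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_perfect_prediction(self):
        y = [1] * 10 + [0] * 10
        c = confusion_counts(y, y)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)

    def test_degenerate_all_active_predictor(self):
        y_true = [1] * 5 + [0] * 15
        c = confusion_counts(y_true, [1] * 20)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 15, 0, 0)

    def test_counts_partition_n(self, rng):
        y = rng.integers(0, 2, 100)
        p = rng.integers(0, 2, 100)
        assert confusion_counts(y, p).n == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts([1, 0], [1])


class TestMetrics:
    def test_hand_arithmetic_example(self):
        rep = metrics(ConfusionCounts(tp=8, fp=2, tn=8, fn=2))
        assert rep.precision == pytest.approx(0.8)
        assert rep.recall == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(0.8)

    def test_perfect_classifier_scores_one(self):
        rep = metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert (rep.precision, rep.recall, rep.accuracy, rep.f1) == (1, 1, 1, 1)

    def test_zero_denominators_reported_undefined_not_zero(self):
        rep = metrics(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
        assert rep.precision is None and "precision" in rep.undefined
        assert rep.recall == 0.0
        assert rep.f1 is None

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_exhaustive_agreement_with_rational_arithmetic_small_n(self):
        """Every confusion matrix with n <= 12 matches exact hand formulas."""
        for tp, fp, tn, fn in product(range(13), repeat=4):
            n = tp + fp + tn + fn
            if n == 0 or n > 12:
                continue
            rep = metrics(ConfusionCounts(tp, fp, tn, fn))
            assert rep.accuracy == (tp + tn) / n
            assert abs(rep.accuracy - Fraction(tp + tn, n)) < 1e-15
            if tp + fp:
                assert rep.precision == tp / (tp + fp)
            else:
                assert rep.precision is None


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 1], [0.2, 0.4])

    def test_rank_formulation_matches_all_pairs_brute_force(self, rng):
        y = rng.integers(0, 2, 200)
        y[:5] = 1
        y[5:10] = 0  # guarantee both classes
        s = np.round(rng.random(200), 2)  # coarse scores force ties
        auc, _ = roc_auc(y, s)
        assert abs(auc - float(brute_force_auc(y.tolist(), s.tolist()))) < 1e-12

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 50)
        if y.sum() in (0, 50):
            return
        s = rng.random(50)
        a1, _ = roc_auc(y, s)
        a2, _ = roc_auc(y, 1 - s)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)


class TestCumulativeGain:
    def test_perfect_ranking_captures_all_actives_at_prevalence_depth(self):
        y = [1] * 20 + [0] * 80
        s = np.linspace(1, 0, 100)
        gain = cumulative_gain(y, s, [0.2])
        assert gain["gain"].iloc[0] == 1.0

    def test_gain_is_monotone_and_reaches_one(self, rng):
        y = rng.integers(0, 2, 200)
        y[0], y[1] = 1, 0
        s = rng.random(200)
        gain = cumulative_gain(y, s, np.linspace(0.05, 1.0, 20))
        g = gain["gain"].to_numpy()
        assert (np.diff(g) >= 0).all()
        assert g[-1] == 1.0

    def test_random_scores_track_the_diagonal(self, rng):
        y = np.array([1] * 100 + [0] * 100)
        depths = [0.25, 0.5, 0.75]
        gains = np.mean(
            [cumulative_gain(y, rng.random(200), depths)["gain"].to_numpy()
             for _ in range(30)],
            axis=0,
        )
        assert np.allclose(gains, depths, atol=0.05)

    def test_empty_depths_rejected(self):
        with pytest.raises(ValidationError):
            cumulative_gain([0, 1], [0.1, 0.9], [])


class TestProbabilityByOutcome:
    def test_group_membership_follows_hard_label_rule(self, rng):
        y = rng.integers(0, 2, 300)
        p = rng.random(300)
        groups = probability_by_outcome(y, p)
        assert all(v >= 0.5 for v in groups["TP"]["values"])
        assert all(v < 0.5 for v in groups["TN"]["values"])
        assert groups["TP"]["mean"] is None or groups["TP"]["mean"] >= 0.5
        total = sum(groups[g]["n"] for g in ("TP", "TN", "FP", "FN"))
        assert total == 300

    def test_separated_model_scores_tp_above_fp(self, ensemble, dataset):
        p = ensemble.models["random_forest"].predict_proba(dataset.descriptors)
        groups = probability_by_outcome(dataset.labels, p)
        if groups["FP"]["n"]:
            assert groups["TP"]["mean"] > groups["FP"]["mean"]

    def test_empty_groups_reported_empty(self):
        groups = probability_by_outcome([1, 1, 0], [0.9, 0.8, 0.1])
        assert groups["FP"]["n"] == 0 and groups["FP"]["mean"] is None
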