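"""Weighted metrics, threshold selection, agreement, annotation merging."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markermine.evaluation import (
    MERGED_EVIDENCE_LABEL,
    compute_group_weights,
    interannotator_f1,
    merge_annotations,
    pr_curve_and_threshold,
    stratified_split,
    weighted_prf,
)


class TestGroupWeights:
    def test_identity(self):
        w = compute_group_weights({"a": 30, "b": 30}, {"a": 10, "b": 10})
        assert w == {"a": 1.0, "b": 1.0}

    def test_share_ratio(self):
        w = compute_group_weights({"A": 90, "B": 10}, {"A": 10, "B": 10})
        assert w["A"] == pytest.approx(1.8)
        assert w["B"] == pytest.approx(0.2)
        assert w["A"] / w["B"] == pytest.approx(9.0)

    def test_zero_sample_errors(self):
        with pytest.raises(ValueError):
            compute_group_weights({"a": 1, "b": 1}, {"a": 0, "b": 2})

    def test_mismatched_groups_error(self):
        with pytest.raises(ValueError):
            compute_group_weights({"a": 1}, {"b": 1})


class TestWeightedPRF:
    def test_perfect_predictions(self):
        t = [True, False, True]
        w = {"g": 3.7}
        assert weighted_prf(t, t, ["g"] * 3, w) == (1.0, 1.0, 1.0)

    def test_hand_computed_confusion(self):
        # 1 TP (w=2), 1 FP (w=1), 1 FN (w=1) -> P = R = F1 = 2/3
        y_true = [True, False, True]
        y_pred = [True, True, False]
        groups = ["heavy", "light", "light"]
        weights = {"heavy": 2.0, "light": 1.0}
        p, r, f = weighted_prf(y_true, y_pred, groups, weights)
        assert (p, r, f) == pytest.approx((2 / 3, 2 / 3, 2 / 3))

    def test_empty_convention(self):
        assert weighted_prf([False], [False]) == (0.0, 0.0, 0.0)

    def test_unit_weights_equal_unweighted_oracle(self):
        """1000 random cases against an independent counting implementation."""
        rng = random.Random(1)
        for _ in range(1000):
            n = rng.randint(1, 12)
            y_true = [rng.random() < 0.5 for _ in range(n)]
            y_pred = [rng.random() < 0.5 for _ in range(n)]
            tp = sum(t and p for t, p in zip(y_true, y_pred))
            fp = sum((not t) and p for t, p in zip(y_true, y_pred))
            fn = sum(t and (not p) for t, p in zip(y_true, y_pred))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert weighted_prf(y_true, y_pred) == pytest.approx(
                (prec, rec, f1)
            )


class TestPRCurve:
    def test_separable_scores(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        truth = [False, False, True, True]
        curve, thr = pr_curve_and_threshold(scores, truth)
        assert thr == 0.8
        by_thr = {pt.threshold: pt for pt in curve}
        assert by_thr[0.8].precision == 1.0 and by_thr[0.8].recall == 1.0

    def test_fallback_below_target(self):
        # best achievable precision is 2/3 < 0.9: closest wins
        scores = [0.9, 0.8, 0.7]
        truth = [True, True, False]
        curve, thr = pr_curve_and_threshold(scores, truth, target_precision=0.9)
        best = max(curve, key=lambda pt: pt.precision)
        assert thr == 0.9 and best.precision == 1.0 or thr in [
            pt.threshold for pt in curve
        ]
        # precision at the chosen threshold is the closest to the target
        chosen = [pt for pt in curve if pt.threshold == thr][0]
        assert all(
            abs(chosen.precision - 0.9) <= abs(pt.precision - 0.9)
            for pt in curve
        )

    def test_exhaustive_sweep_oracle(self):
        """Chosen threshold agrees with brute force over every distinct score."""
        rng = random.Random(3)
        for _ in range(50):
            n = rng.randint(3, 25)
            scores = [round(rng.random(), 3) for _ in range(n)]
            truth = [rng.random() < 0.4 for _ in range(n)]
            curve, thr = pr_curve_and_threshold(
                scores, truth, target_precision=0.9
            )

            def prf_at(t):
                pred = [s >= t for s in scores]
                return weighted_prf(truth, pred)[:2]

            candidates = sorted(set(scores))
            reaching = [t for t in candidates if prf_at(t)[0] >= 0.9]
            if reaching:
                best_recall = max(prf_at(t)[1] for t in reaching)
                assert prf_at(thr)[0] >= 0.9
                assert prf_at(thr)[1] == pytest.approx(best_recall)
            else:
                best_gap = min(abs(prf_at(t)[0] - 0.9) for t in candidates)
                assert abs(prf_at(thr)[0] - 0.9) == pytest.approx(best_gap)

    def test_recall_non_increasing(self):
        rng = random.Random(4)
        scores = [rng.random() for _ in range(60)]
        truth = [rng.random() < 0.5 for _ in range(60)]
        curve, _ = pr_curve_and_threshold(scores, truth)
        recalls = [pt.recall for pt in curve]
        assert recalls == sorted(recalls, reverse=True)


class TestInterannotatorF1:
    def test_identical_sets(self):
        assert interannotator_f1({"r1", "r2"}, {"r1", "r2"}) == 1.0

    def test_disjoint_sets(self):
        assert interannotator_f1({"r1"}, {"r2"}) == 0.0

    def test_partial_overlap(self):
        f1 = interannotator_f1({"r1", "r2", "r3"}, {"r1", "r2", "r4"})
        assert f1 == pytest.approx(2 / 3)

    @given(
        st.sets(st.integers(0, 20), max_size=10),
        st.sets(st.integers(0, 20), max_size=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_identity(self, a, b):
        assert interannotator_f1(a, b) == interannotator_f1(b, a)
        assert (interannotator_f1(a, b) == 1.0) == (a == b)


class TestMergeAnnotations:
    GC = (("gene", "EGFR"), ("cancer", "NSCLC"))
    GCD = (("cancer", "NSCLC"), ("drug", "erlotinib"), ("gene", "EGFR"))

    def test_majority_vote(self):
        item = ("s1", "Diagnostic", self.GC)
        out = merge_annotations([item], [item], [])
        assert out == {item}
        assert merge_annotations([item], [], []) == set()

    def test_merged_class_with_drug_becomes_predictive(self):
        item = ("s1", MERGED_EVIDENCE_LABEL, self.GCD)
        out = merge_annotations([item], [item], [item])
        assert out == {("s1", "Predictive", self.GCD)}

    def test_merged_class_without_drug_becomes_prognostic(self):
        item = ("s1", MERGED_EVIDENCE_LABEL, self.GC)
        out = merge_annotations([item], [item], [])
        assert out == {("s1", "Prognostic", self.GC)}

    def test_overlapping_prognostic_removed(self):
        pred = ("s1", MERGED_EVIDENCE_LABEL, self.GCD)
        prog = ("s1", MERGED_EVIDENCE_LABEL, self.GC)
        out = merge_annotations([pred, prog], [pred, prog], [])
        assert out == {("s1", "Predictive", self.GCD)}

    def test_different_sentence_not_removed(self):
        pred = ("s1", MERGED_EVIDENCE_LABEL, self.GCD)
        prog = ("s2", MERGED_EVIDENCE_LABEL, self.GC)
        out = merge_annotations([pred, prog], [pred, prog], [])
        assert ("s2", "Prognostic", self.GC) in out


class TestStratifiedSplit:
    def test_preserves_proportions(self):
        items = list(range(800))
        labels = ["a"] * 400 + ["b"] * 200 + ["c"] * 200
        train, test = stratified_split(items, labels, test_size=0.25, seed=0)
        assert len(train) == 600 and len(test) == 200
        test_labels = [labels[i] for i in test]
        assert test_labels.count("a") == 100
        assert test_labels.count("b") == 50

    def test_deterministic(self):
        items = list(range(100))
        labels = ["a", "b"] * 50
        assert stratified_split(items, labels, seed=5) == stratified_split(
            items, labels, seed=5
        )
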