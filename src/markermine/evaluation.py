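"""Group-weighted evaluation, threshold selection, and annotation merging.

Because annotation sentences are drawn equally from keyword groups rather
than randomly from the literature, test-set metrics are re-weighted: each
candidate contributes its group's population-to-sample ratio to the
confusion matrix, so precision/recall estimate performance on randomly
selected sentences.  Thresholds are then chosen on the precision-recall
curve to hit a target precision (0.9 by convention) with maximal recall.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "compute_group_weights",
    "weighted_prf",
    "pr_curve_and_threshold",
    "interannotator_f1",
    "merge_annotations",
    "stratified_split",
    "MERGED_EVIDENCE_LABEL",
]

#: Label used during annotation for the merged predictive/prognostic class.
MERGED_EVIDENCE_LABEL = "Predictive/Prognostic"


def compute_group_weights(
    population: Mapping[str, float], sample: Mapping[str, float]
) -> dict[str, float]:
    """weight_g = (population share of g) / (sample share of g).

    The absolute scale of the weights cancels in precision/recall; weights
    are reported on the share-ratio scale, where equal population and sample
    proportions give weight 1 for every group.
    """
    if set(population) != set(sample):
        raise ValueError("population and sample must cover the same groups")
    pop_total = sum(population.values())
    samp_total = sum(sample.values())
    weights = {}
    for g in population:
        if sample[g] <= 0:
            raise ValueError(f"group {g!r} has non-positive sample count")
        if population[g] <= 0:
            raise ValueError(f"group {g!r} has non-positive population count")
        weights[g] = (population[g] / pop_total) / (sample[g] / samp_total)
    return weights


def weighted_prf(
    y_true: Sequence[bool],
    y_pred: Sequence[bool],
    groups: Sequence[str] | None = None,
    weights: Mapping[str, float] | None = None,
) -> tuple[float, float, float]:
    """Weighted precision, recall and F1 (0/0 -> 0 by convention)."""
    n = len(y_true)
    if len(y_pred) != n:
        raise ValueError("y_true and y_pred must align")
    w = np.ones(n)
    if weights is not None:
        if groups is None or len(groups) != n:
            raise ValueError("groups must align with candidates when weighting")
        w = np.array([weights[g] for g in groups], dtype=float)
    t = np.asarray(y_true, dtype=bool)
    p = np.asarray(y_pred, dtype=bool)
    tp = float(w[t & p].sum())
    fp = float(w[~t & p].sum())
    fn = float(w[t & ~p].sum())
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float
    recall: float


def pr_curve_and_threshold(
    scores: Sequence[float],
    y_true: Sequence[bool],
    groups: Sequence[str] | None = None,
    weights: Mapping[str, float] | None = None,
    target_precision: float = 0.9,
) -> tuple[list[PRPoint], float]:
    """Precision-recall curve over distinct scores and a target threshold.

    The chosen threshold has precision >= target with maximal recall; when
    no threshold reaches the target, the one with precision closest to the
    target is returned (ties favouring higher recall).
    """
    scores = np.asarray(scores, dtype=float)
    curve: list[PRPoint] = []
    for thr in sorted(set(scores.tolist())):
        pred = scores >= thr
        prec, rec, _ = weighted_prf(y_true, pred.tolist(), groups, weights)
        curve.append(PRPoint(float(thr), prec, rec))
    reaching = [pt for pt in curve if pt.precision >= target_precision]
    if reaching:
        # ties on recall resolve to the strictest threshold: any threshold in
        # a separating gap scores identically on the calibration data, and
        # the highest one keeps the most precision headroom on new data
        best = max(reaching, key=lambda pt: (pt.recall, pt.threshold))
    else:
        best = min(
            curve,
            key=lambda pt: (abs(pt.precision - target_precision), -pt.recall),
        )
    return curve, best.threshold


def interannotator_f1(
    annots_a: Iterable[Hashable], annots_b: Iterable[Hashable]
) -> float:
    """F1 agreement between two annotators' accepted relation sets.

    Treating one annotator as reference: F1 = 2·TP / (2·TP + FP + FN); the
    measure is symmetric in the two sets and equals 1 iff they are identical.
    """
    a, b = set(annots_a), set(annots_b)
    if not a and not b:
        return 1.0
    tp = len(a & b)
    denom = 2 * tp + len(a - b) + len(b - a)
    return 2 * tp / denom if denom else 0.0


def merge_annotations(
    annots_a: Iterable[tuple],
    annots_b: Iterable[tuple],
    annots_c: Iterable[tuple],
) -> set[tuple]:
    """Majority-vote merge of three annotators, with the predictive/prognostic split.

    Annotation items are ``(sentence_id, label, slots)`` tuples where
    ``slots`` is an ordered tuple of ``(entity_type, key)`` pairs.  A
    candidate is accepted when at least two annotators accepted it.
    Accepted items carrying the merged predictive/prognostic label are
    resolved by the drug slot: with a drug -> Predictive, without ->
    Prognostic.  Finally any Prognostic relation sharing its gene and cancer
    with a Predictive relation in the same sentence is removed.
    """
    votes = Counter()
    for annots in (annots_a, annots_b, annots_c):
        for item in set(annots):
            votes[item] += 1
    accepted = {item for item, n in votes.items() if n >= 2}

    resolved: set[tuple] = set()
    for sent_id, label, slots in accepted:
        if label == MERGED_EVIDENCE_LABEL:
            has_drug = any(etype == "drug" for etype, _ in slots)
            label = "Predictive" if has_drug else "Prognostic"
        resolved.add((sent_id, label, slots))

    def slot_key(slots: tuple, etype: str):
        for t, k in slots:
            if t == etype:
                return k
        return None

    predictive_gc = {
        (sent_id, slot_key(slots, "gene"), slot_key(slots, "cancer"))
        for sent_id, label, slots in resolved
        if label == "Predictive"
    }
    return {
        (sent_id, label, slots)
        for sent_id, label, slots in resolved
        if not (
            label == "Prognostic"
            and (sent_id, slot_key(slots, "gene"), slot_key(slots, "cancer"))
            in predictive_gc
        )
    }


def stratified_split(
    items: Sequence, labels: Sequence, test_size: float = 0.25, seed: int = 0
) -> tuple[list, list]:
    """Deterministic 75/25 (by default) split preserving label proportions."""
    idx = np.arange(len(items))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_size,
        random_state=seed,
        stratify=np.asarray(labels),
    )
    return (
        [items[i] for i in sorted(train_idx)],
        [items[i] for i in sorted(test_idx)],
    )
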