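"""Sentence triage for annotation and extraction.

A sentence enters the candidate pool when it mentions at least one gene, one
cancer type and one variant (a drug is not required — only the predictive
evidence type involves one).  Because clinically relevant assertions are rare
among such sentences, a keyword search over five stem groups enriches the
pool, and annotation samples are drawn equally from each group with a quota
of point-mutation sentences.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus import ParsedSentence
from .relations import TEMPLATES, generate_candidates

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_KEYWORD_GROUPS",
    "SelectionRecord",
    "has_required_entities",
    "assign_groups",
    "count_task_candidates",
    "build_selection_record",
    "sample_for_annotation",
]

#: Keyword stems per enrichment group.  Stems match as case-insensitive
#: substrings anywhere in the sentence ("sensitiv" catches "sensitive" and
#: "sensitivity"); all-uppercase stems (DFS) match as standalone tokens,
#: case-sensitively.
DEFAULT_KEYWORD_GROUPS: dict[str, frozenset[str]] = {
    "general": frozenset({"marker"}),
    "diagnostic": frozenset({"diagnostic"}),
    "predictive": frozenset({"sensitiv", "resistance", "efficacy", "predict"}),
    "predisposing": frozenset({"risk", "predispos"}),
    "prognostic": frozenset({"survival", "prognos", "DFS"}),
}


@dataclass
class SelectionRecord:
    sentence: ParsedSentence
    matched_groups: frozenset[str]
    has_point_mutation: bool
    candidate_count: int


def has_required_entities(sent: ParsedSentence) -> bool:
    """True iff the sentence has >= 1 gene, >= 1 cancer and >= 1 variant mention."""
    types = [m.entity_type for m in sent.mentions]
    return (
        types.count("gene") >= 1
        and types.count("cancer") >= 1
        and types.count("variant") >= 1
    )


def assign_groups(
    sent: ParsedSentence | str,
    groups: Mapping[str, Iterable[str]] = DEFAULT_KEYWORD_GROUPS,
) -> frozenset[str]:
    text = sent if isinstance(sent, str) else sent.text
    low = text.lower()
    matched = set()
    for name, stems in groups.items():
        for stem in stems:
            if stem.isupper() and len(stem) > 1:
                if re.search(rf"\b{re.escape(stem)}\b", text):
                    matched.add(name)
                    break
            elif stem.lower() in low:
                matched.add(name)
                break
    return frozenset(matched)


def count_task_candidates(sent: ParsedSentence) -> int:
    """Biomarker-task candidate count: gene-cancer pairs + cancer-drug-gene triples.

    This is the combinatoric load an annotator (or the classifier) faces for
    the biomarker task on this sentence, and the quantity capped when
    sampling for annotation.
    """
    pairs = len(generate_candidates(sent, template=TEMPLATES["Prognostic"]))
    triples = len(generate_candidates(sent, template=TEMPLATES["Predictive"]))
    return pairs + triples


def build_selection_record(
    sent: ParsedSentence,
    groups: Mapping[str, Iterable[str]] = DEFAULT_KEYWORD_GROUPS,
) -> SelectionRecord:
    return SelectionRecord(
        sentence=sent,
        matched_groups=assign_groups(sent, groups),
        has_point_mutation=any(
            m.entity_type == "variant" and m.variant_group == "substitution"
            for m in sent.mentions
        ),
        candidate_count=count_task_candidates(sent),
    )


def sample_for_annotation(
    records: Sequence[SelectionRecord],
    total_n: int,
    cap: int = 5,
    point_mut_frac: float = 0.5,
    seed: int = 0,
    groups: Sequence[str] | None = None,
) -> list[SelectionRecord]:
    """Draw a balanced annotation sample.

    Sentences with more than ``cap`` biomarker-task candidates are excluded
    outright.  ``total_n / n_groups`` sentences are drawn per keyword group
    (a sentence drawn under one group is consumed and unavailable to the
    others); within each group, ``point_mut_frac`` of the draws (rounded
    down) are taken from point-mutation sentences when available.
    Deterministic under ``seed``; exhausted groups yield what they have with
    a warning.
    """
    if groups is None:
        groups = sorted(DEFAULT_KEYWORD_GROUPS)
    rng = random.Random(seed)
    eligible = [r for r in records if r.candidate_count <= cap]
    per_group = total_n // len(groups)
    drawn: list[SelectionRecord] = []
    taken: set[int] = set()

    def draw(pool: list[SelectionRecord], k: int) -> list[SelectionRecord]:
        pool = sorted(
            pool, key=lambda r: (r.sentence.doc_id, r.sentence.text)
        )
        rng.shuffle(pool)
        picked = pool[: max(0, k)]
        for r in picked:
            taken.add(id(r))
        return picked

    for g in groups:
        avail = [
            r for r in eligible if g in r.matched_groups and id(r) not in taken
        ]
        n_pm = int(per_group * point_mut_frac)
        pm_pool = [r for r in avail if r.has_point_mutation]
        got = draw(pm_pool, n_pm)
        rest_pool = [
            r for r in avail if id(r) not in taken
        ]
        got += draw(rest_pool, per_group - len(got))
        if len(got) < per_group:
            logger.warning(
                "group %s exhausted: drew %d of %d", g, len(got), per_group
            )
        drawn.extend(got)
    return drawn
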