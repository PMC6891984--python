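"""End-to-end workflows tying the stages together.

These helpers run the whole chain — simulate / read, tag, triage, train,
predict, collate, export — and are what the command-line interface, the
test-suite and the reproduction script call into.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .corpus import DocumentRecord, ParsedSentence
from .evaluation import pr_curve_and_threshold, stratified_split, weighted_prf
from .kb import BiomarkerRecord, collate, export_kb
from .lexicon import Lexicon, fixture_lexicon
from .ner import tag_sentence
from .relations import (
    TEMPLATES,
    GoldRelation,
    RelationExtractor,
    save_model,
)
from .synthetic import GeneratorConfig, GoldSentence, SyntheticCorpus, generate_corpus

__all__ = [
    "tag_gold_corpus",
    "split_corpus",
    "train_extractor",
    "evaluate_per_template",
    "select_thresholds",
    "run_end_to_end",
]


def tag_gold_corpus(
    corpus: SyntheticCorpus, lex: Lexicon | None = None
) -> tuple[list[ParsedSentence], list[list[GoldRelation]]]:
    """Parse + NER-tag every gold sentence; gold relations as span tuples."""
    lex = lex or corpus.lexicon
    sentences: list[ParsedSentence] = []
    gold: list[list[GoldRelation]] = []
    for gs in corpus.gold:
        sent = gs.as_parsed()
        tag_sentence(sent, lex)
        sentences.append(sent)
        gold.append(gs.gold_relations())
    return sentences, gold


def split_corpus(
    corpus: SyntheticCorpus,
    sentences: Sequence[ParsedSentence],
    gold: Sequence[Sequence[GoldRelation]],
    test_size: float = 0.25,
    seed: int = 0,
):
    """Stratified split (by template category) of tagged sentences + gold."""
    idx = list(range(len(sentences)))
    labels = [gs.category for gs in corpus.gold]
    train_idx, test_idx = stratified_split(idx, labels, test_size, seed)
    pick = lambda ids: (
        [sentences[i] for i in ids],
        [list(gold[i]) for i in ids],
        [corpus.gold[i] for i in ids],
    )
    return pick(train_idx), pick(test_idx)


def train_extractor(
    sentences: Sequence[ParsedSentence],
    gold: Sequence[Sequence[GoldRelation]],
    random_state: int = 0,
    **kw,
) -> RelationExtractor:
    model = RelationExtractor(random_state=random_state, **kw)
    model.fit(sentences, gold)
    return model


def _candidate_truth(
    model: RelationExtractor,
    sentences: Sequence[ParsedSentence],
    gold: Sequence[Sequence[GoldRelation]],
    template_name: str,
):
    cands, owner, probs = model.score_candidates(sentences, template_name)
    tpl = TEMPLATES[template_name]
    truth = []
    for c, si in zip(cands, owner):
        spans = {
            g.spans for g in gold[si] if g.template == template_name
        }
        truth.append(c.char_spans() in spans)
    return truth, probs.tolist(), owner


def evaluate_per_template(
    model: RelationExtractor,
    sentences: Sequence[ParsedSentence],
    gold: Sequence[Sequence[GoldRelation]],
    threshold: float | Mapping[str, float] = 0.5,
) -> dict[str, tuple[float, float, float]]:
    """Candidate-level precision/recall/F1 per template at a threshold."""
    out = {}
    for name in model.classifiers_:
        truth, probs, _ = _candidate_truth(model, sentences, gold, name)
        thr = threshold[name] if isinstance(threshold, Mapping) else threshold
        pred = [p >= thr for p in probs]
        out[name] = weighted_prf(truth, pred)
    return out


def select_thresholds(
    model: RelationExtractor,
    sentences: Sequence[ParsedSentence],
    gold: Sequence[Sequence[GoldRelation]],
    target_precision: float = 0.9,
    variant_target_precision: float = 0.94,
) -> dict[str, float]:
    """Choose per-template thresholds at a target precision on held-out data.

    The associated-variant relation is held to a higher bar than the four
    evidence types, matching its role as a qualifier attached to already
    accepted evidence.
    """
    chosen = {}
    for name in model.classifiers_:
        truth, probs, _ = _candidate_truth(model, sentences, gold, name)
        if not probs:
            continue
        target = (
            variant_target_precision
            if name == "AssociatedVariant"
            else target_precision
        )
        _, thr = pr_curve_and_threshold(
            probs, truth, target_precision=target
        )
        chosen[name] = thr
    return chosen


@dataclass
class EndToEndResult:
    corpus: SyntheticCorpus
    model: RelationExtractor
    records: list[BiomarkerRecord]
    biomarkers_path: Path
    sentences_path: Path


def run_end_to_end(
    seed: int,
    out_dir,
    counts: Mapping[str, int] | None = None,
    test_size: float = 0.25,
) -> EndToEndResult:
    """simulate -> tag -> train -> predict -> collate -> export.

    Fully deterministic under ``seed``: repeated runs produce byte-identical
    TSVs.  The model is trained on a stratified training split and applied
    to the whole corpus; the collated biomarker table and supporting
    sentences are exported under ``out_dir``.
    """
    out_dir = Path(out_dir)
    cfg = GeneratorConfig(seed=seed)
    if counts is not None:
        cfg.counts = dict(counts)
    corpus = generate_corpus(cfg, out_dir=out_dir / "corpus")
    sentences, gold = tag_gold_corpus(corpus)
    (train_s, train_g, _), _ = split_corpus(
        corpus, sentences, gold, test_size=test_size, seed=seed
    )
    model = train_extractor(train_s, train_g, random_state=seed % (2**31))
    docs = {d.doc_id: d for d in corpus.documents}
    items = model.predict(sentences, docs=docs)
    records = collate(items)
    bio_path, sent_path = export_kb(records, out_dir / "kb")
    save_model(model, out_dir / "model.json")
    return EndToEndResult(
        corpus=corpus,
        model=model,
        records=records,
        biomarkers_path=bio_path,
        sentences_path=sent_path,
    )
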