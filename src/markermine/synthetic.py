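"""Deterministic template-based corpus generator.

Every other stage of the pipeline — tagging, triage, candidate generation,
classifier training, collation — is testable without any download because
this module fabricates annotated corpora: template sentences with known
entity spans, a hand-written dependency tree per template (replayed by
:class:`~markermine.corpus.TemplateParser`, so no live parser is needed),
and gold relations of all five types plus realistic negatives.

Positive templates carry at least one gold relation; negative templates
carry none but still mention a gene, a cancer and a variant term (so they
pass triage) and contain enrichment keywords (so they land in keyword
groups).  Several templates carry distractor entities (an extra gene or
drug) so that negative candidates exist inside positive sentences — the
situation the classifier actually faces.

Sentences differ between templates in wording far more than real abstracts
do; what the generator exercises is the feature machinery and the learning
setup, not linguistic robustness (see the methods note).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .corpus import (
    DocumentRecord,
    ParsedSentence,
    SectionBlock,
    TemplateParser,
    tokenize,
    write_corpus_jsonl,
)
from .lexicon import Lexicon, TermEntry, fixture_lexicon
from .relations import TEMPLATES, GoldRelation

__all__ = [
    "SentenceTemplate",
    "GeneratorConfig",
    "GoldMention",
    "GoldSentence",
    "SyntheticCorpus",
    "generate_corpus",
    "SUBSTITUTIONS",
    "SENTENCE_TEMPLATES",
]

SUBSTITUTIONS = [
    "V600E",
    "T315I",
    "L858R",
    "T790M",
    "G12D",
    "V617F",
    "R132H",
    "D816V",
    "E545K",
    "H1047R",
]

JOURNALS = [
    "J Synth Oncol",
    "Ann Fabricated Med",
    "Mol Template Rep",
]

# item kinds: ("t", word) literal; ("v", word, group) literal variant entity;
# ("p", NAME) placeholder entity (GENE/GENE2/CANCER/DRUG/DRUG2/SUBST)
_PLACEHOLDER_TYPES = {
    "GENE": "gene",
    "GENE2": "gene",
    "CANCER": "cancer",
    "DRUG": "drug",
    "DRUG2": "drug",
    "SUBST": "variant",
}

_NO_SPACE_BEFORE = {".", ",", ";", ":", ")", "?", "!"}


@dataclass(frozen=True)
class SentenceTemplate:
    """A template sentence: items, a dependency tree over items, gold relations.

    ``arcs[i] = (head_item, label)`` with one root (head ``-1``).  Relation
    slots reference item indices, in the slot order of the named template.
    """

    name: str
    category: str
    items: tuple[tuple, ...]
    arcs: tuple[tuple[int, str], ...]
    relations: tuple[tuple[str, tuple[int, ...]], ...]
    groups: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.items) != len(self.arcs):
            raise ValueError(f"template {self.name}: items/arcs length mismatch")
        roots = [i for i, (h, _) in enumerate(self.arcs) if h == -1]
        if len(roots) != 1:
            raise ValueError(f"template {self.name}: needs exactly one root")
        for rel_name, slots in self.relations:
            tpl = TEMPLATES[rel_name]
            if len(slots) != tpl.arity:
                raise ValueError(
                    f"template {self.name}: bad arity for {rel_name}"
                )
            for slot_type, idx in zip(tpl.slots, slots):
                item = self.items[idx]
                itype = (
                    _PLACEHOLDER_TYPES[item[1]]
                    if item[0] == "p"
                    else "variant"
                    if item[0] == "v"
                    else None
                )
                if itype != slot_type:
                    raise ValueError(
                        f"template {self.name}: item {idx} is {itype}, "
                        f"{rel_name} slot needs {slot_type}"
                    )


def _t(w):
    return ("t", w)


def _v(w, g):
    return ("v", w, g)


def _p(n):
    return ("p", n)


SENTENCE_TEMPLATES: tuple[SentenceTemplate, ...] = (
    SentenceTemplate(
        name="diag-criterion",
        category="diagnostic",
        items=(
            _p("GENE"), _p("SUBST"), _t("is"), _t("a"), _t("major"),
            _t("diagnostic"), _t("criterion"), _t("for"), _p("CANCER"), _t("."),
        ),
        arcs=(
            (1, "compound"), (6, "nsubj"), (6, "cop"), (6, "det"), (6, "amod"),
            (6, "amod"), (-1, "root"), (6, "prep"), (7, "pobj"), (6, "punct"),
        ),
        relations=(("Diagnostic", (8, 0)), ("AssociatedVariant", (0, 1))),
        groups=frozenset({"diagnostic"}),
    ),
    SentenceTemplate(
        name="diag-workup",
        category="diagnostic",
        items=(
            _t("Detection"), _t("of"), _p("GENE"), _p("SUBST"), _t("supports"),
            _t("the"), _t("diagnostic"), _t("workup"), _t("of"), _p("CANCER"),
            _t(","), _t("unlike"), _p("GENE2"), _t("."),
        ),
        arcs=(
            (4, "nsubj"), (0, "prep"), (3, "compound"), (1, "pobj"),
            (-1, "root"), (7, "det"), (7, "amod"), (4, "dobj"), (7, "prep"),
            (8, "pobj"), (4, "punct"), (4, "prep"), (11, "pobj"), (4, "punct"),
        ),
        relations=(("Diagnostic", (9, 2)), ("AssociatedVariant", (2, 3))),
        groups=frozenset({"diagnostic"}),
    ),
    SentenceTemplate(
        name="pred-sensitivity",
        category="predictive",
        items=(
            _p("CANCER"), _t("patients"), _t("with"), _p("GENE"),
            _v("mutations", "mutation"), _t("showed"), _t("sensitivity"),
            _t("to"), _p("DRUG"), _t("."),
        ),
        arcs=(
            (1, "compound"), (5, "nsubj"), (1, "prep"), (4, "compound"),
            (2, "pobj"), (-1, "root"), (5, "dobj"), (6, "prep"), (7, "pobj"),
            (5, "punct"),
        ),
        relations=(("Predictive", (0, 8, 3)), ("AssociatedVariant", (3, 4))),
        groups=frozenset({"predictive"}),
    ),
    SentenceTemplate(
        name="pred-efficacy",
        category="predictive",
        items=(
            _p("GENE"), _p("SUBST"), _t("predicts"), _t("efficacy"), _t("of"),
            _p("DRUG"), _t("but"), _t("not"), _p("DRUG2"), _t("in"),
            _p("CANCER"), _t("."),
        ),
        arcs=(
            (1, "compound"), (2, "nsubj"), (-1, "root"), (2, "dobj"),
            (3, "prep"), (4, "pobj"), (5, "cc"), (8, "neg"), (5, "conj"),
            (2, "prep"), (9, "pobj"), (2, "punct"),
        ),
        relations=(("Predictive", (10, 5, 0)), ("AssociatedVariant", (0, 1))),
        groups=frozenset({"predictive"}),
    ),
    SentenceTemplate(
        name="predis-germline",
        category="predisposing",
        items=(
            _t("Germline"), _v("mutations", "mutation"), _t("in"), _p("GENE"),
            _t("increase"), _t("the"), _t("risk"), _t("of"), _t("developing"),
            _p("CANCER"), _t("."),
        ),
        arcs=(
            (1, "amod"), (4, "nsubj"), (1, "prep"), (2, "pobj"), (-1, "root"),
            (6, "det"), (4, "dobj"), (6, "prep"), (7, "pcomp"), (8, "dobj"),
            (4, "punct"),
        ),
        relations=(("Predisposing", (9, 3)), ("AssociatedVariant", (3, 1))),
        groups=frozenset({"predisposing"}),
    ),
    SentenceTemplate(
        name="predis-carriers",
        category="predisposing",
        items=(
            _p("GENE"), _v("variants", "mutation"), _t("predispose"),
            _t("carriers"), _t("to"), _p("CANCER"), _t(","), _t("whereas"),
            _p("GENE2"), _v("variants", "mutation"), _t("do"), _t("not"),
            _t("."),
        ),
        arcs=(
            (1, "compound"), (2, "nsubj"), (-1, "root"), (2, "dobj"),
            (2, "prep"), (4, "pobj"), (2, "punct"), (10, "mark"),
            (9, "compound"), (10, "nsubj"), (2, "advcl"), (10, "neg"),
            (2, "punct"),
        ),
        relations=(
            ("Predisposing", (5, 0)),
            ("AssociatedVariant", (0, 1)),
            ("AssociatedVariant", (8, 9)),
        ),
        groups=frozenset({"predisposing"}),
    ),
    SentenceTemplate(
        name="prog-expression",
        category="prognostic",
        items=(
            _t("High"), _v("expression", "expression"), _t("of"), _p("GENE"),
            _t("is"), _t("associated"), _t("with"), _t("poor"), _t("survival"),
            _t("in"), _p("CANCER"), _t("."),
        ),
        arcs=(
            (1, "amod"), (5, "nsubjpass"), (1, "prep"), (2, "pobj"),
            (5, "auxpass"), (-1, "root"), (5, "prep"), (8, "amod"), (6, "pobj"),
            (5, "prep"), (9, "pobj"), (5, "punct"),
        ),
        relations=(("Prognostic", (10, 3)), ("AssociatedVariant", (3, 1))),
        groups=frozenset({"prognostic"}),
    ),
    SentenceTemplate(
        name="prog-dfs",
        category="prognostic",
        items=(
            _p("GENE"), _p("SUBST"), _t("is"), _t("an"), _t("independent"),
            _t("prognostic"), _t("marker"), _t("of"), _t("shorter"), _t("DFS"),
            _t("in"), _p("CANCER"), _t("."),
        ),
        arcs=(
            (1, "compound"), (6, "nsubj"), (6, "cop"), (6, "det"), (6, "amod"),
            (6, "amod"), (-1, "root"), (6, "prep"), (9, "amod"), (7, "pobj"),
            (6, "prep"), (10, "pobj"), (6, "punct"),
        ),
        relations=(("Prognostic", (11, 0)), ("AssociatedVariant", (0, 1))),
        groups=frozenset({"prognostic", "general"}),
    ),
    SentenceTemplate(
        name="var-sequencing",
        category="variant",
        items=(
            _t("Targeted"), _t("sequencing"), _t("of"), _p("CANCER"),
            _t("samples"), _t("revealed"), _t("recurrent"), _p("GENE"),
            _p("SUBST"), _v("mutations", "mutation"), _t("in"), _t("the"),
            _t("risk"), _t("cohort"), _t("."),
        ),
        arcs=(
            (1, "amod"), (5, "nsubj"), (1, "prep"), (4, "compound"),
            (2, "pobj"), (-1, "root"), (9, "amod"), (9, "compound"),
            (9, "compound"), (5, "dobj"), (5, "prep"), (13, "det"),
            (13, "compound"), (10, "pobj"), (5, "punct"),
        ),
        relations=(
            ("AssociatedVariant", (7, 8)),
            ("AssociatedVariant", (7, 9)),
        ),
        groups=frozenset({"predisposing"}),
    ),
    SentenceTemplate(
        name="var-detected",
        category="variant",
        items=(
            _t("The"), _p("GENE"), _p("SUBST"), _v("variant", "mutation"),
            _t("was"), _t("detected"), _t("in"), _t("several"), _p("CANCER"),
            _t("biopsies"), _t("without"), _t("survival"), _t("correlation"),
            _t("."),
        ),
        arcs=(
            (3, "det"), (3, "compound"), (3, "compound"), (5, "nsubjpass"),
            (5, "auxpass"), (-1, "root"), (5, "prep"), (9, "amod"),
            (9, "compound"), (6, "pobj"), (5, "prep"), (12, "compound"),
            (10, "pobj"), (5, "punct"),
        ),
        relations=(
            ("AssociatedVariant", (1, 2)),
            ("AssociatedVariant", (1, 3)),
        ),
        groups=frozenset({"prognostic"}),
    ),
    SentenceTemplate(
        name="neg-assay",
        category="negative",
        items=(
            _t("We"), _t("measured"), _v("expression", "expression"),
            _t("profiles"), _t("in"), _p("CANCER"), _t("cell"), _t("lines"),
            _t("lacking"), _p("GENE"), _t("to"), _t("calibrate"), _t("the"),
            _t("survival"), _t("assay"), _t("."),
        ),
        arcs=(
            (1, "nsubj"), (-1, "root"), (3, "compound"), (1, "dobj"),
            (1, "prep"), (7, "compound"), (7, "compound"), (4, "pobj"),
            (7, "acl"), (8, "dobj"), (11, "aux"), (1, "advcl"), (14, "det"),
            (14, "compound"), (11, "dobj"), (1, "punct"),
        ),
        relations=(),
        groups=frozenset({"prognostic"}),
    ),
    SentenceTemplate(
        name="neg-profiling",
        category="negative",
        items=(
            _v("Expression", "expression"), _t("profiling"), _t("of"),
            _p("CANCER"), _t("tissues"), _t("placed"), _p("GENE"), _t("among"),
            _t("markers"), _t("with"), _t("uncertain"), _t("relevance"),
            _t("."),
        ),
        arcs=(
            (1, "compound"), (5, "nsubj"), (1, "prep"), (4, "compound"),
            (2, "pobj"), (-1, "root"), (5, "dobj"), (5, "prep"), (7, "pobj"),
            (8, "prep"), (11, "amod"), (9, "pobj"), (5, "punct"),
        ),
        relations=(),
        groups=frozenset({"general"}),
    ),
    SentenceTemplate(
        name="neg-no-mutations",
        category="negative",
        items=(
            _t("A"), _t("sensitive"), _t("assay"), _t("found"), _t("no"),
            _v("mutations", "mutation"), _t(","), _t("and"), _p("GENE"),
            _t("levels"), _t("in"), _p("CANCER"), _t("did"), _t("not"),
            _t("predict"), _t("risk"), _t("."),
        ),
        arcs=(
            (2, "det"), (2, "amod"), (3, "nsubj"), (-1, "root"), (5, "neg"),
            (3, "dobj"), (3, "punct"), (3, "cc"), (9, "compound"),
            (14, "nsubj"), (9, "prep"), (10, "pobj"), (14, "aux"), (14, "neg"),
            (3, "conj"), (14, "dobj"), (3, "punct"),
        ),
        relations=(),
        groups=frozenset({"predictive", "predisposing"}),
    ),
    SentenceTemplate(
        name="neg-imaging",
        category="negative",
        items=(
            _t("The"), _t("diagnostic"), _t("yield"), _t("of"), _t("imaging"),
            _t("in"), _p("CANCER"), _t("was"), _t("not"), _t("improved"),
            _t("by"), _p("GENE"), _t("testing"), _t(","), _t("despite"),
            _t("frequent"), _v("mutations", "mutation"), _t("."),
        ),
        arcs=(
            (2, "det"), (2, "amod"), (9, "nsubjpass"), (2, "prep"),
            (3, "pobj"), (2, "prep"), (5, "pobj"), (9, "auxpass"), (9, "neg"),
            (-1, "root"), (9, "agent"), (12, "compound"), (10, "pobj"),
            (9, "punct"), (9, "prep"), (16, "amod"), (14, "pobj"),
            (9, "punct"),
        ),
        relations=(),
        groups=frozenset({"diagnostic"}),
    ),
)

DEFAULT_COUNTS = {
    "diagnostic": 100,
    "predictive": 100,
    "predisposing": 100,
    "prognostic": 100,
    "variant": 100,
    "negative": 100,
}


@dataclass
class GeneratorConfig:
    seed: int
    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    lexicon: Lexicon | None = None    # defaults to the shipped fixture lexicon

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class GoldMention:
    entity_type: str
    term_ids: tuple[str, ...]
    char_span: tuple[int, int]
    text: str
    variant_group: str | None = None


@dataclass
class GoldSentence:
    doc_id: str
    text: str
    tokens: list[tuple[str, int, int]]
    arcs: list[tuple[int, int, str]]
    mentions: list[GoldMention]
    relations: list[tuple[str, tuple[int, ...]]]   # (template, mention idxs)
    category: str
    groups: frozenset[str]
    has_point_mutation: bool

    def as_parsed(self, section_label: str = "abstract") -> ParsedSentence:
        sent = ParsedSentence(
            text=self.text,
            tokens=[tuple(t) for t in self.tokens],
            arcs=[tuple(a) for a in self.arcs],
            doc_id=self.doc_id,
            section_label=section_label,
        )
        sent.validate()
        return sent

    def gold_relations(self) -> list[GoldRelation]:
        return [
            GoldRelation(
                template=name,
                spans=tuple(self.mentions[i].char_span for i in idxs),
            )
            for name, idxs in self.relations
        ]


@dataclass
class SyntheticCorpus:
    documents: list[DocumentRecord]
    gold: list[GoldSentence]
    lexicon: Lexicon

    def parser(self) -> TemplateParser:
        return TemplateParser(
            {gs.text: (gs.tokens, gs.arcs) for gs in self.gold}
        )

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_corpus_jsonl(self.documents, out_dir / "corpus.jsonl")
        with open(out_dir / "gold.jsonl", "w", encoding="utf-8") as fh:
            for gs in self.gold:
                fh.write(
                    json.dumps(
                        {
                            "doc_id": gs.doc_id,
                            "text": gs.text,
                            "tokens": gs.tokens,
                            "arcs": gs.arcs,
                            "mentions": [
                                {
                                    "entity_type": m.entity_type,
                                    "term_ids": list(m.term_ids),
                                    "start": m.char_span[0],
                                    "end": m.char_span[1],
                                    "text": m.text,
                                    "variant_group": m.variant_group,
                                }
                                for m in gs.mentions
                            ],
                            "relations": [
                                {"type": name, "mention_idxs": list(idxs)}
                                for name, idxs in gs.relations
                            ],
                            "category": gs.category,
                            "groups": sorted(gs.groups),
                            "has_point_mutation": gs.has_point_mutation,
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )
        by_type = {"gene": [], "cancer": [], "drug": [], "variant": []}
        for e in self.lexicon.entries:
            by_type[e.entity_type].append(e)
        for etype, fname in (
            ("gene", "genes.tsv"),
            ("cancer", "cancers.tsv"),
            ("drug", "drugs.tsv"),
            ("variant", "variants.tsv"),
        ):
            with open(out_dir / fname, "w", encoding="utf-8") as fh:
                for e in sorted(by_type[etype], key=lambda e: e.term_id):
                    fh.write(
                        f"{e.term_id}\t{e.entity_type}\t{e.canonical_name}\t"
                        + "|".join(sorted(e.synonyms))
                        + "\n"
                    )
        with open(out_dir / "stopwords.txt", "w", encoding="utf-8") as fh:
            for w in sorted(self.lexicon.stopwords):
                fh.write(w + "\n")


def _fill_template(
    tpl: SentenceTemplate,
    rng: random.Random,
    lex: Lexicon,
) -> tuple[str, list, list, list[GoldMention], list]:
    """Fill placeholders; returns (text, tokens, arcs, mentions, relations)."""
    genes = sorted(lex.by_type("gene"), key=lambda e: e.term_id)
    cancers = sorted(lex.by_type("cancer"), key=lambda e: e.term_id)
    drugs = sorted(
        (e for e in lex.by_type("drug") if not e.term_id.startswith(("inhibitor:", "category:"))),
        key=lambda e: e.term_id,
    )
    variant_entries = {
        e.term_id: e for e in lex.by_type("variant")
    }
    if not (genes and cancers and drugs):
        raise ValueError(
            f"template {tpl.name}: lexicon lacks entries for placeholders"
        )
    gene_pick = rng.sample(genes, k=2) if len(genes) >= 2 else genes * 2
    drug_pick = rng.sample(drugs, k=2) if len(drugs) >= 2 else drugs * 2
    fills: dict[str, tuple[str, tuple[str, ...], str | None]] = {}
    for kind, *rest in tpl.items:
        if kind != "p":
            continue
        name = rest[0]
        if name in fills:
            raise ValueError(f"template {tpl.name}: duplicate placeholder {name}")
        if name == "GENE":
            e = gene_pick[0]
            fills[name] = (e.canonical_name, (e.term_id,), None)
        elif name == "GENE2":
            e = gene_pick[1]
            fills[name] = (e.canonical_name, (e.term_id,), None)
        elif name == "CANCER":
            e = rng.choice(cancers)
            fills[name] = (e.canonical_name, (e.term_id,), None)
        elif name == "DRUG":
            e = drug_pick[0]
            fills[name] = (e.canonical_name, (e.term_id,), None)
        elif name == "DRUG2":
            e = drug_pick[1]
            fills[name] = (e.canonical_name, (e.term_id,), None)
        elif name == "SUBST":
            s = rng.choice(SUBSTITUTIONS)
            fills[name] = (s, (s,), "substitution")
        else:
            raise ValueError(f"template {tpl.name}: unknown placeholder {name}")

    text = ""
    tokens: list[tuple[str, int, int]] = []
    item_range: list[tuple[int, int]] = []   # [first_tok, last_tok] per item
    item_span: list[tuple[int, int]] = []    # char span per item
    for kind, *rest in tpl.items:
        if kind == "p":
            word = fills[rest[0]][0]
        else:
            word = rest[0]
        if text and word not in _NO_SPACE_BEFORE:
            text += " "
        start = len(text)
        text += word
        ftoks = tokenize(word)
        first = len(tokens)
        for surf, a, b in ftoks:
            tokens.append((surf, start + a, start + b))
        item_range.append((first, len(tokens) - 1))
        item_span.append((start, start + len(word)))

    # project item-level arcs onto tokens; multi-token fillers hang their
    # leading tokens off the final token, which carries the item's arc
    arcs: list[tuple[int, int, str]] = []
    for i, (head_item, label) in enumerate(tpl.arcs):
        first, last = item_range[i]
        for t in range(first, last):
            lab = "punct" if tokens[t][0] == "-" else "compound"
            arcs.append((last, t, lab))
        head_tok = -1 if head_item == -1 else item_range[head_item][1]
        arcs.append((head_tok, last, label))
    arcs.sort(key=lambda a: a[1])

    mentions: list[GoldMention] = []
    item_to_mention: dict[int, int] = {}
    for i, (kind, *rest) in enumerate(tpl.items):
        if kind == "p":
            word, ids, group = fills[rest[0]]
            etype = _PLACEHOLDER_TYPES[rest[0]]
        elif kind == "v":
            word, group = rest
            entry = None
            for e in variant_entries.values():
                if word.lower() in {s.lower() for s in e.synonyms}:
                    entry = e
                    break
            if entry is None:
                raise ValueError(
                    f"template {tpl.name}: variant literal {word!r} "
                    "missing from lexicon"
                )
            ids = (entry.term_id,)
            etype = "variant"
        else:
            continue
        item_to_mention[i] = len(mentions)
        mentions.append(
            GoldMention(
                entity_type=etype,
                term_ids=tuple(sorted(ids)),
                char_span=item_span[i],
                text=text[item_span[i][0] : item_span[i][1]],
                variant_group=group,
            )
        )
    relations = [
        (name, tuple(item_to_mention[i] for i in idxs))
        for name, idxs in tpl.relations
    ]
    return text, tokens, arcs, mentions, relations


def generate_corpus(
    config: GeneratorConfig, out_dir=None
) -> SyntheticCorpus:
    """Generate a corpus per config; deterministic under ``config.seed``.

    Returns the corpus in memory; with ``out_dir`` also writes corpus
    JSON-lines, gold standoff JSON-lines, and the mini-lexicon TSVs.
    """
    lex = config.lexicon if config.lexicon is not None else fixture_lexicon()
    rng = random.Random(config.seed)
    by_cat: dict[str, list[SentenceTemplate]] = {}
    for tpl in SENTENCE_TEMPLATES:
        by_cat.setdefault(tpl.category, []).append(tpl)
    unknown = set(config.counts) - set(by_cat)
    if unknown:
        raise ValueError(f"no templates for categories: {sorted(unknown)}")

    documents: list[DocumentRecord] = []
    gold: list[GoldSentence] = []
    i = 0
    for cat in sorted(config.counts):
        for _ in range(config.counts[cat]):
            tpl = rng.choice(by_cat[cat])
            text, tokens, arcs, mentions, relations = _fill_template(
                tpl, rng, lex
            )
            doc_id = f"SYN{i:06d}"
            year = rng.randint(1995, 2020)
            journal = rng.choice(JOURNALS)
            documents.append(
                DocumentRecord(
                    doc_id=doc_id,
                    title="",
                    journal=journal,
                    year=year,
                    pmid=10_000_000 + i,
                    sections=(
                        SectionBlock(
                            label="abstract", raw_label="abstract", text=text
                        ),
                    ),
                )
            )
            gold.append(
                GoldSentence(
                    doc_id=doc_id,
                    text=text,
                    tokens=tokens,
                    arcs=arcs,
                    mentions=mentions,
                    relations=relations,
                    category=cat,
                    groups=tpl.groups,
                    has_point_mutation=any(
                        m.variant_group == "substitution" for m in mentions
                    ),
                )
            )
            i += 1
    corpus = SyntheticCorpus(documents=documents, gold=gold, lexicon=lex)
    for gs in corpus.gold:
        gs.as_parsed()   # validates token spans and tree structure
    if out_dir is not None:
        corpus.write(out_dir)
    return corpus
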