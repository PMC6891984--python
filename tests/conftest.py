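"""Shared fixtures: fixture lexicon, sentence builders, synthetic corpus."""

from __future__ import annotations

import pytest

from markermine.corpus import (
    DocumentRecord,
    ParsedSentence,
    SectionBlock,
    SimpleParser,
    parse_sentences,
)
from markermine.lexicon import fixture_lexicon
from markermine.ner import EntityMention, tag_sentence
from markermine.pipeline import (
    split_corpus,
    tag_gold_corpus,
    train_extractor,
)
from markermine.synthetic import GeneratorConfig, generate_corpus

CORPUS_SEED = 11


@pytest.fixture(scope="session")
def lex():
    return fixture_lexicon()


@pytest.fixture(scope="session")
def parser():
    return SimpleParser()


@pytest.fixture()
def tag_text(lex, parser):
    """Parse + NER-tag a raw text; returns the list of sentences."""

    def _tag(text: str, lexicon=None) -> list[ParsedSentence]:
        doc = DocumentRecord(
            doc_id="t", sections=(SectionBlock("abstract", "abstract", text),)
        )
        sents = parse_sentences(doc, parser)
        for s in sents:
            tag_sentence(s, lexicon or lex)
        return sents

    return _tag


def make_mention_sentence(types: list[str]) -> ParsedSentence:
    """A sentence of one-word tokens, one non-overlapping mention per type entry."""
    words = [f"w{i}" for i in range(len(types))]
    text = " ".join(words)
    tokens = []
    pos = 0
    for w in words:
        tokens.append((w, pos, pos + len(w)))
        pos += len(w) + 1
    arcs = [(-1, 0, "root")] + [(i - 1, i, "dep") for i in range(1, len(words))]
    sent = ParsedSentence(text=text, tokens=tokens, arcs=arcs, doc_id="m")
    sent.mentions = [
        EntityMention(
            entity_type=t,
            term_ids=frozenset({f"id{i}"}),
            token_span=(i, i + 1),
            char_span=tokens[i][1:],
            text=tokens[i][0],
            variant_group="substitution" if t == "variant" else None,
        )
        for i, t in enumerate(types)
    ]
    return sent


@pytest.fixture(scope="session")
def synth600():
    """600-sentence synthetic corpus (100 per category), tagged, with gold."""
    corpus = generate_corpus(GeneratorConfig(seed=CORPUS_SEED))
    sentences, gold = tag_gold_corpus(corpus)
    return corpus, sentences, gold


@pytest.fixture(scope="session")
def trained(synth600):
    """Model trained on a stratified 400-sentence split; 200 held out."""
    corpus, sentences, gold = synth600
    train, test = split_corpus(
        corpus, sentences, gold, test_size=1 / 3, seed=CORPUS_SEED
    )
    model = train_extractor(train[0], train[1], random_state=CORPUS_SEED)
    return model, train, test
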