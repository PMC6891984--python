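"""Entity tagging: longest match, mutations, fusions, acronyms, merging."""

import pytest

from markermine.corpus import (
    DocumentRecord,
    ParsedSentence,
    SectionBlock,
    SimpleParser,
    parse_sentences,
)
from markermine.lexicon import Lexicon, TermEntry, compile_matcher
from markermine.ner import (
    match_point_mutations,
    match_terms,
    tag_sentence,
)
from markermine.synthetic import GeneratorConfig, generate_corpus


def by_type(sent, etype):
    return [m for m in sent.mentions if m.entity_type == etype]


class TestDictionaryMatching:
    def test_longest_match_wins(self, tag_text):
        (s,) = tag_text("We studied non-small cell lung cancer cases.")
        cancers = by_type(s, "cancer")
        assert [m.text for m in cancers] == ["non-small cell lung cancer"]

    def test_hyphen_space_equivalence(self, tag_text):
        (s,) = tag_text("We studied non small cell lung cancer cases.")
        assert [m.text for m in by_type(s, "cancer")] == [
            "non small cell lung cancer"
        ]

    def test_dual_type_same_span(self, tag_text):
        (s,) = tag_text("Hereditary retinoblastoma was reviewed.")
        spans = {(m.entity_type, m.char_span) for m in s.mentions}
        types = {t for t, _ in spans}
        assert {"gene", "cancer"} <= types
        assert len({sp for _, sp in spans}) == 1

    def test_no_hits(self, tag_text):
        (s,) = tag_text("Nothing relevant here.")
        assert s.mentions == []


class TestPointMutations:
    @pytest.mark.parametrize("tok", ["V600E", "T315I", "L858R"])
    def test_valid_substitutions(self, tag_text, tok):
        (s,) = tag_text(f"The {tok} mutation was found.")
        variants = by_type(s, "variant")
        assert [m.text for m in variants] == [tok]
        assert variants[0].variant_group == "substitution"

    def test_non_amino_letters_rejected(self, tag_text):
        (s,) = tag_text("Sample X123Y was processed.")
        assert by_type(s, "variant") == []

    def test_blocklist_skipped(self, tag_text):
        (s,) = tag_text("Cells T47D were cultured.")
        assert by_type(s, "variant") == []


class TestFusions:
    def test_disjoint_ids_flag_fusion(self, tag_text):
        (s,) = tag_text("The BCR-ABL1 fusion drives disease.")
        (g,) = by_type(s, "gene")
        assert g.is_fusion and g.term_ids == frozenset({"613", "25"})
        assert g.text == "BCR-ABL1"

    def test_overlapping_ids_merge_to_single_gene(self, tag_text):
        (s,) = tag_text("HER2/neu status was assessed.")
        (g,) = by_type(s, "gene")
        assert not g.is_fusion and g.term_ids == frozenset({"2064"})

    def test_no_separator_unchanged(self, tag_text):
        (s,) = tag_text("EGFR expression was high.")
        assert [m.text for m in by_type(s, "gene")] == ["EGFR"]

    def test_space_around_separator_blocks_fusion(self, tag_text):
        (s,) = tag_text("BCR - ABL1 were each studied.")
        assert len(by_type(s, "gene")) == 2


class TestAcronyms:
    def test_overlapping_ids_keep_long_form_only(self, tag_text):
        (s,) = tag_text(
            "In non-small cell lung carcinoma (NSCLC) mutations occur."
        )
        cancers = by_type(s, "cancer")
        assert [m.text for m in cancers] == ["non-small cell lung carcinoma"]

    def test_short_form_inherits_long_form_ids(self, tag_text):
        (s,) = tag_text(
            "Seen in myeloproliferative neoplasms (MPNs) and elsewhere."
        )
        cancers = sorted(by_type(s, "cancer"), key=lambda m: m.char_span)
        assert [m.text for m in cancers] == [
            "myeloproliferative neoplasms",
            "MPNs",
        ]
        assert cancers[0].term_ids == cancers[1].term_ids

    def test_disjoint_ids_discard_short_form(self, tag_text):
        # custom lexicon: long form is a cancer, short form collides with a gene
        lex = compile_matcher(
            Lexicon(
                entries=[
                    TermEntry(
                        "DOID:x",
                        "cancer",
                        "alpha beta carcinoma",
                        frozenset({"alpha beta carcinoma"}),
                    ),
                    TermEntry("g9", "gene", "ABC", frozenset({"ABC"})),
                ]
            )
        )
        (s,) = tag_text("We studied alpha beta carcinoma (ABC) cohorts.", lex)
        assert [m.entity_type for m in s.mentions] == ["cancer"]
        assert s.mentions[0].text == "alpha beta carcinoma"


class TestPostprocessing:
    @pytest.mark.parametrize(
        "text,expect_gene",
        [
            ("MTOR signaling was active.", False),
            ("The EGFR pathway is induced.", False),
            ("EGFR mutations were found.", True),
        ],
    )
    def test_pathway_suppression(self, tag_text, text, expect_gene):
        (s,) = tag_text(text)
        assert bool(by_type(s, "gene")) is expect_gene

    def test_adjacent_merge(self, tag_text):
        (s,) = tag_text("HER2 neu amplification predicts response.")
        (g,) = by_type(s, "gene")
        assert g.text == "HER2 neu" and g.term_ids == frozenset({"2064"})


WORKED_EXAMPLES = [
    (
        "JAK2 V617F is the most common mutation in myeloproliferative "
        "neoplasms (MPNs) and is a major diagnostic criterion.",
        {
            ("gene", "JAK2"),
            ("variant", "V617F"),
            ("cancer", "myeloproliferative neoplasms"),
            ("cancer", "MPNs"),
        },
    ),
    (
        "In non-small cell lung cancer (NSCLC) driver mutations of EGFR are "
        "positive predictive biomarkers for efficacy of erlotinib and "
        "gefitinib.",
        {
            ("cancer", "non-small cell lung cancer"),
            ("variant", "mutations"),
            ("gene", "EGFR"),
            ("drug", "erlotinib"),
            ("drug", "gefitinib"),
        },
    ),
    (
        "Our study suggests that one BRCA1 variant may be associated with "
        "increased risk of breast cancer.",
        {
            ("gene", "BRCA1"),
            ("variant", "variant"),
            ("cancer", "breast cancer"),
        },
    ),
    (
        "Overexpression of Her2 in breast cancer is a key feature of "
        "pathobiology of the disease and is associated with poor prognosis.",
        {
            ("variant", "Overexpression"),
            ("gene", "Her2"),
            ("cancer", "breast cancer"),
        },
    ),
]


@pytest.mark.parametrize("text,expected", WORKED_EXAMPLES)
def test_worked_example_entity_sets(tag_text, text, expected):
    """One representative sentence per evidence type tags exactly as documented."""
    (s,) = tag_text(text)
    assert {(m.entity_type, m.text) for m in s.mentions} == expected


@pytest.fixture(scope="module")
def tagged_corpus():
    corpus = generate_corpus(GeneratorConfig(seed=3))
    lex = corpus.lexicon
    sents = []
    for gs in corpus.gold[:150]:
        sent = gs.as_parsed()
        tag_sentence(sent, lex)
        sents.append(sent)
    return sents


class TestPipelineInvariants:
    def test_no_same_type_overlaps(self, tagged_corpus):
        for s in tagged_corpus:
            ms = s.mentions
            for i, a in enumerate(ms):
                for b in ms[i + 1 :]:
                    if a.entity_type == b.entity_type:
                        assert not a.overlaps(b), (s.text, a, b)

    def test_span_consistency(self, tagged_corpus):
        for s in tagged_corpus:
            for m in s.mentions:
                assert s.text[m.char_span[0] : m.char_span[1]] == m.text

    def test_determinism(self, lex):
        corpus = generate_corpus(GeneratorConfig(seed=3))
        for gs in corpus.gold[:30]:
            a = tag_sentence(gs.as_parsed(), corpus.lexicon).mentions
            b = tag_sentence(gs.as_parsed(), corpus.lexicon).mentions
            assert a == b
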