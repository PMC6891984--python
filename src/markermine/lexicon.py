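"""Typed term lists compiled to a token-sequence matcher.

Term lists for the four entity types (gene, cancer, drug, variant) are
consumed as TSV files — ``term_id<TAB>entity_type<TAB>canonical_name<TAB>
syn1|syn2|...`` — filtered against a stopword list, optionally expanded with
gene-derived inhibitor terms ("EGFR inhibitors"), and compiled into an index
over token sequences so dictionary tagging is linear in sentence length.

Matching conventions (applied identically to lexicon entries and sentences):

* synonyms of four or more characters match case-insensitively; shorter
  synonyms (e.g. 3-letter gene symbols) match case-sensitively, since short
  symbols collide with ordinary words beyond what a stopword list covers;
* token sequences are compared with hyphen tokens removed, so orthographic
  variants such as "non-small cell" / "non small cell" are equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .corpus import tokenize

__all__ = [
    "TermEntry",
    "Matcher",
    "Lexicon",
    "ENTITY_TYPES",
    "load_wordlist",
    "expand_inhibitors",
    "compile_matcher",
    "fixture_lexicon",
]

ENTITY_TYPES = ("gene", "cancer", "drug", "variant")

_DATA_DIR = Path(__file__).parent / "data"

#: Minimum synonym length (characters) for case-insensitive matching.
CASE_INSENSITIVE_MIN_LEN = 4


@dataclass(frozen=True)
class TermEntry:
    term_id: str
    entity_type: str
    canonical_name: str
    synonyms: frozenset[str]

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity_type {self.entity_type!r}")


def _norm_tokens(text: str) -> tuple[str, ...]:
    """Token surfaces with hyphen tokens dropped (the comparison form)."""
    return tuple(t for t, _, _ in tokenize(text) if t != "-")


@dataclass
class Matcher:
    """Compiled token-sequence index: synonym tokens -> {(entity_type, term_id)}."""

    ci: dict[tuple[str, ...], set[tuple[str, str]]] = field(default_factory=dict)
    cs: dict[tuple[str, ...], set[tuple[str, str]]] = field(default_factory=dict)
    max_len: int = 0

    def add(self, synonym: str, entity_type: str, term_id: str) -> None:
        toks = _norm_tokens(synonym)
        if not toks:
            return
        if len(synonym) >= CASE_INSENSITIVE_MIN_LEN:
            key = tuple(t.lower() for t in toks)
            self.ci.setdefault(key, set()).add((entity_type, term_id))
        else:
            self.cs.setdefault(toks, set()).add((entity_type, term_id))
        self.max_len = max(self.max_len, len(toks))

    def lookup(self, tokens: Sequence[str]) -> set[tuple[str, str]]:
        """Hits for an exact token sequence (already hyphen-free)."""
        out: set[tuple[str, str]] = set()
        key = tuple(tokens)
        if key in self.cs:
            out |= self.cs[key]
        low = tuple(t.lower() for t in key)
        if low in self.ci:
            out |= self.ci[low]
        return out


@dataclass
class Lexicon:
    entries: list[TermEntry]
    stopwords: frozenset[str] = frozenset()
    matcher: Matcher | None = None

    def by_type(self, entity_type: str) -> list[TermEntry]:
        return [e for e in self.entries if e.entity_type == entity_type]

    def variant_group(self, term_id: str) -> str:
        """Controlled variant-group label for a variant term id."""
        return term_id


def _read_tsv(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
                )
            yield lineno, parts


def load_wordlist(
    paths: Iterable[str | Path],
    stopword_path: str | Path | None = None,
) -> Lexicon:
    """Load typed term lists and apply stopword filtering.

    Synonyms equal (case-insensitively) to a stopword are removed; entries
    left with no synonyms are dropped.  Duplicate term ids within an entity
    type and unknown entity types raise with the offending line number.
    """
    stopwords: frozenset[str] = frozenset()
    if stopword_path is not None:
        with open(stopword_path, encoding="utf-8") as fh:
            stopwords = frozenset(
                w.strip().lower() for w in fh if w.strip()
            )
    entries: list[TermEntry] = []
    seen: set[tuple[str, str]] = set()
    for path in paths:
        for lineno, (term_id, etype, canonical, syns) in _read_tsv(path):
            if etype not in ENTITY_TYPES:
                raise ValueError(
                    f"{path}:{lineno}: unknown entity_type {etype!r}"
                )
            if (etype, term_id) in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate term_id {term_id!r} for type {etype}"
                )
            seen.add((etype, term_id))
            synonyms = {s for s in syns.split("|") if s}
            synonyms.add(canonical)
            synonyms = {s for s in synonyms if s.lower() not in stopwords}
            if not synonyms:
                continue
            entries.append(
                TermEntry(term_id, etype, canonical, frozenset(synonyms))
            )
    return Lexicon(entries=entries, stopwords=stopwords)


def expand_inhibitors(
    lex: Lexicon, categories: Iterable[str] = ()
) -> Lexicon:
    """Add gene-derived inhibitor drug terms and general drug-category terms.

    For every gene synonym G, a drug entry matching "G inhibitor" and
    "G inhibitors" is added under the id ``inhibitor:<gene id>``.  Existing
    entries are never removed or altered.
    """
    new_entries = list(lex.entries)
    for gene in lex.by_type("gene"):
        syns = set()
        for g in sorted(gene.synonyms):
            syns.add(f"{g} inhibitor")
            syns.add(f"{g} inhibitors")
        new_entries.append(
            TermEntry(
                term_id=f"inhibitor:{gene.term_id}",
                entity_type="drug",
                canonical_name=f"{gene.canonical_name} inhibitor",
                synonyms=frozenset(syns),
            )
        )
    existing_drug_ids = {e.term_id for e in lex.by_type("drug")}
    for cat in categories:
        cat = cat.strip()
        if not cat:
            continue
        term_id = f"category:{cat.lower().replace(' ', '_')}"
        if term_id in existing_drug_ids:
            continue
        new_entries.append(
            TermEntry(
                term_id=term_id,
                entity_type="drug",
                canonical_name=cat,
                synonyms=frozenset({cat}),
            )
        )
    return Lexicon(entries=new_entries, stopwords=lex.stopwords)


def compile_matcher(
    lex: Lexicon,
    tokenizer: Callable[[str], list[tuple[str, int, int]]] = tokenize,
) -> Lexicon:
    """Compile synonyms into the token-sequence matcher (idempotent)."""
    # tokenizer parameter kept for contract symmetry with sentence
    # tokenization; _norm_tokens uses the shared package tokenizer.
    del tokenizer
    matcher = Matcher()
    for entry in lex.entries:
        for syn in entry.synonyms:
            matcher.add(syn, entry.entity_type, entry.term_id)
    return replace(lex, matcher=matcher)


def fixture_lexicon(
    expand: bool = False, with_categories: bool = True
) -> Lexicon:
    """The small curated lexicon shipped with the package, compiled.

    A stand-in for full ontology-derived term lists (Entrez genes, Disease
    Ontology cancers, WikiData drugs); drop in full TSVs with the same
    contract for production runs.
    """
    lex = load_wordlist(
        [
            _DATA_DIR / "genes.tsv",
            _DATA_DIR / "cancers.tsv",
            _DATA_DIR / "drugs.tsv",
            _DATA_DIR / "variants.tsv",
        ],
        stopword_path=_DATA_DIR / "stopwords.txt",
    )
    if expand:
        cats: list[str] = []
        if with_categories:
            with open(_DATA_DIR / "drug_categories.txt", encoding="utf-8") as fh:
                cats = [line.strip() for line in fh if line.strip()]
        lex = expand_inhibitors(lex, cats)
    return compile_matcher(lex)
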