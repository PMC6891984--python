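"""Corpus ingestion and sentence parsing.

Documents arrive either as BioC XML (collection/document/passage) or as a
JSON-lines dialect (one document per line).  Text is normalised (markup
stripped, character entities decoded), body sections are filtered against a
whitelist of canonical section headers, and each retained block is split into
:class:`ParsedSentence` objects by a pluggable parser.

The parser is a contract, not a dependency: anything that can turn a block of
text into sentences with token spans and a dependency tree will do.  Two
implementations ship with the package — :class:`SimpleParser`, a fast
heuristic tokenizer/splitter that emits a chain tree (sufficient for entity
tagging and triage), and :class:`TemplateParser`, which replays dependency
arcs stored alongside synthetic template sentences so the relation-feature
code can be exercised hermetically.  A real statistical dependency parser can
be plugged in by wrapping it in the same ``parse(text)`` interface.
"""

from __future__ import annotations

import html
import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Protocol, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "SectionBlock",
    "DocumentRecord",
    "ParsedSentence",
    "SentenceParse",
    "Parser",
    "SimpleParser",
    "TemplateParser",
    "CorpusFormatError",
    "normalize_text",
    "canonical_section_label",
    "default_section_synonyms",
    "default_section_whitelist",
    "filter_sections",
    "read_corpus",
    "write_corpus_jsonl",
    "parse_sentences",
    "tokenize",
]

_DATA_DIR = Path(__file__).parent / "data"

# Canonical body-section labels retained by default.
DEFAULT_WHITELIST = frozenset(
    {"introduction", "methods", "results", "discussion", "conclusion"}
)


class CorpusFormatError(ValueError):
    """Raised when an input corpus file cannot be interpreted."""


@dataclass(frozen=True)
class SectionBlock:
    """One labelled block of document text."""

    label: str          # canonical label ("introduction", ...) or "unknown"
    raw_label: str      # header as found in the source document
    text: str


@dataclass(frozen=True)
class DocumentRecord:
    """A document with metadata and ordered text sections.

    ``title`` and ``abstract`` are carried both as fields of convenience via
    ``sections`` (labels "title"/"abstract") so provenance of extracted
    sentences can distinguish title, abstract, and main-body text.
    """

    doc_id: str
    title: str = ""
    journal: str = ""
    year: int | None = None
    pmid: int | None = None
    sections: tuple[SectionBlock, ...] = ()

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if self.year is not None and self.year < 0:
            raise ValueError(f"document {self.doc_id}: year must be >= 0")


@dataclass
class ParsedSentence:
    """A tokenized sentence with a dependency tree and attached mentions.

    Token spans are 0-based half-open character offsets into ``text``.  Arcs
    are ``(head, dependent, label)`` triples over token indices; exactly one
    token has head ``-1`` (the root) and the arc set forms a tree.
    """

    text: str
    tokens: list[tuple[str, int, int]]
    arcs: list[tuple[int, int, str]]
    doc_id: str = ""
    section_label: str = ""
    mentions: list = field(default_factory=list)

    def validate(self) -> None:
        prev_end = 0
        for surf, s, e in self.tokens:
            if not (0 <= s < e <= len(self.text)):
                raise ValueError(f"token span ({s},{e}) out of bounds")
            if s < prev_end:
                raise ValueError("token spans overlap or are unordered")
            if self.text[s:e] != surf:
                raise ValueError(f"token {surf!r} does not match text at ({s},{e})")
            prev_end = e
        n = len(self.tokens)
        heads = {}
        roots = 0
        for h, d, _ in self.arcs:
            if d in heads:
                raise ValueError(f"token {d} has more than one head")
            heads[d] = h
            if h == -1:
                roots += 1
        if n and (roots != 1 or set(heads) != set(range(n))):
            raise ValueError("arc set is not a single-rooted spanning structure")
        # acyclicity / connectivity: every token must reach the root
        for d in range(n):
            seen = set()
            cur = d
            while cur != -1:
                if cur in seen:
                    raise ValueError("dependency arcs contain a cycle")
                seen.add(cur)
                cur = heads[cur]


# ---------------------------------------------------------------------------
# text normalisation and section handling
# ---------------------------------------------------------------------------

_TAG_RE = re.compile(r"</?[A-Za-z][^>]*?/?>")


def normalize_text(raw: str) -> str:
    """Strip markup tags and decode character entities.

    Tags are removed first and entities decoded second, so encoded markup
    such as ``&lt;br&gt;`` decodes to the literal text ``<br>`` and is *not*
    re-stripped.  All other characters are preserved.
    """
    return html.unescape(_TAG_RE.sub("", raw))


def default_section_synonyms() -> dict[str, str]:
    """Raw-header -> canonical-label table shipped with the package."""
    with open(_DATA_DIR / "section_synonyms.json", encoding="utf-8") as fh:
        return {k.lower(): v for k, v in json.load(fh).items()}


def default_section_whitelist() -> frozenset[str]:
    return DEFAULT_WHITELIST


def canonical_section_label(raw: str, synonyms: dict[str, str] | None = None) -> str:
    """Canonicalize a section header (case-insensitive); unknowns -> "unknown"."""
    if synonyms is None:
        synonyms = default_section_synonyms()
    key = raw.strip().lower().rstrip(":").strip()
    if key in synonyms:
        return synonyms[key]
    if key in DEFAULT_WHITELIST or key in {"title", "abstract"}:
        return key
    return "unknown"


def filter_sections(
    doc: DocumentRecord,
    whitelist: Iterable[str] = DEFAULT_WHITELIST,
    synonyms: dict[str, str] | None = None,
) -> DocumentRecord:
    """Keep title, abstract, and whitelisted body sections; drop the rest.

    Text content is never altered — blocks are only relabelled (to their
    canonical label) or removed.  Order is preserved.
    """
    if synonyms is None:
        synonyms = default_section_synonyms()
    allowed = set(whitelist)
    kept: list[SectionBlock] = []
    for sec in doc.sections:
        label = sec.label if sec.label != "unknown" else canonical_section_label(
            sec.raw_label, synonyms
        )
        if label in {"title", "abstract"}:
            kept.append(replace(sec, label=label))
        else:
            canon = canonical_section_label(sec.raw_label, synonyms)
            if canon in allowed:
                kept.append(replace(sec, label=canon))
    return replace(doc, sections=tuple(kept))


# ---------------------------------------------------------------------------
# corpus readers / writers
# ---------------------------------------------------------------------------

def _doc_from_json(obj: dict, index: int) -> DocumentRecord:
    try:
        sections = tuple(
            SectionBlock(
                label=s.get("label", "unknown"),
                raw_label=s.get("raw_label", s.get("label", "")),
                text=s["text"],
            )
            for s in obj.get("sections", [])
        )
        return DocumentRecord(
            doc_id=str(obj["doc_id"]),
            title=obj.get("title", ""),
            journal=obj.get("journal", ""),
            year=obj.get("year"),
            pmid=obj.get("pmid"),
            sections=sections,
        )
    except (KeyError, TypeError) as exc:
        raise CorpusFormatError(f"document {index}: malformed record ({exc})") from exc


def _read_jsonl(path: Path) -> Iterator[DocumentRecord]:
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"document {i}: invalid JSON ({exc})") from exc
            yield _doc_from_json(obj, i)


def _read_bioc(path: Path) -> Iterator[DocumentRecord]:
    """Stream a BioC XML collection.

    Passages carry a ``section`` infon used as the raw section label; the
    passages labelled title/abstract populate the corresponding metadata.
    """
    index = 0
    try:
        context = etree.iterparse(str(path), events=("end",), tag="document")
        for _, elem in context:
            doc_id = (elem.findtext("id") or "").strip()
            infons = {
                inf.get("key"): (inf.text or "")
                for inf in elem.findall("infon")
            }
            title = infons.get("title", "")
            sections: list[SectionBlock] = []
            for passage in elem.findall("passage"):
                pinfons = {
                    inf.get("key"): (inf.text or "")
                    for inf in passage.findall("infon")
                }
                raw_label = pinfons.get("section", "unknown")
                text = normalize_text(passage.findtext("text") or "")
                canon = canonical_section_label(raw_label)
                if canon == "title" and not title:
                    title = text
                sections.append(
                    SectionBlock(label=canon, raw_label=raw_label, text=text)
                )
            pmid = infons.get("pmid")
            year = infons.get("year")
            try:
                yield DocumentRecord(
                    doc_id=doc_id or f"doc{index}",
                    title=title,
                    journal=infons.get("journal", ""),
                    year=int(year) if year else None,
                    pmid=int(pmid) if pmid else None,
                    sections=tuple(sections),
                )
            except ValueError as exc:
                raise CorpusFormatError(f"document {index}: {exc}") from exc
            index += 1
            elem.clear()
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"document {index}: malformed XML ({exc})") from exc


def read_corpus(path: str | Path, format: str = "jsonl") -> Iterator[DocumentRecord]:
    """Yield one :class:`DocumentRecord` per document, streaming.

    ``format`` is ``"bioc-xml"`` or ``"jsonl"``.
    """
    path = Path(path)
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "bioc-xml":
        return _read_bioc(path)
    raise CorpusFormatError(f"unknown corpus format: {format!r}")


def write_corpus_jsonl(docs: Iterable[DocumentRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            obj = {
                "doc_id": doc.doc_id,
                "title": doc.title,
                "journal": doc.journal,
                "sections": [
                    {"label": s.label, "raw_label": s.raw_label, "text": s.text}
                    for s in doc.sections
                ],
            }
            if doc.year is not None:
                obj["year"] = doc.year
            if doc.pmid is not None:
                obj["pmid"] = doc.pmid
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# tokenization and the parser contract
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Split text into word/punctuation tokens with character spans.

    Every non-alphanumeric, non-space character becomes its own token, so
    hyphenated and slash-joined names ("BCR-ABL1", "HER2/neu") split into
    their parts plus the separator — the convention the entity matcher and
    fusion detector rely on.
    """
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


class SentenceParse(NamedTuple):
    """One sentence from a parsed block.

    ``start``/``end`` delimit the sentence within the block; token spans are
    relative to the sentence slice itself.
    """

    start: int
    end: int
    tokens: list[tuple[str, int, int]]     # offsets relative to the sentence
    arcs: list[tuple[int, int, str]]


class Parser(Protocol):
    def parse(self, text: str) -> list[SentenceParse]:
        """Split ``text`` into sentences with token spans and dependency arcs."""
        ...


_SENT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(\"'])")


class SimpleParser:
    """Heuristic sentence splitter + tokenizer emitting a left-headed chain tree.

    The chain tree (token i headed by token i-1, token 0 as root) satisfies
    the tree invariants and makes entity tagging and triage possible on
    arbitrary text without a model download.  Dependency-path features from a
    chain tree are surface-adjacency features; for linguistically meaningful
    paths plug in a real parser or use stored template arcs.
    """

    def parse(self, text: str) -> list[SentenceParse]:
        out: list[SentenceParse] = []
        pos = 0
        boundaries = [m.start() for m in _SENT_SPLIT_RE.finditer(text)] + [len(text)]
        for end in boundaries:
            chunk = text[pos:end]
            if chunk.strip():
                stripped_off = pos + (len(chunk) - len(chunk.lstrip()))
                sent_text = chunk.strip()
                toks = tokenize(sent_text)
                arcs = [(-1, 0, "root")] + [
                    (i - 1, i, "dep") for i in range(1, len(toks))
                ]
                if not toks:
                    arcs = []
                out.append(
                    SentenceParse(
                        start=stripped_off,
                        end=stripped_off + len(sent_text),
                        tokens=toks,
                        arcs=arcs,
                    )
                )
            pos = end
        return out


class TemplateParser:
    """Replays stored token spans and dependency arcs, keyed by sentence text.

    Built from the synthetic corpus' gold file (or any mapping), this parser
    makes the full pipeline — including dependency-path features — hermetic:
    parsing a known sentence returns exactly the arcs stored with it.
    """

    def __init__(
        self,
        table: dict[str, tuple[list[tuple[str, int, int]], list[tuple[int, int, str]]]],
    ) -> None:
        self._table = dict(table)

    def add(self, text, tokens, arcs) -> None:
        self._table[text] = (tokens, arcs)

    def parse(self, text: str) -> list[SentenceParse]:
        key = text.strip()
        if key not in self._table:
            raise ValueError(f"no stored parse for sentence: {key[:60]!r}...")
        tokens, arcs = self._table[key]
        off = text.find(key)
        return [
            SentenceParse(
                start=off,
                end=off + len(key),
                tokens=[(s, a, b) for s, a, b in tokens],
                arcs=[(h, d, l) for h, d, l in arcs],
            )
        ]


def parse_sentences(doc: DocumentRecord, parser: Parser) -> list[ParsedSentence]:
    """Parse every retained section of a document into sentences.

    A parser failure on one section is logged and skipped rather than
    aborting the document.
    """
    out: list[ParsedSentence] = []
    blocks: list[tuple[str, str]] = []
    labels_present = {s.label for s in doc.sections}
    if doc.title and "title" not in labels_present:
        blocks.append(("title", doc.title))
    blocks.extend((s.label, s.text) for s in doc.sections)
    for label, text in blocks:
        if not text.strip():
            continue
        try:
            parses = parser.parse(text)
        except Exception as exc:  # noqa: BLE001 - contract: skip, don't crash
            logger.warning(
                "parser failed on %s/%s: %s", doc.doc_id, label, exc
            )
            continue
        for sp in parses:
            sent = ParsedSentence(
                text=text[sp.start : sp.end],
                tokens=sp.tokens,
                arcs=sp.arcs,
                doc_id=doc.doc_id,
                section_label=label,
            )
            sent.validate()
            out.append(sent)
    return out
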