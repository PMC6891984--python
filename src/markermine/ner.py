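"""Dictionary-based entity recognition with biomarker-specific post-processing.

The tagging pipeline, in order:

1. greedy longest-match dictionary tagging per entity type (a longer span
   suppresses shorter overlapping matches of the same type; spans of
   *different* types may coincide — "retinoblastoma" is both a gene and a
   cancer);
2. a regular expression for protein-coding point mutations (V600E, T315I);
3. gene-fusion detection for gene pairs joined by ``/``, ``-`` or ``:``
   (BCR-ABL1 becomes a fusion mention; HER2/neu collapses to ERBB2);
4. acronym resolution for parenthesized short forms via a backward
   letter-alignment scan over the preceding long form;
5. removal of pathway-like gene mentions ("MTOR signaling");
6. merging of adjacent same-type mentions whose identifiers agree
   ("HER2 neu" -> one ERBB2 mention).

The order matters: fusions must form before acronym resolution or adjacent
merging can touch their parts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import ParsedSentence
from .lexicon import ENTITY_TYPES, Lexicon

__all__ = [
    "EntityMention",
    "match_terms",
    "match_point_mutations",
    "detect_fusions",
    "resolve_acronyms",
    "postprocess_mentions",
    "tag_sentence",
    "default_point_mutation_blocklist",
    "POINT_MUTATION_RE",
]

_DATA_DIR = Path(__file__).parent / "data"

# One-letter amino-acid codes at both ends, a position in between.
POINT_MUTATION_RE = re.compile(
    r"[ACDEFGHIKLMNPQRSTVWY][0-9]+[ACDEFGHIKLMNPQRSTVWY]"
)

PATHWAY_TRIGGERS = frozenset(
    {"signaling", "signalling", "pathway", "cascade", "axis"}
)

FUSION_SEPARATORS = frozenset({"/", "-", ":"})


@dataclass(frozen=True)
class EntityMention:
    """A typed span in one sentence carrying ontology identifiers."""

    entity_type: str
    term_ids: frozenset[str]
    token_span: tuple[int, int]      # [start, end) token indices
    char_span: tuple[int, int]       # [start, end) character offsets
    text: str
    is_fusion: bool = False
    variant_group: str | None = None

    def __post_init__(self) -> None:
        if self.token_span[1] <= self.token_span[0]:
            raise ValueError("empty token span")
        if not self.term_ids:
            raise ValueError("mention must carry at least one term id")
        if self.is_fusion and (self.entity_type != "gene" or len(self.term_ids) < 2):
            raise ValueError("fusion mentions are gene mentions with >= 2 ids")

    def overlaps(self, other: "EntityMention") -> bool:
        a, b = self.char_span, other.char_span
        return a[0] < b[1] and b[0] < a[1]


def default_point_mutation_blocklist() -> frozenset[str]:
    """Tokens never treated as point mutations (e.g. cell-line codes)."""
    with open(_DATA_DIR / "point_mutation_blocklist.txt", encoding="utf-8") as fh:
        return frozenset(w.strip() for w in fh if w.strip())


def _mention_from_tokens(
    sent: ParsedSentence,
    entity_type: str,
    term_ids: Iterable[str],
    tok_start: int,
    tok_end: int,
    **kw,
) -> EntityMention:
    c0 = sent.tokens[tok_start][1]
    c1 = sent.tokens[tok_end - 1][2]
    return EntityMention(
        entity_type=entity_type,
        term_ids=frozenset(term_ids),
        token_span=(tok_start, tok_end),
        char_span=(c0, c1),
        text=sent.text[c0:c1],
        **kw,
    )


# ---------------------------------------------------------------------------
# 1. dictionary matching
# ---------------------------------------------------------------------------

def match_terms(sent: ParsedSentence, lex: Lexicon) -> list[EntityMention]:
    """Greedy longest-match dictionary tagging, each entity type independently."""
    if lex.matcher is None:
        raise ValueError("lexicon matcher not compiled; call compile_matcher first")
    matcher = lex.matcher
    # comparison view: token surfaces with hyphen tokens skipped, keeping a
    # map back to original token indices
    norm: list[tuple[str, int]] = [
        (surf, i) for i, (surf, _, _) in enumerate(sent.tokens) if surf != "-"
    ]
    mentions: list[EntityMention] = []
    for etype in ENTITY_TYPES:
        i = 0
        while i < len(norm):
            best = None
            max_l = min(matcher.max_len, len(norm) - i)
            for length in range(max_l, 0, -1):
                seq = [norm[i + k][0] for k in range(length)]
                hits = {
                    tid for (t, tid) in matcher.lookup(seq) if t == etype
                }
                if hits:
                    best = (length, hits)
                    break
            if best is None:
                i += 1
                continue
            length, hits = best
            tok_start = norm[i][1]
            tok_end = norm[i + length - 1][1] + 1
            group = None
            if etype == "variant":
                group = lex.variant_group(sorted(hits)[0])
            mentions.append(
                _mention_from_tokens(
                    sent, etype, hits, tok_start, tok_end, variant_group=group
                )
            )
            i += length
    return mentions


# ---------------------------------------------------------------------------
# 2. point-mutation regex
# ---------------------------------------------------------------------------

def match_point_mutations(
    sent: ParsedSentence, blocklist: frozenset[str] | None = None
) -> list[EntityMention]:
    """Single tokens shaped like protein substitutions become variant mentions."""
    if blocklist is None:
        blocklist = default_point_mutation_blocklist()
    out: list[EntityMention] = []
    for i, (surf, _, _) in enumerate(sent.tokens):
        if surf in blocklist:
            continue
        if POINT_MUTATION_RE.fullmatch(surf):
            out.append(
                _mention_from_tokens(
                    sent,
                    "variant",
                    {surf.upper()},
                    i,
                    i + 1,
                    variant_group="substitution",
                )
            )
    return out


def _dedupe_same_type_overlaps(
    mentions: list[EntityMention],
) -> list[EntityMention]:
    """Keep at most one mention per overlapping same-type cluster (longest wins)."""
    kept: list[EntityMention] = []
    for m in sorted(
        mentions,
        key=lambda m: (-(m.char_span[1] - m.char_span[0]), m.char_span[0]),
    ):
        if any(
            k.entity_type == m.entity_type and k.overlaps(m) for k in kept
        ):
            continue
        kept.append(m)
    kept.sort(key=lambda m: (m.char_span[0], m.entity_type))
    return kept


# ---------------------------------------------------------------------------
# 3. fusion detection
# ---------------------------------------------------------------------------

def detect_fusions(
    mentions: list[EntityMention], sent: ParsedSentence
) -> list[EntityMention]:
    """Join gene mentions separated by exactly one of ``/ - :``.

    Overlapping id sets mean both names refer to the same gene (HER2/neu ->
    ERBB2): the pair merges into an ordinary mention carrying the
    intersection.  Disjoint sets flag a fusion (BCR-ABL1): one mention with
    ``is_fusion=True`` carrying the union.  The separator must sit directly
    between the two gene spans with no intervening whitespace.
    """
    genes = sorted(
        (m for m in mentions if m.entity_type == "gene"),
        key=lambda m: m.token_span[0],
    )
    others = [m for m in mentions if m.entity_type != "gene"]
    changed = True
    while changed:
        changed = False
        for i in range(len(genes) - 1):
            m1, m2 = genes[i], genes[i + 1]
            sep_idx = m1.token_span[1]
            if sep_idx + 1 != m2.token_span[0]:
                continue
            sep_surf, sep_s, sep_e = sent.tokens[sep_idx]
            if sep_surf not in FUSION_SEPARATORS:
                continue
            # tight joins only: no whitespace on either side of the separator
            if m1.char_span[1] != sep_s or sep_e != m2.char_span[0]:
                continue
            common = m1.term_ids & m2.term_ids
            if common:
                merged = _mention_from_tokens(
                    sent, "gene", common, m1.token_span[0], m2.token_span[1]
                )
            else:
                merged = _mention_from_tokens(
                    sent,
                    "gene",
                    m1.term_ids | m2.term_ids,
                    m1.token_span[0],
                    m2.token_span[1],
                    is_fusion=True,
                )
            genes[i : i + 2] = [merged]
            changed = True
            break
    out = others + genes
    out.sort(key=lambda m: (m.char_span[0], m.entity_type))
    return out


# ---------------------------------------------------------------------------
# 4. acronym resolution
# ---------------------------------------------------------------------------

def _find_long_form(short: str, long_text: str) -> int | None:
    """Backward letter-alignment scan; returns the long-form start offset.

    Each character of the short form (last to first) must appear, in order,
    scanning backward through the text before the parenthesis; the first
    short-form character must start a word.
    """
    s_idx = len(short) - 1
    l_idx = len(long_text) - 1
    while s_idx >= 0:
        c = short[s_idx].lower()
        if not c.isalnum():
            s_idx -= 1
            continue
        while l_idx >= 0:
            lc = long_text[l_idx].lower()
            if lc == c and not (
                s_idx == 0 and l_idx > 0 and long_text[l_idx - 1].isalnum()
            ):
                break
            l_idx -= 1
        if l_idx < 0:
            return None
        l_idx -= 1
        s_idx -= 1
    return l_idx + 1


def resolve_acronyms(
    mentions: list[EntityMention], sent: ParsedSentence
) -> list[EntityMention]:
    """Reconcile parenthesized short forms with their preceding long forms.

    For each aligned (long form, short form) pair: overlapping ids on both
    sides -> keep one mention (the long form); ids on one side only -> the
    other side inherits them; disjoint ids on both sides -> the short form
    is discarded as less trustworthy.
    """
    toks = sent.tokens
    mentions = list(mentions)
    for p in range(len(toks) - 2):
        if toks[p][0] != "(" or toks[p + 2][0] != ")":
            continue
        sf_surf, sf_s, sf_e = toks[p + 1]
        if not (2 <= len(sf_surf) <= 10) or not any(c.isalpha() for c in sf_surf):
            continue
        paren_char = toks[p][1]
        lf_start = _find_long_form(sf_surf, sent.text[:paren_char])
        if lf_start is None:
            continue
        lf_end = paren_char
        while lf_end > lf_start and sent.text[lf_end - 1].isspace():
            lf_end -= 1
        lf_words = len(sent.text[lf_start:lf_end].split())
        if lf_words == 0 or lf_words > min(len(sf_surf) + 5, len(sf_surf) * 2):
            continue
        lf_tok_idx = [
            i for i, (_, a, b) in enumerate(toks) if a >= lf_start and b <= lf_end
        ]
        if not lf_tok_idx:
            continue
        lf_range = (lf_tok_idx[0], lf_tok_idx[-1] + 1)

        long_ms = [
            m
            for m in mentions
            if lf_range[0] <= m.token_span[0] and m.token_span[1] <= lf_range[1]
        ]
        short_ms = [
            m
            for m in mentions
            if m.token_span[0] <= p + 1 < m.token_span[1]
        ]
        if not long_ms and not short_ms:
            continue
        paired = [
            (lm, sm)
            for lm in long_ms
            for sm in short_ms
            if lm.term_ids & sm.term_ids
        ]
        if paired:
            # same concept on both sides: keep the long form only
            lm, sm = paired[0]
            merged = replace(lm, term_ids=frozenset(lm.term_ids & sm.term_ids))
            mentions = [m for m in mentions if m not in (lm, sm)] + [merged]
        elif long_ms and short_ms:
            # conflicting identities: drop the short form
            mentions = [m for m in mentions if m not in short_ms]
        elif long_ms:
            # short form not in the lexicon: inherit the long form's identity
            lm = long_ms[0]
            mentions.append(
                _mention_from_tokens(
                    sent,
                    lm.entity_type,
                    lm.term_ids,
                    p + 1,
                    p + 2,
                    variant_group=lm.variant_group,
                )
            )
        else:
            # long form not in the lexicon: project the short form onto it
            sm = short_ms[0]
            mentions.append(
                _mention_from_tokens(
                    sent,
                    sm.entity_type,
                    sm.term_ids,
                    lf_range[0],
                    lf_range[1],
                    variant_group=sm.variant_group,
                )
            )
    mentions.sort(key=lambda m: (m.char_span[0], m.entity_type))
    return mentions


# ---------------------------------------------------------------------------
# 5 + 6. pathway suppression and adjacent merging
# ---------------------------------------------------------------------------

def postprocess_mentions(
    mentions: list[EntityMention], sent: ParsedSentence
) -> list[EntityMention]:
    # (a) pathway-like gene mentions
    kept = []
    for m in mentions:
        if m.entity_type == "gene" and m.token_span[1] < len(sent.tokens):
            nxt = sent.tokens[m.token_span[1]][0].lower()
            if nxt in PATHWAY_TRIGGERS:
                continue
        kept.append(m)
    # (b) adjacent same-type mentions with agreeing ids, whitespace-separated
    changed = True
    while changed:
        changed = False
        kept.sort(key=lambda m: (m.char_span[0], m.entity_type))
        for i, m1 in enumerate(kept):
            for m2 in kept[i + 1 :]:
                if m2.entity_type != m1.entity_type:
                    continue
                if m1.token_span[1] != m2.token_span[0]:
                    continue
                gap = sent.text[m1.char_span[1] : m2.char_span[0]]
                if gap.strip():
                    continue
                common = m1.term_ids & m2.term_ids
                if not common:
                    continue
                merged = _mention_from_tokens(
                    sent,
                    m1.entity_type,
                    common,
                    m1.token_span[0],
                    m2.token_span[1],
                    is_fusion=m1.is_fusion and m2.is_fusion and len(common) >= 2,
                    variant_group=m1.variant_group,
                )
                kept = [m for m in kept if m not in (m1, m2)] + [merged]
                changed = True
                break
            if changed:
                break
    kept.sort(key=lambda m: (m.char_span[0], m.entity_type))
    return kept


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def tag_sentence(
    sent: ParsedSentence,
    lex: Lexicon,
    blocklist: frozenset[str] | None = None,
) -> ParsedSentence:
    """Run the full NER pipeline and attach mentions to the sentence."""
    mentions = match_terms(sent, lex) + match_point_mutations(sent, blocklist)
    mentions = _dedupe_same_type_overlaps(mentions)
    mentions = detect_fusions(mentions, sent)
    mentions = resolve_acronyms(mentions, sent)
    mentions = postprocess_mentions(mentions, sent)
    sent.mentions = mentions
    return sent
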