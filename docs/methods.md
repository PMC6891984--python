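# Methods

This note documents the models and procedures implemented in `markermine`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the shipped tests demonstrate.

## Problem setting

The unit of extraction is the single sentence.  A sentence may assert that
a gene (possibly qualified by a specific variant) is clinically linked to a
cancer type under one of four evidence types — diagnostic, predictive
(drug response), predisposing (germline risk) or prognostic — and the goal
is to recover these assertions as structured tuples with literature
provenance, at high precision, so that a human curator reviewing a
citation-ranked table spends little time on false positives.  Assertions
spread across sentence boundaries (coreference, tables, figure captions)
are out of reach by construction; this is the dominant source of missed
evidence and is shared by essentially all sentence-level extraction
systems.

## Corpus handling

Documents are normalised by stripping markup tags first and decoding
character entities second, so encoded markup (`&lt;br&gt;`) survives as
literal text and is never re-stripped.  Body sections are kept only when
their header canonicalizes (case-insensitively, through a shipped,
replaceable synonym table) into a whitelist: introduction, methods,
results, discussion, conclusion.  Title and abstract blocks are always
retained, because provenance distinguishes title / abstract / main-body
mentions.  All character offsets in the package are 0-based half-open.

Sentence splitting, tokenization and dependency parsing sit behind a
minimal contract (`parse(text) -> sentences with token spans and arcs`).
Two implementations ship: a heuristic splitter emitting a left-headed
chain tree (adequate for tagging and triage; its "dependency paths" are
surface adjacency), and a replay parser that returns dependency trees
stored with synthetic template sentences.  A statistical parser (e.g. a
spaCy pipeline) can be wrapped in the same contract for production runs;
nothing else in the package changes.

## Lexicon and entity recognition

Term lists are consumed as typed TSVs and compiled to a token-sequence
index.  Two matching conventions, chosen here because the underlying
sources do not fix them:

* synonyms of ≥ 4 characters match case-insensitively; shorter synonyms
  match case-sensitively.  Rationale: 2–3 letter gene symbols ("ICE",
  "neu") collide with ordinary words far beyond what a stopword list
  covers, while longer names are orthographically stable under casing.
* token sequences are compared with hyphen tokens removed, so
  "non-small cell" ≡ "non small cell".

Stopword filtering removes synonyms equal to a stopword (case-insensitive)
and drops entries left empty; the operation is idempotent.  Gene-derived
inhibitor terms ("EGFR inhibitor(s)") are generated as drug entries from
every gene synonym, plus configurable drug-category terms (chemotherapy,
tyrosine kinase inhibitor, …).

Tagging runs, in order: longest-match dictionary tagging per entity type
(a longer span suppresses overlapping shorter ones of the same type; spans
of different types may coincide — "retinoblastoma" is both a gene and a
cancer); the point-mutation regex
`[ACDEFGHIKLMNPQRSTVWY][0-9]+[ACDEFGHIKLMNPQRSTVWY]` on whole tokens, with
a configurable blocklist for lookalikes such as cell-line codes (T47D);
fusion detection for gene mentions joined tightly by `/ - :` (identifier
overlap ⇒ same gene, merged; disjoint ⇒ fusion mention carrying the id
union); acronym resolution via a backward letter-alignment scan from the
parenthesized short form into the preceding long form (shared ids ⇒ keep
the long form; ids on one side only ⇒ the other side inherits them;
conflicting ids ⇒ drop the short form); pathway-mention suppression (gene
followed by signaling/signalling/pathway/cascade/axis); and merging of
directly adjacent same-type mentions with agreeing ids.  The order is a
design choice: fusions must exist before acronym resolution or adjacent
merging can touch their parts.  Three-letter amino-acid substitution codes
(Val600Glu) are not matched; extending the token regex would be the
natural place.

The shipped fixture lexicon is a small curated stand-in (16 genes, 13
cancers, 10 drugs, 6 variant groups) used by tests and the synthetic
generator.  Its generic-variant entry deliberately carries the surface
forms `mutations | variant | variants` and not the bare singular
"mutation": in sentences pairing a specific substitution with an
appositive "…mutation" ("V617F is the most common mutation…") the
singular form is a description of the substitution already captured, not
an additional variant mention, and excluding it keeps the variant column
clean.  Production lexicons supply their own policy.

## Triage

A sentence is a candidate when it has ≥ 1 gene, ≥ 1 cancer and ≥ 1 variant
mention (a drug is not required; only predictive assertions involve one).
Keyword enrichment assigns sentences to five stem groups — general
(marker), diagnostic (diagnostic), predictive (sensitiv, resistance,
efficacy, predict), predisposing (risk, predispos), prognostic (survival,
prognos, DFS).  Stems match as case-insensitive substrings anywhere in the
sentence, so "sensitiv" catches sensitive/sensitivity; all-uppercase stems
(DFS) match as standalone tokens, case-sensitively, to avoid firing inside
ordinary words.  Keyword matching runs on the raw sentence text after full
NER, a choice that matters only if tagging were to rewrite text (it does
not).

Annotation sampling draws an equal number of sentences per group
(multi-group sentences are eligible everywhere but consumed once), with
half of each group's draw (rounded down) taken from sentences containing a
specific point mutation, and excludes sentences with more than five
biomarker-task candidates (gene–cancer pairs plus cancer–drug–gene
triples), since candidate-dense sentences are disproportionately
error-prone and expensive to annotate.  Sampling is deterministic under a
seed.

## Relation model

Candidates for a template of arity *n* are all ordered *n*-tuples of
pairwise non-overlapping mentions whose entity-type sequence equals the
template's slots — (cancer, gene) for diagnostic / predisposing /
prognostic, (cancer, drug, gene) for predictive, (gene, variant) for the
associated-variant relation.  Non-overlap excludes tuples pairing two
annotations of the same span.  Without a type filter a sentence with five
mentions yields 5·4·3 = 60 arity-3 candidates; with typing, two genes and
two cancers yield exactly the four gene–cancer pairs.  (For a sentence
with two genes and three variants the ordered gene–variant pairing yields
six combinations; a published description of the same setup states four,
which we read as a printed inconsistency and do not reproduce.)

Each candidate is vectorized with four sparse feature families:

1. sentence bag-of-words (lowercased);
2. per-slot mention-token unigrams, namespaced by slot index;
3. dependency-edge labels on the minimal subtree of the (undirected)
   dependency tree connecting the mention head tokens — the union of
   pairwise tree paths, unique for a tree;
4. surface words of subtree tokens outside the candidate's mentions.

A mention's head token is its token with minimal arc distance to the root,
ties broken rightmost (head-final English noun phrases).  A disconnected
arc graph is a contract violation and raises.

Per template, a logistic regression (L2, C = 1.0, balanced class weights,
liblinear, fixed random state) is fitted on candidates labelled by exact
span-tuple match against the gold standard — no partial credit, since a
near-miss tuple asserts a different biomarker.  Training errors out if a
template has no positive example.  Templates are scored independently; a
gene–cancer pair may legitimately be both diagnostic and prognostic in one
sentence.  Models serialize to a self-describing JSON archive (vocabulary,
coefficients, intercept, thresholds, feature-config tag); reloading
reproduces predictions bit-for-bit.

At prediction time the four evidence templates are scored and thresholded
first, then associated-variant relations; each accepted variant relation
is attached to every accepted evidence relation in the sentence whose gene
mention shares identifiers, producing one evidence item per (evidence,
variant) pair, and `[unknown]` when no variant attaches.  Default
thresholds (AssociatedVariant 0.70, Diagnostic 0.63, Predictive 0.93,
Predisposing 0.86, Prognostic 0.65) encode a high-precision/low-recall
operating point: frequently discussed biomarkers surface in many sentences,
so lost recall on any one sentence is recovered elsewhere, while false
positives directly waste curator time.

## Evaluation and threshold selection

Because annotation sentences are drawn equally from keyword groups rather
than randomly, test metrics are group-weighted: each candidate contributes
weight (population share of its group) / (sample share of its group) to
the confusion matrix, making precision/recall estimates representative of
randomly selected literature sentences.  The weight scale cancels in the
metrics; weights are reported as share ratios (identical proportions give
weight 1).  A candidate in several groups takes the weight of the group it
was sampled under.  0/0 ratios are 0 by convention.

Precision-recall curves are evaluated at every distinct score.  The
selected threshold is the one reaching the target precision (0.9 for
evidence types, 0.94 for the variant relation, which acts as a qualifier
on already-accepted evidence) with maximal recall; ties on recall resolve
to the *strictest* threshold, because any threshold inside a separating
gap is indistinguishable on calibration data and the highest one keeps the
most precision headroom on new data.  If no threshold reaches the target,
the closest precision wins (ties again favouring recall).

Inter-annotator agreement between two accepted-relation sets is F1
(2·TP / (2·TP + FP + FN)), symmetric in the annotators.  Three-annotator
merging accepts a candidate on ≥ 2 votes; relations annotated under the
merged predictive/prognostic class split on the drug slot (with drug ⇒
predictive, without ⇒ prognostic), and a prognostic relation sharing gene
and cancer with a predictive relation in the same sentence is then removed
as redundant.  Train/test splitting is a deterministic stratified 75/25
split preserving evidence-type proportions.

## Knowledgebase collation

Evidence items group by (evidence type, gene-id set, cancer-id set,
drug-id set, variant group); fusion mentions key on their sorted id set.
Variant group is part of record identity, so "EGFR mutation" and an
EGFR substitution are distinct rows, mirroring the variant column a
curator filters on.  Citation count is the number of distinct documents;
records sort by citation count with a fixed lexicographic tie-break, so
export is bit-stable.  CIViC matching compares evidence type, gene id,
disease id and — for predictive records — the drug name case-insensitively
with surrounding whitespace ignored; no fuzzy matching, so drug-family
vs specific-drug mismatches surface as unmatched rather than being
silently resolved.  The exact variant is deliberately ignored when
matching, so that any biomarker of a curated gene/disease/type lines up.
Substitution records can be labelled somatic / germline-common / both /
unlabelled by membership lookup in user-supplied (gene, substitution)
sets, e.g. derived from COSMIC somatic annotations and >1%-frequency
dbSNP entries.

## Synthetic corpus

The generator fabricates annotated corpora from fourteen hand-written
sentence templates: two per evidence type, two variant-only, four
negatives.  Templates store a dependency tree over template items; filled
multi-token names hang their leading tokens off their final token, which
carries the item's arc — so every generated sentence has a valid tree
replayed verbatim by the fixture parser, and the feature extractor is
exercised without a live parser.  Placeholders are filled by seeded
sampling from the fixture lexicon (genes, cancers, drugs, and ten
protein substitutions); negatives still contain a gene, a cancer and a
variant term plus enrichment keywords, and several positive templates
carry distractor genes or drugs so negative candidates exist inside
positive sentences.  The default configuration generates 100 sentences
per category (600 total), giving a positive-candidate fraction in the
trainable 0.2–0.8 band and, after a stratified split, the 400-train /
200-test setup used by the reproduction script — sized so the whole
suite runs in seconds on one core.

What passing on this corpus shows: the candidate machinery, feature
extraction, training, thresholding and collation are wired correctly, and
the learning setup can recover planted relations, including separating
positives from in-sentence distractor negatives that share the full
bag-of-words and differ only in dependency structure.  What it does not
show: robustness to real linguistic variety.  The templates are far more
separable than PubMed prose — per-template F1 of 1.0 here says nothing
about F1 on real abstracts, where realistic figures for this task are far
lower and the precision/recall trade-off is the whole point of per-type
thresholds.

## Known limitations

* Single-sentence scope; no coreference or cross-sentence assembly.
* No directionality (sensitivity vs resistance), germline/somatic status,
  or evidence-level fields; these are left to the curator.
* Dictionary NER only; no statistical normalisation, so recall is bounded
  by lexicon coverage (mitigated in practice by high-recall lexicons, with
  the relation classifier filtering false matches in context).
* Single-gene biomarkers only; multi-gene signatures and compound
  variants are not modelled.
* The chain-tree fallback parser makes dependency features degenerate to
  adjacency; meaningful path features require a real parser or stored
  trees.
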