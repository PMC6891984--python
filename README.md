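# markermine

Text-mining of clinically relevant cancer biomarkers from biomedical
literature, for knowledgebase curators and precision-oncology analysts.

Curated resources such as [CIViC](https://civicdb.org) collect *evidence
items*: structured assertions that a gene (and, where identifiable, a
specific variant) is linked to a cancer type — and, for drug-response
markers, to a drug — under one of four clinical evidence types:

| evidence type | meaning | relation slots |
|---|---|---|
| Diagnostic | the variant helps diagnose or exclude a cancer | (cancer, gene) |
| Predictive | the variant predicts drug sensitivity or resistance | (cancer, drug, gene) |
| Predisposing | a germline variant raises the risk of developing a cancer | (cancer, gene) |
| Prognostic | the variant predicts survival outcome | (cancer, gene) |

Manual curation of these assertions from the literature is the bottleneck.
`markermine` implements a sentence-level extraction pipeline that triages
the literature and proposes candidate evidence items ranked by how many
distinct papers support them:

1. **Corpus ingestion** — BioC XML or JSON-lines documents; markup
   stripped, entities decoded, body sections filtered against a canonical
   section-header whitelist; sentence splitting / tokenization /
   dependency parsing behind a pluggable parser contract.
2. **Entity recognition** — greedy longest-match dictionary tagging of
   genes, cancer types, drugs and variant terms from TSV term lists, plus a
   point-mutation regular expression (`V600E`), gene-fusion detection
   (`BCR-ABL1`), parenthesized-acronym resolution (`…lung carcinoma
   (NSCLC)`), pathway-mention suppression (`MTOR signaling`) and
   adjacent-mention merging (`HER2 neu`).
3. **Sentence triage** — keep sentences with ≥1 gene, ≥1 cancer and ≥1
   variant; enrich with five keyword groups (marker / diagnostic /
   sensitiv, resistance, efficacy, predict / risk, predispos / survival,
   prognos, DFS); draw balanced annotation samples.
4. **Relation extraction** — for each relation template, every ordered
   tuple of non-overlapping mentions with the right type signature is a
   candidate; candidates are vectorized (sentence bag-of-words, per-slot
   mention unigrams, dependency-edge labels and interior words of the
   minimal dependency subtree connecting the mention heads) and scored by
   a per-template logistic regression.  Scores are thresholded per
   template — default thresholds (AssociatedVariant 0.70, Diagnostic 0.63,
   Predictive 0.93, Predisposing 0.86, Prognostic 0.65) favour precision
   (~0.9) over recall.  Accepted gene–variant relations are attached to
   accepted evidence relations sharing the gene; evidence without a
   variant is flagged `[unknown]`.
5. **Knowledgebase collation** — evidence items grouped into biomarker
   records, ranked by distinct-paper citation count, optionally matched
   against a CIViC export and labelled somatic / germline-common from
   user-supplied variant sets, exported as TSV.

The classifiers follow scikit-learn conventions (`fit` / `predict`,
`get_params`, fitted attributes with trailing underscores), so they compose
with sklearn model selection.  A deterministic synthetic-corpus generator
(`markermine.synthetic`) fabricates annotated corpora — template sentences
with known entity spans, stored dependency trees and gold relations of all
five types plus negatives — so the entire pipeline is testable offline.

## Worked example

Tagging one sentence with the shipped fixture lexicon:

```python
from markermine import fixture_lexicon, tag_sentence
from markermine.corpus import DocumentRecord, SectionBlock, SimpleParser, parse_sentences

lex = fixture_lexicon()
text = ("In non-small cell lung cancer (NSCLC) driver mutations of EGFR are "
        "positive predictive biomarkers for efficacy of erlotinib and gefitinib.")
doc = DocumentRecord(doc_id="ex", sections=(SectionBlock("abstract", "abstract", text),))
(sent,) = parse_sentences(doc, SimpleParser())
tag_sentence(sent, lex)
for m in sent.mentions:
    print(f"{m.entity_type:8s} {m.text:30s} {','.join(sorted(m.term_ids))}")
```

prints

```
cancer   non-small cell lung cancer     DOID:3908
variant  mutations                      mutation
gene     EGFR                           1956
drug     erlotinib                      Q418369
drug     gefitinib                      Q417169
```

— the acronym `(NSCLC)` has been merged into the long-form cancer mention,
and the sentence carries the gene, variant term, cancer and both drugs an
extraction needs.  Training and evaluating the relation classifiers on a
seeded synthetic corpus (600 sentences, stratified 400/200 split):

```python
from markermine.synthetic import GeneratorConfig, generate_corpus
from markermine.pipeline import tag_gold_corpus, split_corpus, train_extractor, evaluate_per_template

corpus = generate_corpus(GeneratorConfig(seed=1))
sentences, gold = tag_gold_corpus(corpus)
train, test = split_corpus(corpus, sentences, gold, test_size=1/3, seed=1)
model = train_extractor(train[0], train[1], random_state=1)
for name, (p, r, f1) in evaluate_per_template(model, test[0], test[1], 0.5).items():
    print(f"{name:18s} P={p:.3f} R={r:.3f} F1={f1:.3f}")
```

prints

```
Diagnostic         P=1.000 R=1.000 F1=1.000
Predictive         P=1.000 R=1.000 F1=1.000
Predisposing       P=1.000 R=1.000 F1=1.000
Prognostic         P=1.000 R=1.000 F1=1.000
AssociatedVariant  P=1.000 R=1.000 F1=1.000
```

(the synthetic templates are deliberately separable; see
`docs/methods.md` for what this does and does not demonstrate).
`model.predict(sentences, docs=...)` then yields evidence items such as
`Diagnostic JAK2 / chronic myeloid leukemia / V617F, p=0.99`, and
`markermine.kb.collate` + `export_kb` turn them into the citation-ranked
`biomarkers.tsv` / `sentences.tsv` tables.

The same flow is available from the shell:

```bash
markermine simulate --seed 3 --out-dir corpus/        # synthetic corpus + gold + lexicon
markermine tag --corpus corpus/corpus.jsonl --out mentions.tsv
markermine pipeline --seed 3 --out-dir run/           # simulate→tag→train→predict→export
markermine kb-build --relations evidence.tsv --out-dir kb/ --civic civic.tsv
```

## Input formats

* **Corpus JSON-lines** — one document per line:
  `{"doc_id", "pmid", "title", "journal", "year", "sections": [{"label", "text"}]}`
  (`pmid`/`year` optional).  BioC XML collections are also read
  (`--format bioc-xml`), with the passage `section` infon as the raw
  section label.
* **Term lists** — `term_id<TAB>entity_type<TAB>canonical_name<TAB>syn1|syn2|…`
  (UTF-8, `#` comments).  The shipped fixture lists are small curated
  stand-ins; drop in full Entrez / Disease Ontology / WikiData-derived
  lists with the same contract for production runs.
* **Stopwords** — one lowercase term per line; term-list synonyms
  colliding with a stopword (e.g. the gene alias "ICE") are removed.
* **CIViC export** — TSV with columns `evidence_type, entrez_id, doid, drug`.

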