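"""Collation of evidence items into a citation-ranked biomarker table.

Evidence items are grouped by (evidence type, gene, cancer, drug, variant
group); each record counts the distinct papers supporting it and carries
every supporting sentence.  Records can be flagged against a CIViC-style
export (matching on evidence type, gene and disease identifiers and — for
predictive biomarkers — case-insensitive drug-name equality, ignoring the
exact variant) and point-mutation records can be labelled somatic or
germline-common against user-supplied variant sets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .relations import EvidenceItem, UNKNOWN_VARIANT

__all__ = [
    "BiomarkerRecord",
    "CivicEntry",
    "collate",
    "match_civic",
    "read_civic_tsv",
    "classify_origin",
    "read_variant_set",
    "export_kb",
]

EVIDENCE_TYPES = ("Diagnostic", "Predictive", "Predisposing", "Prognostic")

BIOMARKER_COLUMNS = [
    "record_id",
    "evidence_type",
    "gene_id",
    "gene_name",
    "cancer_id",
    "cancer_name",
    "drug_id",
    "drug_name",
    "variant_group",
    "variant_text",
    "citation_count",
    "in_civic",
]

SENTENCE_COLUMNS = [
    "record_id",
    "doc_id",
    "pmid",
    "year",
    "journal",
    "section_label",
    "sentence_text",
]


@dataclass
class BiomarkerRecord:
    record_id: int
    evidence_type: str
    gene_id: str          # sorted id set joined with ";" (fusions carry both)
    gene_name: str
    cancer_id: str
    cancer_name: str
    drug_id: str
    drug_name: str
    variant_group: str
    variant_text: str
    citation_count: int
    mentions: list[tuple] = field(default_factory=list)
    in_civic: bool = False
    origin: str | None = None


@dataclass(frozen=True)
class CivicEntry:
    evidence_type: str
    gene_id: str
    cancer_id: str
    drug: str = ""

    def __post_init__(self) -> None:
        if self.evidence_type not in EVIDENCE_TYPES:
            raise ValueError(f"unknown evidence type {self.evidence_type!r}")


def _id_key(ids: Sequence[str]) -> str:
    return ";".join(sorted(ids))


def _most_common(values: Iterable[str]) -> str:
    counts: dict[str, int] = {}
    order: dict[str, int] = {}
    for i, v in enumerate(values):
        counts[v] = counts.get(v, 0) + 1
        order.setdefault(v, i)
    if not counts:
        return ""
    return max(counts, key=lambda v: (counts[v], -order[v]))


def collate(items: Iterable[EvidenceItem]) -> list[BiomarkerRecord]:
    """Group evidence items into biomarker records ranked by citation count."""
    groups: dict[tuple, list[EvidenceItem]] = {}
    for it in items:
        key = (
            it.evidence_type,
            _id_key(it.gene_ids),
            _id_key(it.cancer_ids),
            _id_key(it.drug_ids),
            it.variant_group,
        )
        groups.setdefault(key, []).append(it)
    records: list[BiomarkerRecord] = []
    for key, its in groups.items():
        etype, gene_key, cancer_key, drug_key, vgroup = key
        docs = {it.doc_id for it in its}
        mentions = sorted(
            (
                it.doc_id,
                it.pmid,
                it.year,
                it.journal,
                it.section_label,
                it.sentence_text,
            )
            for it in its
        )
        records.append(
            BiomarkerRecord(
                record_id=-1,
                evidence_type=etype,
                gene_id=gene_key,
                gene_name=_most_common(it.gene_text for it in its),
                cancer_id=cancer_key,
                cancer_name=_most_common(it.cancer_text for it in its),
                drug_id=drug_key,
                drug_name=_most_common(
                    it.drug_text for it in its if it.drug_text
                ),
                variant_group=vgroup,
                variant_text=_most_common(
                    it.variant_text
                    for it in its
                    if it.variant_text != UNKNOWN_VARIANT
                )
                or UNKNOWN_VARIANT,
                citation_count=len(docs),
                mentions=mentions,
            )
        )
    records.sort(
        key=lambda r: (
            -r.citation_count,
            r.evidence_type,
            r.gene_id,
            r.cancer_id,
            r.drug_id,
            r.variant_group,
        )
    )
    for i, r in enumerate(records):
        r.record_id = i
    return records


def read_civic_tsv(path) -> list[CivicEntry]:
    """Read a CIViC-style export: evidence_type, entrez_id, doid, drug."""
    out = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                CivicEntry(
                    evidence_type=row["evidence_type"],
                    gene_id=row["entrez_id"],
                    cancer_id=row["doid"],
                    drug=row.get("drug", "") or "",
                )
            )
    return out


def match_civic(
    records: Sequence[BiomarkerRecord], civic: Iterable[CivicEntry]
) -> list[BiomarkerRecord]:
    """Set ``in_civic`` on each record; no other field is altered.

    A record matches when some entry agrees on evidence type, gene id and
    cancer id; predictive records additionally require drug-name equality
    (case-insensitive, surrounding whitespace ignored; no fuzzy matching, so
    drug-family vs specific-drug mismatches surface as unmatched).  The
    exact variant is deliberately ignored.
    """
    civic = list(civic)
    out = []
    for rec in records:
        gene_ids = set(rec.gene_id.split(";"))
        cancer_ids = set(rec.cancer_id.split(";"))
        hit = False
        for e in civic:
            if e.evidence_type != rec.evidence_type:
                continue
            if e.gene_id not in gene_ids or e.cancer_id not in cancer_ids:
                continue
            if rec.evidence_type == "Predictive":
                if e.drug.strip().lower() != rec.drug_name.strip().lower():
                    continue
            hit = True
            break
        out.append(replace(rec, in_civic=hit, mentions=list(rec.mentions)))
    return out


def read_variant_set(path) -> set[tuple[str, str]]:
    """Read a (gene_id, substitution) set from TSV: gene_id<TAB>variant."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, var = line.split("\t")[:2]
            out.add((gene, var.upper()))
    return out


def classify_origin(
    records: Sequence[BiomarkerRecord],
    somatic_set: set[tuple[str, str]],
    common_set: set[tuple[str, str]],
) -> dict[int, str]:
    """Label substitution records somatic / germline-common by set membership.

    Only records with ``variant_group == "substitution"`` are labelled
    (others are skipped).  Returns record_id -> label in {"somatic",
    "germline-common", "both", "unlabelled"}; "both" flags membership in
    both supplied sets.  The label is also written onto each record's
    ``origin`` field.
    """
    labels: dict[int, str] = {}
    for rec in records:
        if rec.variant_group != "substitution":
            continue
        keys = {
            (gid, rec.variant_text.upper()) for gid in rec.gene_id.split(";")
        }
        in_somatic = bool(keys & somatic_set)
        in_common = bool(keys & common_set)
        if in_somatic and in_common:
            label = "both"
        elif in_somatic:
            label = "somatic"
        elif in_common:
            label = "germline-common"
        else:
            label = "unlabelled"
        rec.origin = label
        labels[rec.record_id] = label
    return labels


def export_kb(records: Sequence[BiomarkerRecord], out_dir) -> tuple[Path, Path]:
    """Write biomarkers.tsv and sentences.tsv (bit-stable for equal input).

    Empty drug fields export as empty strings, not "NA".
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bio_rows = []
    sent_rows = []
    for rec in records:
        bio_rows.append(
            {
                "record_id": rec.record_id,
                "evidence_type": rec.evidence_type,
                "gene_id": rec.gene_id,
                "gene_name": rec.gene_name,
                "cancer_id": rec.cancer_id,
                "cancer_name": rec.cancer_name,
                "drug_id": rec.drug_id,
                "drug_name": rec.drug_name,
                "variant_group": rec.variant_group,
                "variant_text": rec.variant_text,
                "citation_count": rec.citation_count,
                "in_civic": rec.in_civic,
            }
        )
        for doc_id, pmid, year, journal, section, text in rec.mentions:
            sent_rows.append(
                {
                    "record_id": rec.record_id,
                    "doc_id": doc_id,
                    "pmid": "" if pmid is None else pmid,
                    "year": "" if year is None else year,
                    "journal": journal,
                    "section_label": section,
                    "sentence_text": text,
                }
            )
    bio_path = out_dir / "biomarkers.tsv"
    sent_path = out_dir / "sentences.tsv"
    pd.DataFrame(bio_rows, columns=BIOMARKER_COLUMNS).to_csv(
        bio_path, sep="\t", index=False, lineterminator="\n"
    )
    pd.DataFrame(sent_rows, columns=SENTENCE_COLUMNS).to_csv(
        sent_path, sep="\t", index=False, lineterminator="\n"
    )
    return bio_path, sent_path
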