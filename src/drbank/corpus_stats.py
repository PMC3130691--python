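"""Descriptive corpus statistics: relation-type distribution, sense
distributions, connective contextual ambiguity, and sense-by-IMRAD-segment
distributions."""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .model import AnnotatedCorpus, ClassMapping, RelationRecord, build_class_mapping
from .standoff import extract_text

__all__ = [
    "DistributionTable",
    "relation_type_distribution",
    "sense_distribution",
    "ambiguity_table",
    "normalize_section",
    "imrad_distribution",
    "IMRAD_SEGMENTS",
    "EXCLUDED_SECTION",
]

#: Canonical rhetorical segments, in reporting order.
IMRAD_SEGMENTS = ("Introduction", "Methods", "Results", "Abstract", "Discussion")

EXCLUDED_SECTION = "excluded"


@dataclass
class DistributionTable:
    """Labeled count table. Percentages are always recomputed from the
    counts (against ``denominator`` when set, else the column total), so
    they can never drift from the underlying tallies."""

    counts: pd.DataFrame
    denominator: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def total(self, column: Optional[str] = None) -> int:
        col = self.counts[column] if column else self.counts.iloc[:, 0]
        return int(col.sum())

    def percentages(self, column: Optional[str] = None) -> pd.Series:
        col = self.counts[column] if column else self.counts.iloc[:, 0]
        denom = self.denominator if self.denominator is not None else col.sum()
        return 100.0 * col / denom if denom else col * 0.0

    def row_percentages(self) -> pd.DataFrame:
        """Percentages across each row, over the row's own total."""
        totals = self.counts.sum(axis=1)
        return 100.0 * self.counts.div(totals.replace(0, 1), axis=0)

    def to_text(self) -> str:
        return self.counts.to_string()


def _connective_text(rec: RelationRecord, doc_text: str) -> str:
    """Lowercased, whitespace-collapsed connective surface string."""
    assert rec.conn_spans is not None
    return " ".join(extract_text(doc_text, rec.conn_spans).lower().split())


def relation_type_distribution(corpus: AnnotatedCorpus) -> DistributionTable:
    """Token and unique-expression-type counts per relation type.

    Connective types are counted case-insensitively over surface strings
    (modified forms are distinct types); implicit types over the inserted
    strings, excluding the dummy "NONE" marker. NoRel has no types.
    """
    tokens = Counter()
    type_sets: dict[str, set[str]] = defaultdict(set)
    for doc in corpus.documents.values():
        for rec in doc.records:
            tokens[rec.rel_type] += 1
            if rec.rel_type in ("Explicit", "AltLex") and rec.conn_spans:
                type_sets[rec.rel_type].add(_connective_text(rec, doc.text))
            elif rec.rel_type == "Implicit" and rec.implicit_conn is not None:
                if not rec.has_dummy_conn:
                    type_sets[rec.rel_type].add(
                        " ".join(rec.implicit_conn.lower().split())
                    )
    rows = ["Explicit", "Implicit", "AltLex", "NoRel"]
    df = pd.DataFrame(
        {
            "tokens": [tokens.get(r, 0) for r in rows],
            "types": [len(type_sets.get(r, ())) for r in rows],
        },
        index=rows,
    )
    return DistributionTable(counts=df)


def sense_distribution(
    corpus: AnnotatedCorpus, granularity: str = "type"
) -> DistributionTable:
    """Per-sense counts split by relation type; relations carrying two
    senses are tallied separately under the ordered "Sense1/Sense2" key."""
    if granularity not in ("type", "leaf"):
        raise ValueError(f"granularity must be 'type' or 'leaf', got {granularity!r}")

    def name(sense) -> str:
        return sense.stype if granularity == "type" else sense.leaf

    single: dict[str, Counter] = defaultdict(Counter)
    multi: dict[str, Counter] = defaultdict(Counter)
    for rec in corpus.iter_records():
        if rec.sense1 is None:
            continue
        if rec.sense2 is not None:
            multi[f"{name(rec.sense1)}/{name(rec.sense2)}"][rec.rel_type] += 1
        else:
            single[name(rec.sense1)][rec.rel_type] += 1

    cols = ["Explicit", "Implicit", "AltLex"]
    rows = sorted(single) + sorted(multi)
    data = {c: [(single | multi)[r].get(c, 0) for r in rows] for c in cols}
    df = pd.DataFrame(data, index=rows)
    df["TOTAL"] = df.sum(axis=1)
    return DistributionTable(
        counts=df,
        meta={"n_single_rows": len(single), "n_multi_rows": len(multi)},
    )


def ambiguity_table(corpus: AnnotatedCorpus) -> DistributionTable:
    """Contextual ambiguity of explicit connectives.

    Uses only the first sense, at type granularity, over lowercased
    connective surface strings; keeps connective types realized with at
    least two distinct sense types. ``meta['total_tokens']`` carries the
    grand token count over the ambiguous types.
    """
    sense_sets: dict[str, set[str]] = defaultdict(set)
    token_counts: Counter = Counter()
    for doc in corpus.documents.values():
        for rec in doc.records:
            if rec.rel_type != "Explicit" or rec.conn_spans is None:
                continue
            if rec.sense1 is None:
                continue
            conn = _connective_text(rec, doc.text)
            sense_sets[conn].add(rec.sense1.stype)
            token_counts[conn] += 1

    ambiguous = sorted(c for c, senses in sense_sets.items() if len(senses) >= 2)
    df = pd.DataFrame(
        {
            "n_senses": [len(sense_sets[c]) for c in ambiguous],
            "senses": [", ".join(sorted(sense_sets[c])) for c in ambiguous],
            "tokens": [token_counts[c] for c in ambiguous],
        },
        index=ambiguous,
    )
    total = int(df["tokens"].sum()) if ambiguous else 0
    explicit_total = sum(
        1 for r in corpus.iter_records() if r.rel_type == "Explicit"
    )
    return DistributionTable(
        counts=df,
        denominator=explicit_total or None,
        meta={"total_tokens": total, "explicit_tokens": explicit_total},
    )


_SECTION_ALIASES = {
    "background": "Introduction",
    "introduction": "Introduction",
    "materials and methods": "Methods",
    "methods": "Methods",
    "results": "Results",
    "abstract": "Abstract",
    "discussion": "Discussion",
}


def normalize_section(raw: Optional[str]) -> str:
    """Canonical rhetorical segment for a raw section label.

    Background folds into Introduction and Materials and Methods into
    Methods; Conclusions, Authors' Contributions, captions, and anything
    unrecognized map to :data:`EXCLUDED_SECTION`.
    """
    if raw is None:
        return EXCLUDED_SECTION
    key = " ".join(raw.lower().split())
    return _SECTION_ALIASES.get(key, EXCLUDED_SECTION)


def imrad_distribution(corpus: AnnotatedCorpus) -> DistributionTable:
    """Type-level sense by canonical segment counts over Explicit,
    Implicit and AltLex relations.

    Records in excluded sections are dropped, NoRel records are dropped,
    and documents without any recognizable segment (no conventional
    rhetorical structure) are skipped wholesale. Row percentages are over
    each sense row's own total.
    """
    cells: dict[str, Counter] = defaultdict(Counter)
    for doc in corpus.documents.values():
        canon = [normalize_section(r.section) for r in doc.records]
        if not any(c != EXCLUDED_SECTION for c in canon):
            continue
        for rec, seg in zip(doc.records, canon):
            if rec.rel_type not in ("Explicit", "Implicit", "AltLex"):
                continue
            if seg == EXCLUDED_SECTION or rec.sense1 is None:
                continue
            cells[rec.sense1.stype][seg] += 1
    rows = sorted(cells)
    df = pd.DataFrame(
        {seg: [cells[r].get(seg, 0) for r in rows] for seg in IMRAD_SEGMENTS},
        index=rows,
    )
    return DistributionTable(counts=df)


def class_distribution(
    corpus: AnnotatedCorpus, mapping: Optional[ClassMapping] = None
) -> DistributionTable:
    """First-sense counts collapsed onto the four generalized classes."""
    mapping = mapping or build_class_mapping()
    counts = Counter(
        mapping[rec.sense1.stype]
        for rec in corpus.iter_records()
        if rec.sense1 is not None
    )
    rows = sorted(counts)
    df = pd.DataFrame({"tokens": [counts[r] for r in rows]}, index=rows)
    return DistributionTable(counts=df)
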