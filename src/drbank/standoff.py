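"""Reader/writer for the pipe-delimited stand-off annotation format.

Each annotation file is flat text with one relation per line; fields are
separated by ``|``. Only a fixed subset of field indices is meaningful
(relation type, connective spans, inserted connective, two senses, Arg1
and Arg2 spans); all other columns are written empty. Span fields hold
``start..end`` offset pairs, semicolon-separated when discontinuous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

from .model import (
    AnnotatedCorpus,
    CharSpan,
    NONE_CONNECTIVE,
    RelationRecord,
    RELATION_TYPES,
    SenseError,
    SenseTaxonomy,
    SpanSet,
    build_taxonomy,
    validate_record,
)

__all__ = [
    "FormatDialect",
    "StandoffParseError",
    "parse_spanset",
    "serialize_spanset",
    "parse_relation_line",
    "serialize_relation",
    "read_annotation_file",
    "read_corpus",
    "write_corpus",
    "extract_text",
]


class StandoffParseError(ValueError):
    """Malformed stand-off annotation content."""


@dataclass(frozen=True)
class FormatDialect:
    """Column layout and offset conventions of an annotation file.

    The default 27-column layout is the compact representation; the
    classic 48-column layout of full PDTB files can be selected via
    ``n_fields``. ``end_inclusive`` accepts files whose span ends point
    at the last character instead of one past it; ``normalize_crlf``
    folds Windows line endings in source texts before offsets are
    resolved.
    """

    n_fields: int = 27
    end_inclusive: bool = False
    normalize_crlf: bool = False

    # Meaningful field indices (0-based).
    F_REL_TYPE: int = 0
    F_CONN_SPANS: int = 1
    F_IMPLICIT_CONN: int = 7
    F_SENSE1: int = 8
    F_SENSE2: int = 9
    F_ARG1_SPANS: int = 14
    F_ARG2_SPANS: int = 20


_SPAN_TOKEN = re.compile(r"^(\d+)\.\.(\d+)$")


def parse_spanset(text: str, dialect: FormatDialect = FormatDialect()) -> SpanSet:
    """Parse ``start..end(;start..end)*`` into a SpanSet; '' is empty."""
    text = text.strip()
    if not text:
        return SpanSet()
    spans = []
    for token in text.split(";"):
        m = _SPAN_TOKEN.match(token.strip())
        if m is None:
            raise StandoffParseError(f"malformed span token {token!r}")
        start, end = int(m.group(1)), int(m.group(2))
        if dialect.end_inclusive:
            end += 1
        if start >= end:
            raise StandoffParseError(f"empty or inverted span token {token!r}")
        spans.append(CharSpan(start, end))
    try:
        return SpanSet(spans)
    except ValueError as exc:
        raise StandoffParseError(str(exc)) from None


def serialize_spanset(spans: SpanSet, dialect: FormatDialect = FormatDialect()) -> str:
    off = 1 if dialect.end_inclusive else 0
    return ";".join(f"{sp.start}..{sp.end - off}" for sp in spans)


def parse_relation_line(
    line: str,
    dialect: FormatDialect = FormatDialect(),
    taxonomy: Optional[SenseTaxonomy] = None,
    doc_id: str = "",
    lineno: Optional[int] = None,
) -> RelationRecord:
    """Parse one pipe-delimited annotation line into a RelationRecord.

    Trailing empty columns may be omitted on input; any populated column
    beyond the dialect's count, or fewer meaningful columns than the
    layout requires, is an error.
    """
    taxonomy = taxonomy or build_taxonomy()
    where = f" (line {lineno})" if lineno is not None else ""

    fields = line.rstrip("\n").split("|")
    if len(fields) < dialect.F_ARG2_SPANS + 1 or (
        len(fields) > dialect.n_fields and any(f.strip() for f in fields[dialect.n_fields:])
    ):
        raise StandoffParseError(
            f"expected {dialect.n_fields} '|'-separated fields, got {len(fields)}{where}"
        )
    fields += [""] * (dialect.n_fields - len(fields))

    rel_type = fields[dialect.F_REL_TYPE].strip()
    if rel_type not in RELATION_TYPES:
        raise StandoffParseError(f"unknown relation type {rel_type!r}{where}")

    def spans(idx: int) -> SpanSet:
        try:
            return parse_spanset(fields[idx], dialect)
        except StandoffParseError as exc:
            raise StandoffParseError(f"field {idx}: {exc}{where}") from None

    def sense(idx: int) -> Optional[object]:
        raw = fields[idx].strip()
        if not raw:
            return None
        try:
            return taxonomy.normalize(raw)
        except SenseError as exc:
            raise StandoffParseError(f"field {idx}: {exc}{where}") from None

    conn = spans(dialect.F_CONN_SPANS)
    implicit_raw = fields[dialect.F_IMPLICIT_CONN].strip()
    return RelationRecord(
        rel_type=rel_type,
        conn_spans=conn if conn else None,
        implicit_conn=implicit_raw if implicit_raw else None,
        sense1=sense(dialect.F_SENSE1),
        sense2=sense(dialect.F_SENSE2),
        arg1_spans=spans(dialect.F_ARG1_SPANS),
        arg2_spans=spans(dialect.F_ARG2_SPANS),
        doc_id=doc_id,
    )


def serialize_relation(
    rec: RelationRecord,
    dialect: FormatDialect = FormatDialect(),
    doc_text: Optional[str] = None,
    taxonomy: Optional[SenseTaxonomy] = None,
) -> str:
    """Serialize a record to one annotation line (constant column count).

    When ``doc_text`` is supplied the record is validated first and an
    invalid record is refused with its violation list.
    """
    if doc_text is not None:
        violations = validate_record(rec, doc_text, taxonomy or build_taxonomy())
        if violations:
            raise ValueError(
                "refusing to serialize invalid record: " + "; ".join(violations)
            )
    fields = [""] * dialect.n_fields
    fields[dialect.F_REL_TYPE] = rec.rel_type
    if rec.conn_spans:
        fields[dialect.F_CONN_SPANS] = serialize_spanset(rec.conn_spans, dialect)
    if rec.implicit_conn is not None:
        fields[dialect.F_IMPLICIT_CONN] = rec.implicit_conn
    if rec.sense1 is not None:
        fields[dialect.F_SENSE1] = str(rec.sense1)
    if rec.sense2 is not None:
        fields[dialect.F_SENSE2] = str(rec.sense2)
    fields[dialect.F_ARG1_SPANS] = serialize_spanset(rec.arg1_spans, dialect)
    fields[dialect.F_ARG2_SPANS] = serialize_spanset(rec.arg2_spans, dialect)
    return "|".join(fields)


# ---------------------------------------------------------------------------
# Corpus-level I/O


def read_annotation_file(
    path: Union[str, Path],
    dialect: FormatDialect = FormatDialect(),
    taxonomy: Optional[SenseTaxonomy] = None,
    doc_id: str = "",
) -> list[RelationRecord]:
    records = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        records.append(
            parse_relation_line(line, dialect, taxonomy, doc_id=doc_id, lineno=lineno)
        )
    return records


def read_corpus(
    src_dir: Union[str, Path],
    ann_dir: Union[str, Path],
    dialect: FormatDialect = FormatDialect(),
    taxonomy: Optional[SenseTaxonomy] = None,
    ann_suffix: str = ".ann",
    src_suffix: str = ".txt",
) -> tuple[AnnotatedCorpus, list[tuple[str, int, str]]]:
    """Load paired source/annotation directories into a corpus.

    Documents pair by file stem. Returns the corpus together with all
    record-level validation violations (violating records are kept, not
    silently dropped). A missing source file or an out-of-bounds span is
    a hard error.
    """
    src_dir, ann_dir = Path(src_dir), Path(ann_dir)
    taxonomy = taxonomy or build_taxonomy()
    corpus = AnnotatedCorpus()
    ann_files = sorted(ann_dir.glob(f"*{ann_suffix}"))
    if not ann_files:
        raise FileNotFoundError(f"no {ann_suffix} files under {ann_dir}")
    for ann_path in ann_files:
        doc_id = ann_path.name[: -len(ann_suffix)]
        src_path = src_dir / f"{doc_id}{src_suffix}"
        if not src_path.exists():
            raise FileNotFoundError(f"missing source text for {doc_id}: {src_path}")
        text = src_path.read_text(encoding="utf-8")
        if dialect.normalize_crlf:
            text = text.replace("\r\n", "\n")
        records = read_annotation_file(ann_path, dialect, taxonomy, doc_id=doc_id)
        for i, rec in enumerate(records):
            for spans in (rec.conn_spans, rec.arg1_spans, rec.arg2_spans):
                if spans and spans.end > len(text):
                    raise StandoffParseError(
                        f"span end {spans.end} beyond length {len(text)} of "
                        f"document {doc_id!r} (record {i + 1})"
                    )
        corpus.add(doc_id, text, records)
    return corpus, corpus.validate(taxonomy)


def write_corpus(
    corpus: AnnotatedCorpus,
    src_dir: Union[str, Path],
    ann_dir: Union[str, Path],
    dialect: FormatDialect = FormatDialect(),
    ann_suffix: str = ".ann",
    src_suffix: str = ".txt",
) -> None:
    src_dir, ann_dir = Path(src_dir), Path(ann_dir)
    src_dir.mkdir(parents=True, exist_ok=True)
    ann_dir.mkdir(parents=True, exist_ok=True)
    for doc_id, doc in corpus.documents.items():
        (src_dir / f"{doc_id}{src_suffix}").write_text(doc.text, encoding="utf-8")
        lines = [serialize_relation(rec, dialect) for rec in doc.records]
        (ann_dir / f"{doc_id}{ann_suffix}").write_text(
            "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
        )


def extract_text(doc_text: str, spans: SpanSet) -> str:
    """Substring anchored by a span set; discontinuous parts are joined
    with a single space, in span order."""
    for sp in spans:
        if sp.end > len(doc_text):
            raise IndexError(
                f"span {sp.start}..{sp.end} exceeds document length {len(doc_text)}"
            )
    return " ".join(doc_text[sp.start : sp.end] for sp in spans)


def convert_dialect(
    rec: RelationRecord, src: FormatDialect, dst: FormatDialect
) -> RelationRecord:
    """Records are offset-convention agnostic in memory; conversion is a
    re-serialization concern, so this is the identity on records."""
    return replace(rec)
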