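"""Core data model for stand-off discourse relation banks.

Provides character-offset spans, the two-tier sense taxonomy (16 types,
31 leaf categories), the generalization of sense types onto the four
PDTB top-level classes, relation records, and record-level validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "CharSpan",
    "SpanSet",
    "SenseLabel",
    "SenseTaxonomy",
    "ClassMapping",
    "RelationRecord",
    "Document",
    "AnnotatedCorpus",
    "SenseError",
    "NONE_CONNECTIVE",
    "RELATION_TYPES",
    "PDTB_CLASSES",
    "build_taxonomy",
    "build_class_mapping",
    "validate_sense",
    "to_pdtb_class",
    "validate_record",
]

#: Relation types recognized in annotation field 0.
RELATION_TYPES = ("Explicit", "Implicit", "AltLex", "NoRel")

#: The four generalized PDTB top-level sense classes.
PDTB_CLASSES = ("Comparison", "Contingency", "Temporal", "Expansion")

#: Dummy inserted-connective marker for implicit relations whose sense
#: (Continuation/Background/Circumstance) admits no connective insertion.
NONE_CONNECTIVE = "NONE"


class SenseError(ValueError):
    """Raised for sense labels that do not exist in the taxonomy."""


@dataclass(frozen=True, order=True)
class CharSpan:
    """Half-open character interval ``[start, end)`` into a source text."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative span start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted span: {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "CharSpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class SpanSet:
    """Ordered set of non-overlapping spans anchoring a (possibly
    discontinuous) text extent; element order is linear text order."""

    spans: tuple[CharSpan, ...]

    def __init__(self, spans: Iterable[CharSpan] = ()) -> None:
        spans = tuple(spans)
        for a, b in zip(spans, spans[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"spans overlap or are out of text order: {a} then {b}"
                )
        object.__setattr__(self, "spans", spans)

    def __iter__(self) -> Iterator[CharSpan]:
        return iter(self.spans)

    def __len__(self) -> int:
        return len(self.spans)

    def __bool__(self) -> bool:
        return bool(self.spans)

    @property
    def start(self) -> int:
        if not self.spans:
            raise ValueError("empty SpanSet has no start offset")
        return self.spans[0].start

    @property
    def end(self) -> int:
        if not self.spans:
            raise ValueError("empty SpanSet has no end offset")
        return self.spans[-1].end

    def coverage(self) -> frozenset[int]:
        """Set of character positions covered by any span."""
        return frozenset(
            i for span in self.spans for i in range(span.start, span.end)
        )

    def contains(self, other: "SpanSet") -> bool:
        """True if every position of *other* is covered by this set."""
        return other.coverage() <= self.coverage()

    def overlaps(self, other: "SpanSet") -> bool:
        """True if the two coverages share at least one character."""
        return any(a.overlaps(b) for a in self.spans for b in other.spans)


@dataclass(frozen=True, order=True)
class SenseLabel:
    """Two-tier sense label: a type, plus a subtype when the type has any."""

    stype: str
    subtype: Optional[str] = None

    def __str__(self) -> str:
        return self.stype if self.subtype is None else f"{self.stype}.{self.subtype}"

    @property
    def leaf(self) -> str:
        """Leaf-granularity name (``Type.Subtype``, or ``Type`` alone)."""
        return str(self)


# ---------------------------------------------------------------------------
# Taxonomy


_TAXONOMY_ENTRIES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("Cause", ("Reason", "Result", "Claim", "Justification")),
    ("Condition", ("Hypothetical", "Factual", "Non-Factual")),
    ("Purpose", ("Goal", "Enablement")),
    ("Temporal", ("Synchronous", "Precedence", "Succession")),
    ("Concession", ("Contra-Expectation", "Expectation")),
    ("Alternative", ("Chosen-Alternative", "Conjunctive", "Disjunctive")),
    ("Contrast", ()),
    ("Instantiation", ()),
    ("Conjunction", ()),
    ("Exception", ()),
    ("Similarity", ()),
    ("Continuation", ()),
    ("Circumstance", ("Forward-Circumstance", "Backward-Circumstance")),
    ("Background", ("Forward-Background", "Backward-Background")),
    ("Restatement", ("Equivalence", "Generalization", "Specification")),
    ("Reinforcement", ()),
)


@dataclass(frozen=True)
class SenseTaxonomy:
    """Mapping from sense type to its ordered (possibly empty) subtypes."""

    entries: Mapping[str, tuple[str, ...]]

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def subtypes(self, stype: str) -> tuple[str, ...]:
        if stype not in self.entries:
            raise SenseError(f"unknown sense type: {stype!r}")
        return self.entries[stype]

    def leaves(self) -> tuple[str, ...]:
        """All leaf category names: each subtype, plus each subtype-less type."""
        out: list[str] = []
        for stype, subs in self.entries.items():
            if subs:
                out.extend(f"{stype}.{sub}" for sub in subs)
            else:
                out.append(stype)
        return tuple(out)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def _canonical(self) -> dict[str, str]:
        return {t.lower(): t for t in self.entries}

    def normalize(self, text: str) -> SenseLabel:
        """Parse ``Type`` or ``Type.Subtype`` text, case/whitespace tolerant.

        Raises :class:`SenseError` for names absent from the taxonomy.
        """
        raw = text.strip()
        if not raw:
            raise SenseError("empty sense label")
        stype_raw, dot, subtype_raw = raw.partition(".")
        types = self._canonical()
        key = stype_raw.strip().lower()
        if key not in types:
            raise SenseError(f"unknown sense type: {stype_raw.strip()!r}")
        stype = types[key]
        if not dot:
            return SenseLabel(stype)
        subs = {s.lower(): s for s in self.entries[stype]}
        skey = subtype_raw.strip().lower()
        if skey not in subs:
            raise SenseError(
                f"unknown subtype {subtype_raw.strip()!r} for sense type {stype!r}"
            )
        return SenseLabel(stype, subs[skey])


def build_taxonomy() -> SenseTaxonomy:
    """Return the fixed bank taxonomy: 16 types, 31 leaf categories."""
    return SenseTaxonomy(entries=dict(_TAXONOMY_ENTRIES))


# ---------------------------------------------------------------------------
# Class mapping


_CLASS_OF_TYPE: dict[str, str] = {
    "Concession": "Comparison",
    "Contrast": "Comparison",
    "Cause": "Contingency",
    "Condition": "Contingency",
    "Purpose": "Contingency",
    "Temporal": "Temporal",
    "Alternative": "Expansion",
    "Background": "Expansion",
    "Circumstance": "Expansion",
    "Conjunction": "Expansion",
    "Continuation": "Expansion",
    "Exception": "Expansion",
    "Instantiation": "Expansion",
    "Reinforcement": "Expansion",
    "Restatement": "Expansion",
    "Similarity": "Expansion",
}


@dataclass(frozen=True)
class ClassMapping:
    """Total map from the 16 sense types onto the 4 generalized classes."""

    entries: Mapping[str, str]

    def __getitem__(self, stype: str) -> str:
        try:
            return self.entries[stype]
        except KeyError:
            raise SenseError(f"sense type not in class mapping: {stype!r}") from None


def build_class_mapping() -> ClassMapping:
    return ClassMapping(entries=dict(_CLASS_OF_TYPE))


def validate_sense(
    label: SenseLabel, taxonomy: SenseTaxonomy, strict: bool = True
) -> bool:
    """Check a sense label against the taxonomy.

    Unknown type or subtype names raise :class:`SenseError`. Under
    ``strict=True`` a type-only label for a type that carries subtypes is
    invalid (the annotation scheme forces a subtype choice); under lenient
    mode such type-level labels are accepted, as needed for aggregate
    tables that report at type granularity.
    """
    subs = taxonomy.subtypes(label.stype)
    if label.subtype is None:
        return not (strict and subs)
    if label.subtype not in subs:
        raise SenseError(
            f"unknown subtype {label.subtype!r} for sense type {label.stype!r}"
        )
    return True


def to_pdtb_class(label: SenseLabel, mapping: ClassMapping) -> str:
    """Generalized 4-way class of a sense label (subtype is ignored)."""
    return mapping[label.stype]


# ---------------------------------------------------------------------------
# Relation records


@dataclass
class RelationRecord:
    """One annotated discourse relation token.

    ``conn_spans`` anchors an explicit connective or AltLex expression;
    ``implicit_conn`` is the inserted string of an implicit relation (the
    marker :data:`NONE_CONNECTIVE` when no connective could be inserted).
    """

    rel_type: str
    arg1_spans: SpanSet
    arg2_spans: SpanSet
    conn_spans: Optional[SpanSet] = None
    implicit_conn: Optional[str] = None
    sense1: Optional[SenseLabel] = None
    sense2: Optional[SenseLabel] = None
    doc_id: str = ""
    section: Optional[str] = None

    @property
    def has_dummy_conn(self) -> bool:
        """True for implicit relations annotated with the "NONE" marker."""
        return self.implicit_conn == NONE_CONNECTIVE

    @property
    def location(self) -> int:
        """Anchor offset: connective start, or Arg2 start for implicits."""
        if self.conn_spans:
            return self.conn_spans.start
        return self.arg2_spans.start

    def senses(self) -> tuple[SenseLabel, ...]:
        return tuple(s for s in (self.sense1, self.sense2) if s is not None)


def _spanset_in_bounds(spans: Optional[SpanSet], n: int) -> bool:
    return spans is None or all(sp.end <= n for sp in spans)


def validate_record(
    rec: RelationRecord,
    doc_text: str,
    taxonomy: SenseTaxonomy,
    strict_senses: bool = False,
) -> list[str]:
    """Return all invariant violations of a record (empty list = valid).

    Checks are deterministic and independent of one another; nothing is
    raised, so callers can collect violations across a whole corpus.
    """
    v: list[str] = []
    if rec.rel_type not in RELATION_TYPES:
        v.append(f"unknown relation type {rec.rel_type!r}")
        return v

    n = len(doc_text)
    for name, spans in (
        ("connective", rec.conn_spans),
        ("Arg1", rec.arg1_spans),
        ("Arg2", rec.arg2_spans),
    ):
        if not _spanset_in_bounds(spans, n):
            v.append(f"{name} span exceeds document length {n}")

    if rec.rel_type in ("Explicit", "AltLex"):
        if not rec.conn_spans:
            v.append(f"{rec.rel_type} relation requires connective spans")
        if rec.implicit_conn is not None:
            v.append(f"{rec.rel_type} relation must not carry an inserted connective")
        if rec.sense1 is None:
            v.append(f"{rec.rel_type} relation requires sense1")
    elif rec.rel_type == "Implicit":
        if rec.conn_spans:
            v.append("Implicit relation must not have connective spans")
        if rec.implicit_conn is None:
            v.append("Implicit relation requires an inserted connective string")
        if rec.sense1 is None:
            v.append("Implicit relation requires sense1")
        if rec.sense2 is not None:
            v.append("Implicit relation must not carry a second sense")
    elif rec.rel_type == "NoRel":
        if rec.conn_spans or rec.implicit_conn is not None:
            v.append("NoRel relation must not have a connective")
        if rec.sense1 is not None or rec.sense2 is not None:
            v.append("NoRel relation must not carry senses")
        if len(rec.arg1_spans) != 1 or len(rec.arg2_spans) != 1:
            v.append("NoRel arguments must each be a single contiguous span")

    if (
        rec.rel_type == "AltLex"
        and rec.conn_spans
        and _spanset_in_bounds(rec.conn_spans, n)
        and _spanset_in_bounds(rec.arg2_spans, n)
        and not rec.arg2_spans.contains(rec.conn_spans)
    ):
        v.append("AltLex expression spans must be contained within Arg2 spans")

    for which, sense in (("sense1", rec.sense1), ("sense2", rec.sense2)):
        if sense is None:
            continue
        try:
            if not validate_sense(sense, taxonomy, strict=strict_senses):
                v.append(f"{which} {sense} requires a subtype")
        except SenseError as exc:
            v.append(f"{which}: {exc}")

    if not rec.arg1_spans:
        v.append("Arg1 spans must be non-empty")
    if not rec.arg2_spans:
        v.append("Arg2 spans must be non-empty")
    return v


# ---------------------------------------------------------------------------
# Corpus container


@dataclass
class Document:
    text: str
    records: list[RelationRecord] = field(default_factory=list)


@dataclass
class AnnotatedCorpus:
    """Mapping from document id to source text plus its relation records."""

    documents: dict[str, Document] = field(default_factory=dict)

    def add(self, doc_id: str, text: str, records: Sequence[RelationRecord] = ()) -> None:
        self.documents[doc_id] = Document(text=text, records=list(records))

    def iter_records(self) -> Iterator[RelationRecord]:
        for doc in self.documents.values():
            yield from doc.records

    @property
    def n_records(self) -> int:
        return sum(len(d.records) for d in self.documents.values())

    def validate(
        self, taxonomy: Optional[SenseTaxonomy] = None
    ) -> list[tuple[str, int, str]]:
        """All violations as ``(doc_id, record_index, message)`` triples."""
        taxonomy = taxonomy or build_taxonomy()
        out: list[tuple[str, int, str]] = []
        for doc_id, doc in self.documents.items():
            for i, rec in enumerate(doc.records):
                for msg in validate_record(rec, doc.text, taxonomy):
                    out.append((doc_id, i, msg))
        return out
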