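"""Synthetic relation banks with known ground truth.

Generates source texts of filler sentences with planted connective
strings at recorded offsets, draws senses from per-connective conditional
distributions, derives a second noisy "annotator" by controlled span
jitter, deletion/insertion, and sense confusion, and builds deterministic
fixture corpora that reproduce the published summary tables cell for
cell. A closed-form accuracy oracle for the connective-only classifier is
provided for acceptance testing.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from . import tables
from .model import (
    AnnotatedCorpus,
    CharSpan,
    ClassMapping,
    NONE_CONNECTIVE,
    RelationRecord,
    SenseLabel,
    SenseTaxonomy,
    SpanSet,
    build_class_mapping,
    build_taxonomy,
)

__all__ = [
    "SynthConfig",
    "PerturbConfig",
    "generate_corpus",
    "perturb_annotations",
    "fixture_from_tables",
    "closed_form_bayes_rate",
]

#: Senses whose implicit relations take the "NONE" dummy connective.
_NONE_SENSE_TYPES = frozenset({"Continuation", "Background", "Circumstance"})

# Pseudo-words chosen not to collide with any plausible connective string,
# so planted connective offsets are unambiguous in the filler text.
_FILLER_WORDS = (
    "zorvat", "quiblen", "marnex", "fodril", "brastin", "welkor", "dunmir",
    "saphrel", "tovek", "grimbal", "nexlor", "pindra", "vostel", "crenna",
    "jaldek", "ombrix", "thrale", "ulvane", "korrin", "blenth",
)


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth generator parameters.

    ``connectives`` maps each explicit connective string to its sense
    conditional distribution (labels may be type-level or leaf-level);
    ``connective_weights`` gives the connective marginal (uniform when
    omitted). Implicit and AltLex inventories default to the explicit
    one. ``sections`` assigns raw section labels to relations in order,
    by quota.
    """

    n_relations: Mapping[str, int]
    connectives: Mapping[str, Mapping[str, float]]
    connective_weights: Optional[Mapping[str, float]] = None
    implicit_connectives: Optional[Mapping[str, Mapping[str, float]]] = None
    altlex_connectives: Optional[Mapping[str, Mapping[str, float]]] = None
    multi_sense_rate: float = 0.0
    pair_second_sense: Optional[Mapping[str, Mapping[str, float]]] = None
    sections: Optional[Sequence[tuple[str, int]]] = None
    doc_size: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for rel, n in self.n_relations.items():
            if n < 0:
                raise ValueError(f"negative relation count for {rel!r}: {n}")
        for inventory in (
            self.connectives,
            self.implicit_connectives,
            self.altlex_connectives,
            self.pair_second_sense,
        ):
            if inventory is None:
                continue
            for key, dist in inventory.items():
                total = sum(dist.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"sense distribution for {key!r} sums to {total}, not 1"
                    )
        if not 0.0 <= self.multi_sense_rate <= 1.0:
            raise ValueError(f"multi_sense_rate outside [0, 1]: {self.multi_sense_rate}")


@dataclass(frozen=True)
class PerturbConfig:
    """Noise model for the derived second annotator.

    ``jitter_prob`` is the per-argument-spanset probability of shifting
    endpoints by up to ``jitter_max`` characters (never producing an
    empty or out-of-bounds span); ``delete_prob`` drops whole relation
    tokens; ``insert_prob`` adds spurious explicit tokens; sense1 labels
    are substituted with probability ``confusion_rate`` (uniformly over
    the other labels in the corpus) or per an explicit row-stochastic
    ``confusion`` matrix over label strings.
    """

    jitter_prob: float = 0.0
    jitter_max: int = 2
    delete_prob: float = 0.0
    insert_prob: float = 0.0
    confusion_rate: float = 0.0
    confusion: Optional[Mapping[str, Mapping[str, float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("jitter_prob", "delete_prob", "insert_prob", "confusion_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {p}")
        if self.confusion is not None:
            for lbl, row in self.confusion.items():
                if abs(sum(row.values()) - 1.0) > 1e-9:
                    raise ValueError(f"confusion row for {lbl!r} does not sum to 1")


# ---------------------------------------------------------------------------
# Corpus builder


class _CorpusBuilder:
    """Accumulates filler text and records, chunking into documents."""

    def __init__(self, doc_size: int = 500, taxonomy: Optional[SenseTaxonomy] = None):
        self.taxonomy = taxonomy or build_taxonomy()
        self.doc_size = doc_size
        self.corpus = AnnotatedCorpus()
        self._parts: list[str] = []
        self._pos = 0
        self._records: list[RelationRecord] = []
        self._n_docs = 0
        self._filler_i = 0

    # -- text assembly -----------------------------------------------------
    def _emit(self, text: str) -> CharSpan:
        start = self._pos
        self._parts.append(text)
        self._pos += len(text)
        return CharSpan(start, self._pos)

    def _gap(self) -> None:
        self._parts.append(". ")
        self._pos += 2

    def filler_sentence(self, rng: Optional[np.random.Generator] = None) -> CharSpan:
        if rng is None:
            n = 4 + self._filler_i % 3
            words = [
                _FILLER_WORDS[(self._filler_i + k) % len(_FILLER_WORDS)]
                for k in range(n)
            ]
            self._filler_i += n
        else:
            n = int(rng.integers(4, 9))
            words = [_FILLER_WORDS[i] for i in rng.integers(0, len(_FILLER_WORDS), n)]
        return self._emit(" ".join(words))

    def sense(self, label: Optional[str]) -> Optional[SenseLabel]:
        return None if label is None else self.taxonomy.normalize(label)

    # -- record constructors ----------------------------------------------
    def add_explicit(
        self,
        conn: str,
        sense1: str,
        sense2: Optional[str] = None,
        section: Optional[str] = None,
        rng: Optional[np.random.Generator] = None,
        rel_type: str = "Explicit",
    ) -> None:
        arg1 = self.filler_sentence(rng)
        self._gap()
        conn_span = self._emit(conn)
        if rel_type == "AltLex":
            # expression is part of Arg2, satisfying the containment rule
            self._parts.append(" ")
            self._pos += 1
            arg2_body = self.filler_sentence(rng)
            arg2 = SpanSet([CharSpan(conn_span.start, arg2_body.end)])
        else:
            self._parts.append(" ")
            self._pos += 1
            arg2 = SpanSet([self.filler_sentence(rng)])
        self._gap()
        self._push(
            RelationRecord(
                rel_type=rel_type,
                conn_spans=SpanSet([conn_span]),
                sense1=self.sense(sense1),
                sense2=self.sense(sense2),
                arg1_spans=SpanSet([arg1]),
                arg2_spans=arg2,
                section=section,
            )
        )

    def add_altlex(
        self,
        expr: str,
        sense1: str,
        sense2: Optional[str] = None,
        section: Optional[str] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        self.add_explicit(expr, sense1, sense2, section, rng, rel_type="AltLex")

    def add_implicit(
        self,
        conn: str,
        sense1: str,
        section: Optional[str] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        arg1 = self.filler_sentence(rng)
        self._gap()
        arg2 = self.filler_sentence(rng)
        self._gap()
        self._push(
            RelationRecord(
                rel_type="Implicit",
                implicit_conn=conn,
                sense1=self.sense(sense1),
                arg1_spans=SpanSet([arg1]),
                arg2_spans=SpanSet([arg2]),
                section=section,
            )
        )

    def add_norel(
        self,
        section: Optional[str] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        arg1 = self.filler_sentence(rng)
        self._gap()
        arg2 = self.filler_sentence(rng)
        self._gap()
        self._push(
            RelationRecord(
                rel_type="NoRel",
                arg1_spans=SpanSet([arg1]),
                arg2_spans=SpanSet([arg2]),
                section=section,
            )
        )

    # -- document chunking -------------------------------------------------
    def _push(self, rec: RelationRecord) -> None:
        self._records.append(rec)
        if len(self._records) >= self.doc_size:
            self._flush()

    def _flush(self) -> None:
        if not self._records and not self._parts:
            return
        doc_id = f"doc{self._n_docs:04d}"
        text = "".join(self._parts)
        for rec in self._records:
            rec.doc_id = doc_id
        self.corpus.add(doc_id, text, self._records)
        self._n_docs += 1
        self._parts, self._records, self._pos = [], [], 0

    def build(self) -> AnnotatedCorpus:
        self._flush()
        return self.corpus


# ---------------------------------------------------------------------------
# Random generation


def _draw(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _weights(cfg: SynthConfig, inventory: Mapping[str, Mapping[str, float]]):
    keys = list(inventory)
    if cfg.connective_weights is None:
        w = np.ones(len(keys))
    else:
        w = np.array([cfg.connective_weights.get(k, 0.0) for k in keys], dtype=float)
        if w.sum() <= 0:
            raise ValueError("connective weights sum to zero over the inventory")
    return keys, w / w.sum()


def _default_pair_table(sense1_type: str) -> Optional[dict[str, float]]:
    """Second-sense conditional mirroring the published multi-sense rows."""
    rows = {
        s2: ex + al
        for (s1, s2), (ex, al) in tables.SENSE_TABLE_MULTI.items()
        if s1 == sense1_type and (ex + al) > 0
    }
    if not rows:
        return None
    total = sum(rows.values())
    return {s2: c / total for s2, c in rows.items()}


def _draw_sense2(
    rng: np.random.Generator, cfg: SynthConfig, sense1: str, taxonomy: SenseTaxonomy
) -> Optional[str]:
    if cfg.multi_sense_rate <= 0.0 or rng.random() >= cfg.multi_sense_rate:
        return None
    s1_type = taxonomy.normalize(sense1).stype
    if cfg.pair_second_sense is not None:
        dist = cfg.pair_second_sense.get(s1_type)
    else:
        dist = _default_pair_table(s1_type)
    return None if dist is None else _draw(rng, dist)


def generate_corpus(
    cfg: SynthConfig, taxonomy: Optional[SenseTaxonomy] = None
) -> AnnotatedCorpus:
    """Generate a corpus whose relation mix and per-connective sense
    conditionals follow ``cfg``; same seed, same bytes."""
    taxonomy = taxonomy or build_taxonomy()
    for conn in cfg.connectives:
        if any(w in _FILLER_WORDS for w in conn.lower().split()):
            raise ValueError(f"connective {conn!r} collides with filler vocabulary")
    rng = np.random.default_rng(cfg.seed)
    builder = _CorpusBuilder(doc_size=cfg.doc_size, taxonomy=taxonomy)

    section_plan: list[Optional[str]] = []
    if cfg.sections:
        for label, quota in cfg.sections:
            section_plan.extend([label] * quota)
    plan_i = 0

    def next_section() -> Optional[str]:
        nonlocal plan_i
        if plan_i < len(section_plan):
            plan_i += 1
            return section_plan[plan_i - 1]
        return None

    exp_keys, exp_p = _weights(cfg, cfg.connectives)
    imp_inventory = cfg.implicit_connectives or cfg.connectives
    imp_keys, imp_p = _weights(cfg, imp_inventory)
    alt_inventory = cfg.altlex_connectives or cfg.connectives
    alt_keys, alt_p = _weights(cfg, alt_inventory)

    for _ in range(cfg.n_relations.get("Explicit", 0)):
        conn = exp_keys[int(rng.choice(len(exp_keys), p=exp_p))]
        sense1 = _draw(rng, cfg.connectives[conn])
        sense2 = _draw_sense2(rng, cfg, sense1, taxonomy)
        builder.add_explicit(conn, sense1, sense2, next_section(), rng)
    for _ in range(cfg.n_relations.get("Implicit", 0)):
        conn = imp_keys[int(rng.choice(len(imp_keys), p=imp_p))]
        sense1 = _draw(rng, imp_inventory[conn])
        if taxonomy.normalize(sense1).stype in _NONE_SENSE_TYPES:
            conn = NONE_CONNECTIVE
        builder.add_implicit(conn, sense1, next_section(), rng)
    for _ in range(cfg.n_relations.get("AltLex", 0)):
        conn = alt_keys[int(rng.choice(len(alt_keys), p=alt_p))]
        sense1 = _draw(rng, alt_inventory[conn])
        sense2 = _draw_sense2(rng, cfg, sense1, taxonomy)
        builder.add_altlex(conn, sense1, sense2, next_section(), rng)
    for _ in range(cfg.n_relations.get("NoRel", 0)):
        builder.add_norel(next_section(), rng)
    return builder.build()


# ---------------------------------------------------------------------------
# Annotator perturbation


def _jitter_spanset(
    spans: SpanSet, rng: np.random.Generator, max_w: int, text_len: int
) -> SpanSet:
    """Shift each span's endpoints by a nonzero amount, redrawing any
    draw that would produce an empty, out-of-bounds, or overlapping span;
    gives up (keeps the original span) after a bounded number of tries."""
    new: list[CharSpan] = []
    for i, sp in enumerate(spans):
        lo = new[-1].end if new else 0
        hi = spans.spans[i + 1].start if i + 1 < len(spans) else text_len
        candidate = sp
        for _ in range(20):
            ds = int(rng.integers(-max_w, max_w + 1))
            de = int(rng.integers(-max_w, max_w + 1))
            s, e = sp.start + ds, sp.end + de
            if (ds, de) != (0, 0) and lo <= s < e <= hi:
                candidate = CharSpan(s, e)
                break
        new.append(candidate)
    return SpanSet(new)


def perturb_annotations(
    corpus: AnnotatedCorpus, cfg: PerturbConfig
) -> AnnotatedCorpus:
    """Derive a second-annotator corpus by seeded record deletion,
    spurious insertion, argument-span jitter, and sense confusion."""
    rng = np.random.default_rng(cfg.seed)
    labels_pool = sorted(
        {str(r.sense1) for r in corpus.iter_records() if r.sense1 is not None}
    )
    taxonomy = build_taxonomy()
    out = AnnotatedCorpus()
    for doc_id, doc in corpus.documents.items():
        records: list[RelationRecord] = []
        for rec in doc.records:
            if cfg.delete_prob and rng.random() < cfg.delete_prob:
                continue
            new = copy.deepcopy(rec)
            if cfg.jitter_prob:
                if rng.random() < cfg.jitter_prob:
                    new.arg1_spans = _jitter_spanset(
                        new.arg1_spans, rng, cfg.jitter_max, len(doc.text)
                    )
                if rng.random() < cfg.jitter_prob:
                    # AltLex Arg2 must keep containing the expression span
                    for _ in range(20):
                        jittered = _jitter_spanset(
                            new.arg2_spans, rng, cfg.jitter_max, len(doc.text)
                        )
                        if (
                            new.rel_type != "AltLex"
                            or new.conn_spans is None
                            or jittered.contains(new.conn_spans)
                        ):
                            new.arg2_spans = jittered
                            break
            if new.sense1 is not None:
                new.sense1 = _confuse(new.sense1, cfg, rng, labels_pool, taxonomy)
            records.append(new)
            if cfg.insert_prob and rng.random() < cfg.insert_prob:
                spurious = _spurious_record(doc.text, rng, labels_pool, taxonomy)
                if spurious is not None:
                    spurious.doc_id = doc_id
                    records.append(spurious)
        out.add(doc_id, doc.text, records)
    return out


def _confuse(
    sense: SenseLabel,
    cfg: PerturbConfig,
    rng: np.random.Generator,
    pool: Sequence[str],
    taxonomy: SenseTaxonomy,
) -> SenseLabel:
    if cfg.confusion is not None:
        row = cfg.confusion.get(str(sense))
        if row is None:
            return sense
        return taxonomy.normalize(_draw(rng, row))
    if cfg.confusion_rate and rng.random() < cfg.confusion_rate:
        others = [l for l in pool if l != str(sense)]
        if others:
            return taxonomy.normalize(others[int(rng.integers(len(others)))])
    return sense


def _spurious_record(
    text: str,
    rng: np.random.Generator,
    labels_pool: Sequence[str],
    taxonomy: SenseTaxonomy,
) -> Optional[RelationRecord]:
    if len(text) < 80:
        return None
    i = int(rng.integers(0, len(text) - 80))
    label = labels_pool[int(rng.integers(len(labels_pool)))] if labels_pool else "Conjunction"
    return RelationRecord(
        rel_type="Explicit",
        conn_spans=SpanSet([CharSpan(i, i + 4)]),
        sense1=taxonomy.normalize(label),
        arg1_spans=SpanSet([CharSpan(i + 5, i + 40)]),
        arg2_spans=SpanSet([CharSpan(i + 41, i + 78)]),
    )


# ---------------------------------------------------------------------------
# Deterministic table fixtures


def fixture_from_tables(table: int) -> AnnotatedCorpus:
    """Deterministic corpus reproducing one published summary table.

    ``3``: relation-type token and unique-expression-type counts.
    ``4``: per-sense counts by relation type, incl. multi-sense rows.
    ``5``: contextual-ambiguity inventory of explicit connectives.
    ``12``: type-level sense counts per rhetorical segment (published
    cells verbatim; two published row totals disagree with their cells
    and are deliberately not repaired).
    """
    if table == 3:
        return _fixture_table3()
    if table == 4:
        return _fixture_table4()
    if table == 5:
        return _fixture_table5()
    if table == 12:
        return _fixture_table12()
    raise ValueError(f"no fixture for table {table}; choose 3, 4, 5, or 12")


def _fixture_table3() -> AnnotatedCorpus:
    b = _CorpusBuilder(doc_size=1000)
    n_exp, t_exp = tables.RELATION_TYPE_TABLE["Explicit"]
    for i in range(n_exp):
        b.add_explicit(f"xconn{i % t_exp}", "Conjunction")
    n_imp, t_imp = tables.RELATION_TYPE_TABLE["Implicit"]
    for i in range(n_imp):
        b.add_implicit(f"iconn{i % t_imp}", "Conjunction")
    n_alt, t_alt = tables.RELATION_TYPE_TABLE["AltLex"]
    for i in range(n_alt):
        b.add_altlex(f"aconn{i % t_alt}", "Cause")
    for _ in range(tables.RELATION_TYPE_TABLE["NoRel"][0]):
        b.add_norel()
    return b.build()


def _fixture_table4() -> AnnotatedCorpus:
    b = _CorpusBuilder(doc_size=1000)
    for sense, (n_exp, n_imp, n_alt) in tables.SENSE_TABLE_SINGLE.items():
        tag = sense.lower()
        for _ in range(n_exp):
            b.add_explicit(f"c-{tag}", sense)
        imp_conn = NONE_CONNECTIVE if sense in _NONE_SENSE_TYPES else f"i-{tag}"
        for _ in range(n_imp):
            b.add_implicit(imp_conn, sense)
        for _ in range(n_alt):
            b.add_altlex(f"a-{tag}", sense)
    for (s1, s2), (n_exp, n_alt) in tables.SENSE_TABLE_MULTI.items():
        tag = f"{s1.lower()}-{s2.lower()}"
        for _ in range(n_exp):
            b.add_explicit(f"c-{tag}", s1, s2)
        for _ in range(n_alt):
            b.add_altlex(f"a-{tag}", s1, s2)
    return b.build()


def _fixture_table5() -> AnnotatedCorpus:
    b = _CorpusBuilder(doc_size=1000)
    for conn, (senses, n_tokens) in tables.AMBIGUITY_TABLE.items():
        for j in range(n_tokens):
            sense = senses[j] if j < len(senses) else senses[0]
            b.add_explicit(conn, sense)
    return b.build()


def _fixture_table12() -> AnnotatedCorpus:
    from .corpus_stats import IMRAD_SEGMENTS

    b = _CorpusBuilder(doc_size=1000)
    for sense, cells in tables.IMRAD_TABLE.items():
        for segment, count in zip(IMRAD_SEGMENTS, cells):
            for _ in range(count):
                b.add_explicit(f"c-{sense.lower()}", sense, section=segment)
    return b.build()


# ---------------------------------------------------------------------------
# Closed-form classifier oracle


def closed_form_bayes_rate(
    cfg: SynthConfig,
    granularity: str = "class",
    mapping: Optional[ClassMapping] = None,
    taxonomy: Optional[SenseTaxonomy] = None,
) -> float:
    """Best achievable accuracy of any per-connective constant predictor
    on first-sense instances drawn from ``cfg``:
    ``sum_c p(c) * max_label p(label | c)`` at the chosen granularity."""
    if granularity not in ("class", "type", "leaf"):
        raise ValueError(f"unknown granularity {granularity!r}")
    mapping = mapping or build_class_mapping()
    taxonomy = taxonomy or build_taxonomy()
    keys, probs = _weights(cfg, cfg.connectives)
    total = 0.0
    for conn, p_conn in zip(keys, probs):
        agg: dict[str, float] = {}
        for label, p in cfg.connectives[conn].items():
            sense = taxonomy.normalize(label)
            if granularity == "class":
                key = mapping[sense.stype]
            elif granularity == "type":
                key = sense.stype
            else:
                key = sense.leaf
            agg[key] = agg.get(key, 0.0) + p
        total += p_conn * max(agg.values())
    return float(total)
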