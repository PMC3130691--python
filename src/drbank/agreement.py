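"""Inter-annotator agreement: token overlap, argument-span match, and
Cohen's kappa for sense labels.

Connective/AltLex identification agreement is the number of one-to-one
matched (overlapping) tokens over the union of both annotators' tokens.
Argument and sense agreement are computed only over matched pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .model import RelationRecord, SpanSet

__all__ = [
    "OverlapAgreement",
    "KappaResult",
    "match_connectives",
    "match_implicit_records",
    "argument_agreement",
    "sense_observed_agreement",
    "cohens_kappa",
    "kappa_from_rates",
]


@dataclass(frozen=True)
class OverlapAgreement:
    """Counts of matched tokens between two annotators' token sets."""

    n_a: int
    n_b: int
    n_common: int

    @property
    def n_union(self) -> int:
        return self.n_a + self.n_b - self.n_common

    @property
    def ratio(self) -> float:
        if self.n_union == 0:
            return 1.0  # two empty annotations agree vacuously
        return self.n_common / self.n_union


@dataclass(frozen=True)
class KappaResult:
    observed: float
    expected: float

    @property
    def kappa(self) -> float:
        return kappa_from_rates(self.observed, self.expected)


def kappa_from_rates(ao: float, ae: float) -> float:
    """Chance-corrected agreement ``(Ao - Ae) / (1 - Ae)``."""
    if not 0.0 <= ao <= 1.0:
        raise ValueError(f"observed agreement outside [0, 1]: {ao}")
    if not 0.0 <= ae < 1.0:
        raise ValueError(f"expected agreement must be in [0, 1): {ae}")
    return (ao - ae) / (1.0 - ae)


def _overlap_size(a: SpanSet, b: SpanSet) -> int:
    total = 0
    for sa in a:
        for sb in b:
            total += max(0, min(sa.end, sb.end) - max(sa.start, sb.start))
    return total


def match_connectives(
    set_a: Sequence[SpanSet],
    set_b: Sequence[SpanSet],
    exhaustive: bool = False,
) -> tuple[list[tuple[int, int]], OverlapAgreement]:
    """One-to-one pairing of tokens whose spans share >=1 character.

    Default strategy pairs greedily in text order, preferring the larger
    character overlap; ``exhaustive=True`` computes a maximum bipartite
    matching instead (used as a testing oracle and for adversarial span
    layouts). Returns the index pairs and the overlap agreement counts.
    """
    if exhaustive:
        pairs = _exhaustive_pairs(set_a, set_b)
    else:
        pairs = _greedy_pairs(set_a, set_b)
    agg = OverlapAgreement(n_a=len(set_a), n_b=len(set_b), n_common=len(pairs))
    return pairs, agg


def _greedy_pairs(
    set_a: Sequence[SpanSet], set_b: Sequence[SpanSet]
) -> list[tuple[int, int]]:
    order_a = sorted(range(len(set_a)), key=lambda i: (set_a[i].start, set_a[i].end))
    used_b: set[int] = set()
    pairs = []
    for i in order_a:
        best: Optional[int] = None
        best_key = (0, 0)
        for j, sb in enumerate(set_b):
            if j in used_b or not set_a[i].overlaps(sb):
                continue
            key = (_overlap_size(set_a[i], sb), -sb.start)
            if best is None or key > best_key:
                best, best_key = j, key
        if best is not None:
            used_b.add(best)
            pairs.append((i, best))
    return pairs


def _exhaustive_pairs(
    set_a: Sequence[SpanSet], set_b: Sequence[SpanSet]
) -> list[tuple[int, int]]:
    rows, cols = [], []
    for i, j in itertools.product(range(len(set_a)), range(len(set_b))):
        if set_a[i].overlaps(set_b[j]):
            rows.append(i)
            cols.append(j)
    if not rows:
        return []
    graph = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(set_a), len(set_b))
    )
    match = maximum_bipartite_matching(graph, perm_type="column")
    return [(i, int(j)) for i, j in enumerate(match) if j >= 0]


def match_implicit_records(
    recs_a: Sequence[RelationRecord], recs_b: Sequence[RelationRecord]
) -> list[tuple[RelationRecord, RelationRecord]]:
    """Pair implicit relations by their Arg2 start-offset identifier."""
    by_loc = {r.arg2_spans.start: r for r in recs_b}
    pairs = []
    for ra in recs_a:
        rb = by_loc.get(ra.arg2_spans.start)
        if rb is not None:
            pairs.append((ra, rb))
    return pairs


def argument_agreement(
    pairs: Sequence[tuple[RelationRecord, RelationRecord]],
    which: str = "arg1",
    criterion: str = "exact",
) -> float:
    """Fraction of matched pairs agreeing on an argument span.

    ``exact`` requires identical covered character positions; ``partial``
    requires at least one shared character.
    """
    if which not in ("arg1", "arg2"):
        raise ValueError(f"which must be 'arg1' or 'arg2', got {which!r}")
    if criterion not in ("exact", "partial"):
        raise ValueError(f"criterion must be 'exact' or 'partial', got {criterion!r}")
    if not pairs:
        raise ValueError("agreement ratio undefined over an empty pair list")
    attr = f"{which}_spans"
    n_agree = 0
    for ra, rb in pairs:
        sa: SpanSet = getattr(ra, attr)
        sb: SpanSet = getattr(rb, attr)
        if criterion == "exact":
            n_agree += sa.coverage() == sb.coverage()
        else:
            n_agree += sa.overlaps(sb)
    return n_agree / len(pairs)


def sense_observed_agreement(
    pairs: Sequence[tuple[RelationRecord, RelationRecord]]
) -> float:
    """Observed sense agreement: a pair agrees when the annotators share
    at least one sense label, at leaf granularity."""
    if not pairs:
        raise ValueError("sense agreement undefined over an empty pair list")
    n_agree = 0
    for ra, rb in pairs:
        if ra.sense1 is None or rb.sense1 is None:
            raise ValueError("sense agreement requires sense1 on both records")
        labels_a = {s.leaf for s in ra.senses()}
        labels_b = {s.leaf for s in rb.senses()}
        n_agree += bool(labels_a & labels_b)
    return n_agree / len(pairs)


def cohens_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> KappaResult:
    """Cohen's kappa from two aligned label sequences.

    Expected agreement uses per-annotator marginals:
    ``Ae = sum_k pA(k) * pB(k)``.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label lists differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    n = len(labels_a)
    if n == 0:
        raise ValueError("kappa undefined for empty label lists")
    ao = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    cats = sorted(set(labels_a) | set(labels_b))
    pa = np.array([sum(l == c for l in labels_a) for c in cats], dtype=float) / n
    pb = np.array([sum(l == c for l in labels_b) for c in cats], dtype=float) / n
    ae = float(pa @ pb)
    if ae >= 1.0:
        raise ValueError(
            "degenerate kappa: both annotators constant with identical marginals"
        )
    return KappaResult(observed=ao, expected=ae)
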