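"""Connective-string-only sense classification.

The sole predictive feature is the lowercased connective surface string.
With one categorical feature, a confidence-rated rule learner reduces to
a per-connective majority vote with a global-majority fallback, which is
Bayes-optimal within the hypothesis class of per-connective constant
predictions; that surrogate is what is implemented here.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import AnnotatedCorpus, ClassMapping, SenseLabel, build_class_mapping
from .standoff import extract_text

__all__ = [
    "Instance",
    "ScenarioConfig",
    "RuleModel",
    "EvalResult",
    "LearningCurveConfig",
    "build_instances",
    "train_rules",
    "evaluate",
    "cross_validate",
    "learning_curve",
    "cross_domain_eval",
]


@dataclass(frozen=True)
class Instance:
    """One training/evaluation item: connective string and sense label."""

    feature: str
    label: str

    def __post_init__(self) -> None:
        if not self.feature:
            raise ValueError("instance feature must be non-empty")


@dataclass(frozen=True)
class ScenarioConfig:
    """Which sense slot feeds the labels, and at which granularity.

    ``sense_slot``: ``first`` uses sense1 of every explicit relation;
    ``second`` uses sense2 when present, else sense1; ``both`` yields one
    instance per relation plus an extra instance for each second sense.
    ``granularity``: ``class`` collapses types onto the 4 generalized
    classes, ``type`` keeps type-level senses.
    """

    sense_slot: str = "first"
    granularity: str = "class"

    def __post_init__(self) -> None:
        if self.sense_slot not in ("first", "second", "both"):
            raise ValueError(f"unknown sense slot {self.sense_slot!r}")
        if self.granularity not in ("class", "type"):
            raise ValueError(f"unknown granularity {self.granularity!r}")


@dataclass
class RuleModel:
    """Per-connective majority rules plus a global-majority fallback."""

    rules: dict[str, str]
    confidences: dict[str, float]
    fallback: str

    def predict(self, feature: str) -> str:
        return self.rules.get(feature, self.fallback)


@dataclass
class EvalResult:
    accuracy: float
    per_class: dict[str, tuple[float, float, float]]  # label -> (P, R, F1)
    macro_f1: float
    never_predicted: tuple[str, ...] = ()


@dataclass(frozen=True)
class LearningCurveConfig:
    train_size: int
    test_size: int
    increment: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.increment <= 0 or self.train_size % self.increment != 0:
            raise ValueError(
                f"increment {self.increment} must divide the training pool "
                f"size {self.train_size}"
            )


def normalize_connective(text: str) -> str:
    return " ".join(text.lower().split())


def _label_at(
    sense: SenseLabel, granularity: str, mapping: ClassMapping
) -> str:
    return mapping[sense.stype] if granularity == "class" else sense.stype


def build_instances(
    corpus: AnnotatedCorpus,
    cfg: ScenarioConfig = ScenarioConfig(),
    mapping: Optional[ClassMapping] = None,
) -> list[Instance]:
    """Extract labeled instances from all explicit relations of a corpus."""
    mapping = mapping or build_class_mapping()
    out: list[Instance] = []
    for doc in corpus.documents.values():
        for rec in doc.records:
            if rec.rel_type != "Explicit":
                continue
            if rec.sense1 is None:
                raise ValueError(
                    f"explicit relation without sense1 in document {rec.doc_id!r}"
                )
            conn = normalize_connective(extract_text(doc.text, rec.conn_spans))
            first = _label_at(rec.sense1, cfg.granularity, mapping)
            second = (
                _label_at(rec.sense2, cfg.granularity, mapping)
                if rec.sense2 is not None
                else None
            )
            if cfg.sense_slot == "first":
                out.append(Instance(conn, first))
            elif cfg.sense_slot == "second":
                out.append(Instance(conn, second if second is not None else first))
            else:  # both
                out.append(Instance(conn, first))
                if second is not None:
                    out.append(Instance(conn, second))
    return out


def _majority(counter: Counter, priors: Counter) -> str:
    # Most frequent; ties broken by higher global prior, then label order.
    return min(counter, key=lambda lbl: (-counter[lbl], -priors[lbl], lbl))


def train_rules(train: Sequence[Instance]) -> RuleModel:
    """Fit per-connective majority rules; confidence is the training
    relative frequency of the winning label for that connective."""
    if not train:
        raise ValueError("cannot train on an empty instance list")
    priors = Counter(inst.label for inst in train)
    by_conn: dict[str, Counter] = defaultdict(Counter)
    for inst in train:
        by_conn[inst.feature][inst.label] += 1
    rules, confidences = {}, {}
    for conn, counter in by_conn.items():
        winner = _majority(counter, priors)
        rules[conn] = winner
        confidences[conn] = counter[winner] / sum(counter.values())
    fallback = _majority(priors, priors)
    return RuleModel(rules=rules, confidences=confidences, fallback=fallback)


def evaluate(model: RuleModel, test: Sequence[Instance]) -> EvalResult:
    """Accuracy plus per-label precision/recall/F1 and macro-F1 over the
    union of gold and predicted labels. A label never predicted gets
    precision 0 by convention and is flagged."""
    if not test:
        raise ValueError("cannot evaluate on an empty test set")
    gold = [inst.label for inst in test]
    pred = [model.predict(inst.feature) for inst in test]
    labels = sorted(set(gold) | set(pred))
    per_class: dict[str, tuple[float, float, float]] = {}
    never = []
    for lbl in labels:
        tp = sum(g == lbl and p == lbl for g, p in zip(gold, pred))
        n_pred = sum(p == lbl for p in pred)
        n_gold = sum(g == lbl for g in gold)
        if n_pred == 0:
            never.append(lbl)
        prec = tp / n_pred if n_pred else 0.0
        rec = tp / n_gold if n_gold else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        per_class[lbl] = (prec, rec, f1)
    accuracy = sum(g == p for g, p in zip(gold, pred)) / len(test)
    macro_f1 = float(np.mean([f for _, _, f in per_class.values()]))
    return EvalResult(
        accuracy=accuracy,
        per_class=per_class,
        macro_f1=macro_f1,
        never_predicted=tuple(never),
    )


def cross_validate(
    instances: Sequence[Instance], k: int = 10, seed: int = 0
) -> EvalResult:
    """k-fold cross-validation with a seeded uniform (non-stratified)
    random partition; metrics are averaged over folds."""
    if k < 2:
        raise ValueError(f"need at least 2 folds, got {k}")
    if len(instances) < k:
        raise ValueError(f"{len(instances)} instances cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(instances))
    folds = np.array_split(order, k)
    results = []
    for fold in folds:
        test_idx = set(fold.tolist())
        train = [instances[i] for i in order if i not in test_idx]
        test = [instances[i] for i in fold]
        results.append(evaluate(train_rules(train), test))
    return _mean_results(results)


def _mean_results(results: Sequence[EvalResult]) -> EvalResult:
    accuracy = float(np.mean([r.accuracy for r in results]))
    macro_f1 = float(np.mean([r.macro_f1 for r in results]))
    labels = sorted({lbl for r in results for lbl in r.per_class})
    per_class = {}
    for lbl in labels:
        rows = [r.per_class[lbl] for r in results if lbl in r.per_class]
        per_class[lbl] = tuple(float(np.mean(col)) for col in zip(*rows))
    never = tuple(sorted({lbl for r in results for lbl in r.never_predicted}))
    return EvalResult(accuracy, per_class, macro_f1, never)


def learning_curve(
    instances: Sequence[Instance], cfg: LearningCurveConfig
) -> list[tuple[int, float]]:
    """Accuracy at nested training-set sizes against one fixed test set.

    A seeded shuffle carves a held-out test set of ``test_size`` and a
    training pool of ``train_size``; accuracies are reported at pool
    prefixes of size increment, 2*increment, ..., train_size.
    """
    if cfg.train_size + cfg.test_size > len(instances):
        raise ValueError(
            f"train_size + test_size = {cfg.train_size + cfg.test_size} exceeds "
            f"{len(instances)} available instances"
        )
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(instances))
    test = [instances[i] for i in order[: cfg.test_size]]
    pool = [instances[i] for i in order[cfg.test_size : cfg.test_size + cfg.train_size]]
    curve = []
    for n in range(cfg.increment, cfg.train_size + 1, cfg.increment):
        model = train_rules(pool[:n])
        curve.append((n, evaluate(model, test).accuracy))
    return curve


def cross_domain_eval(
    train_corpus: AnnotatedCorpus,
    test_corpus: AnnotatedCorpus,
    mapping: Optional[ClassMapping] = None,
    cfg: ScenarioConfig = ScenarioConfig(sense_slot="first", granularity="class"),
) -> EvalResult:
    """Train on every instance of one corpus, evaluate on the other."""
    mapping = mapping or build_class_mapping()
    train = build_instances(train_corpus, cfg, mapping)
    test = build_instances(test_corpus, cfg, mapping)
    return evaluate(train_rules(train), test)
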