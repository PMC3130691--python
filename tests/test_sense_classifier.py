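import math

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from drbank.model import build_class_mapping
from drbank.sense_classifier import (
    Instance,
    LearningCurveConfig,
    RuleModel,
    ScenarioConfig,
    build_instances,
    cross_domain_eval,
    cross_validate,
    evaluate,
    learning_curve,
    train_rules,
)
from drbank.synthesis import (
    SynthConfig,
    closed_form_bayes_rate,
    fixture_from_tables,
    generate_corpus,
)

MAPPING = build_class_mapping()


@pytest.fixture(scope="module")
def table4_corpus():
    return fixture_from_tables(4)


class TestBuildInstances:
    def test_first_sense_total(self, table4_corpus):
        assert len(build_instances(table4_corpus, ScenarioConfig("first", "class"))) == 2636

    def test_both_senses_total(self, table4_corpus):
        assert len(build_instances(table4_corpus, ScenarioConfig("both", "class"))) == 2831

    def test_second_sense_total_unchanged(self, table4_corpus):
        inst = build_instances(table4_corpus, ScenarioConfig("second", "class"))
        assert len(inst) == 2636

    def test_second_falls_back_to_first(self):
        cfg = SynthConfig(
            n_relations={"Explicit": 1},
            connectives={"but": {"Contrast": 1.0}},
            seed=0,
        )
        corpus = generate_corpus(cfg)
        inst = build_instances(corpus, ScenarioConfig("second", "class"))
        assert [i.label for i in inst] == ["Comparison"]

    def test_class_vs_type_granularity(self, table4_corpus):
        by_class = build_instances(table4_corpus, ScenarioConfig("first", "class"))
        by_type = build_instances(table4_corpus, ScenarioConfig("first", "type"))
        assert {i.label for i in by_class} <= {
            "Comparison",
            "Contingency",
            "Temporal",
            "Expansion",
        }
        assert "Cause" in {i.label for i in by_type}

    def test_feature_is_lowercased_surface_string(self, table4_corpus):
        feats = {i.feature for i in build_instances(table4_corpus)}
        assert all(f == f.lower() for f in feats)

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig("third", "class")
        with pytest.raises(ValueError):
            ScenarioConfig("first", "leaf")

    def test_empty_feature_rejected(self):
        with pytest.raises(ValueError):
            Instance("", "Expansion")


class TestTrainRules:
    def test_unanimous_connective(self):
        model = train_rules([Instance("because", "Contingency")] * 10)
        assert model.rules["because"] == "Contingency"
        assert model.confidences["because"] == 1.0

    def test_majority_vote_ambiguous_connective(self):
        train = [Instance("since", "Contingency")] * 30 + [
            Instance("since", "Temporal")
        ] * 22
        model = train_rules(train)
        assert model.rules["since"] == "Contingency"
        assert model.confidences["since"] == pytest.approx(30 / 52)

    def test_unseen_connective_uses_fallback(self):
        model = train_rules(
            [Instance("but", "Comparison")] * 3 + [Instance("so", "Contingency")] * 5
        )
        assert model.predict("meanwhile") == "Contingency"

    def test_tie_broken_by_global_prior(self):
        train = (
            [Instance("while", "Temporal")] * 5
            + [Instance("while", "Comparison")] * 5
            + [Instance("but", "Comparison")] * 3
        )
        model = train_rules(train)
        assert model.rules["while"] == "Comparison"  # higher global prior

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            train_rules([])


class TestEvaluate:
    def test_all_correct(self):
        model = RuleModel(rules={"a": "X"}, confidences={"a": 1.0}, fallback="X")
        res = evaluate(model, [Instance("a", "X")] * 4)
        assert res.accuracy == 1.0
        assert res.macro_f1 == 1.0

    def test_hand_computed_confusion_matrix(self):
        # confusion [[3,1],[2,4]]: gold X pred (X,X,X,Y); gold Y pred (X,X,Y,Y,Y,Y)
        model = RuleModel(
            rules={f"f{i}": p for i, p in enumerate("XXXYXXYYYY")},
            confidences={},
            fallback="X",
        )
        test = [Instance(f"f{i}", g) for i, g in enumerate("XXXXYYYYYY")]
        res = evaluate(model, test)
        assert res.accuracy == pytest.approx(0.7)
        p_x, r_x, f_x = res.per_class["X"]
        assert (p_x, r_x) == (pytest.approx(3 / 5), pytest.approx(3 / 4))
        assert f_x == pytest.approx(2 * (3 / 5) * (3 / 4) / (3 / 5 + 3 / 4))
        p_y, r_y, f_y = res.per_class["Y"]
        assert (p_y, r_y) == (pytest.approx(4 / 5), pytest.approx(4 / 6))
        assert res.macro_f1 == pytest.approx((f_x + f_y) / 2)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(5)
        labels = ["Comparison", "Contingency", "Temporal", "Expansion"]
        gold = [labels[i] for i in rng.integers(0, 4, 300)]
        pred = [labels[i] for i in rng.integers(0, 4, 300)]
        model = RuleModel(
            rules={f"f{i}": p for i, p in enumerate(pred)}, confidences={}, fallback="X"
        )
        test = [Instance(f"f{i}", g) for i, g in enumerate(gold)]
        res = evaluate(model, test)
        p, r, f, _ = precision_recall_fscore_support(
            gold, pred, labels=labels, zero_division=0
        )
        for lbl, pi, ri, fi in zip(labels, p, r, f):
            assert res.per_class[lbl] == (
                pytest.approx(pi),
                pytest.approx(ri),
                pytest.approx(fi),
            )

    def test_never_predicted_class_flagged(self):
        model = RuleModel(rules={}, confidences={}, fallback="X")
        res = evaluate(model, [Instance("a", "X"), Instance("b", "Y")])
        assert "Y" in res.never_predicted
        assert res.per_class["Y"][0] == 0.0  # precision 0 by convention

    def test_accuracy_equals_micro_recall(self):
        rng = np.random.default_rng(7)
        gold = [str(i % 3) for i in range(60)]
        pred = [str(int(i)) for i in rng.integers(0, 3, 60)]
        model = RuleModel(
            rules={f"f{i}": p for i, p in enumerate(pred)}, confidences={}, fallback="0"
        )
        res = evaluate(model, [Instance(f"f{i}", g) for i, g in enumerate(gold)])
        micro_recall = sum(g == p for g, p in zip(gold, pred)) / len(gold)
        assert res.accuracy == pytest.approx(micro_recall)
        assert res.macro_f1 <= max(f for _, _, f in res.per_class.values())

    def test_empty_test_set(self):
        model = RuleModel(rules={}, confidences={}, fallback="X")
        with pytest.raises(ValueError):
            evaluate(model, [])


class TestCrossValidate:
    def test_deterministic_corpus_perfect(self):
        cfg = SynthConfig(
            n_relations={"Explicit": 1000},
            connectives={
                "because": {"Cause.Reason": 1.0},
                "but": {"Contrast": 1.0},
                "meanwhile": {"Temporal.Synchronous": 1.0},
                "moreover": {"Conjunction": 1.0},
                "so that": {"Purpose.Goal": 1.0},
            },
            seed=21,
        )
        inst = build_instances(generate_corpus(cfg))
        res = cross_validate(inst, k=10, seed=2)
        assert res.accuracy == 1.0

    def test_accuracy_near_closed_form_optimum(self):
        cfg = SynthConfig(
            n_relations={"Explicit": 4000},
            connectives={
                "a": {"Cause.Reason": 0.8, "Temporal.Succession": 0.2},
                "b": {"Conjunction": 1.0},
                "c": {"Contrast": 0.7, "Conjunction": 0.3},
                "d": {"Temporal.Precedence": 0.9, "Cause.Result": 0.1},
            },
            seed=13,
        )
        corpus = generate_corpus(cfg)
        inst = build_instances(corpus)
        res = cross_validate(inst, k=10, seed=3)
        bayes = closed_form_bayes_rate(cfg, "class")
        se = math.sqrt(bayes * (1 - bayes) / len(inst))
        assert abs(res.accuracy - bayes) <= 3 * se

    def test_fallback_only_model_equals_majority_prior(self):
        # degenerate model that never saw any test connective
        train = [Instance("zzz", "Expansion")] * 6 + [Instance("zzz", "Temporal")] * 4
        model = train_rules(train)
        test = [Instance("unseen", "Expansion")] * 7 + [
            Instance("unseen", "Temporal")
        ] * 3
        assert evaluate(model, test).accuracy == pytest.approx(0.7)

    def test_too_few_instances(self):
        with pytest.raises(ValueError):
            cross_validate([Instance("a", "X")] * 3, k=10)
        with pytest.raises(ValueError):
            cross_validate([Instance("a", "X")] * 30, k=1)

    def test_seed_reproducibility(self):
        inst = [Instance(f, l) for f, l in zip("abcab" * 20, "XYXXY" * 20)]
        r1 = cross_validate(inst, k=5, seed=42)
        r2 = cross_validate(inst, k=5, seed=42)
        assert r1.accuracy == r2.accuracy


class TestLearningCurve:
    def test_reaches_one_on_deterministic_data(self):
        cfg = SynthConfig(
            n_relations={"Explicit": 600},
            connectives={
                "because": {"Cause.Reason": 1.0},
                "but": {"Contrast": 1.0},
            },
            seed=8,
        )
        inst = build_instances(generate_corpus(cfg))
        curve = learning_curve(
            inst, LearningCurveConfig(train_size=500, test_size=100, increment=50, seed=1)
        )
        assert len(curve) == 10
        assert curve[-1][1] == 1.0
        assert [n for n, _ in curve] == list(range(50, 501, 50))

    def test_plateaus_at_bayes_rate(self):
        cfg = SynthConfig(
            n_relations={"Explicit": 3000},
            connectives={
                "a": {"Cause.Reason": 0.75, "Temporal.Succession": 0.25},
                "b": {"Conjunction": 0.9, "Contrast": 0.1},
            },
            seed=17,
        )
        inst = build_instances(generate_corpus(cfg))
        curve = learning_curve(
            inst,
            LearningCurveConfig(train_size=2500, test_size=500, increment=250, seed=2),
        )
        bayes = closed_form_bayes_rate(cfg, "class")
        se = math.sqrt(bayes * (1 - bayes) / 500)
        assert abs(curve[-1][1] - bayes) <= 3 * se

    def test_increment_must_divide_pool(self):
        with pytest.raises(ValueError):
            LearningCurveConfig(train_size=100, test_size=10, increment=33)

    def test_sizes_must_fit(self):
        inst = [Instance("a", "X")] * 50
        with pytest.raises(ValueError):
            learning_curve(
                inst, LearningCurveConfig(train_size=60, test_size=10, increment=10)
            )


class TestCrossDomain:
    def test_same_corpus_is_resubstitution(self, table4_corpus):
        res = cross_domain_eval(table4_corpus, table4_corpus, MAPPING)
        inst = build_instances(table4_corpus)
        resub = evaluate(train_rules(inst), inst)
        assert res.accuracy == resub.accuracy

    def test_disjoint_vocabulary_pure_fallback(self):
        train_cfg = SynthConfig(
            n_relations={"Explicit": 200},
            connectives={"p": {"Conjunction": 0.7, "Contrast": 0.3}},
            seed=1,
        )
        test_cfg = SynthConfig(
            n_relations={"Explicit": 200},
            connectives={"q": {"Cause.Reason": 0.6, "Temporal.Precedence": 0.4}},
            seed=2,
        )
        train_c, test_c = generate_corpus(train_cfg), generate_corpus(test_cfg)
        res = cross_domain_eval(train_c, test_c, MAPPING)
        # training majority is Expansion; accuracy = its prior in the test set
        test_inst = build_instances(test_c, mapping=MAPPING)
        prior = sum(i.label == "Expansion" for i in test_inst) / len(test_inst)
        assert res.accuracy == pytest.approx(prior)

    def test_shifted_conditionals_transfer_accuracy(self):
        p = {"k": {"Cause.Reason": 0.8, "Temporal.Precedence": 0.2}}
        q = {"k": {"Cause.Reason": 0.3, "Temporal.Precedence": 0.7}}
        train_c = generate_corpus(
            SynthConfig(n_relations={"Explicit": 3000}, connectives=p, seed=5)
        )
        test_c = generate_corpus(
            SynthConfig(n_relations={"Explicit": 3000}, connectives=q, seed=6)
        )
        res = cross_domain_eval(train_c, test_c, MAPPING)
        # train argmax is Contingency; transfer accuracy = q(Contingency|k) = 0.3
        se = math.sqrt(0.3 * 0.7 / 3000)
        assert abs(res.accuracy - 0.3) <= 3 * se
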