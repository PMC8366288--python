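"""Key phrases, relations, rule evaluation and corpus labeling."""

import numpy as np
import pytest

from medinq.preprocessing import RawInquiry, preprocess_corpus
from medinq.rule_engine import (
    CategoryTree,
    Rule,
    RuleSet,
    analyze_sentence,
    evaluate_rule,
    extract_key_phrases,
    label_corpus,
    label_sentence,
    rollup,
)
from tests.conftest import WORKED_EXAMPLE_TEXT, run_pipeline


@pytest.fixture(scope="module")
def worked_sentences(demo, preprocess_config):
    return preprocess_corpus([RawInquiry("w", WORKED_EXAMPLE_TEXT)],
                             preprocess_config)


@pytest.fixture(scope="module")
def worked_analyses(worked_sentences, demo):
    return [
        analyze_sentence(s, demo["lexicon"], demo["nouns"],
                         demo["relation_config"])
        for s in worked_sentences
    ]


class TestKeyPhrases:
    def test_sentence1_phrases(self, worked_sentences, demo):
        phrases = extract_key_phrases(worked_sentences[0], demo["lexicon"],
                                      demo["nouns"])
        assert {p.text for p in phrases} == {
            "any documentation", "allergies", "Product-A"
        }

    def test_sentence3_phrases(self, worked_sentences, demo):
        phrases = extract_key_phrases(worked_sentences[2], demo["lexicon"],
                                      demo["nouns"])
        assert {p.text for p in phrases} == {"MSL"}

    def test_function_words_only(self, demo, preprocess_config):
        sents = preprocess_corpus([RawInquiry("f", "And so it was to be")],
                                  preprocess_config)
        assert extract_key_phrases(sents[0], demo["lexicon"], demo["nouns"]) == []


class TestRelations:
    def test_sentence2_condition_modifies_treatment(self, worked_analyses):
        rels = worked_analyses[1].relations
        hits = [r for r in rels if r.kind == "modifies"
                and getattr(r.source, "entity_type", None) == "Condition"
                and getattr(r.target, "entity_type", None) == "Treatment"]
        assert hits, "expected Condition <modifies> Treatment"

    def test_sentence3_professional_subject_meet(self, worked_analyses):
        rels = worked_analyses[2].relations
        hits = [r for r in rels if r.kind == "subject"
                and getattr(r.source, "entity_type", None) == "Professional"
                and r.target == "meet"]
        assert hits, "expected Professional <subject> meet"

    def test_single_mention_no_cooccur(self, worked_analyses):
        rels = worked_analyses[2].relations
        assert not [r for r in rels if r.kind == "cooccur"]


class TestRuleEvaluation:
    def _rule(self, demo, rule_id):
        return next(r for r in demo["ruleset"] if r.id == rule_id)

    def test_publication_rule_fires_on_sentence1(self, worked_analyses, demo):
        rule = self._rule(demo, "pub-request-available-doc")
        assert evaluate_rule(rule, worked_analyses[0], demo["pairs"])

    def test_safety_rule_fires_on_sentences_1_and_2(self, worked_analyses, demo):
        rule = self._rule(demo, "safety-adverse-pair")
        assert evaluate_rule(rule, worked_analyses[0], demo["pairs"])
        assert evaluate_rule(rule, worked_analyses[1], demo["pairs"])

    def test_safety_rule_rejects_sentence3(self, worked_analyses, demo):
        rule = self._rule(demo, "safety-adverse-pair")
        assert not evaluate_rule(rule, worked_analyses[2], demo["pairs"])

    def test_undeclared_entity_type_is_config_error(self, worked_analyses):
        rule = Rule("bad", 1, "Safety Data",
                    ({"pred": "ENTITY", "type": "Starship"},))
        with pytest.raises(ValueError, match="Starship"):
            evaluate_rule(rule, worked_analyses[0],
                          declared_types={"Condition", "Treatment"})


class TestWorkedExampleLabels:
    def test_prioritization_and_labels(self, worked_analyses, demo):
        """The three-sentence inquiry reproduces its printed labels, with
        Publication Request overruling Safety Data on sentence 1."""
        got = [
            label_sentence(a, demo["ruleset"], demo["pairs"], demo["tree"])
            for a in worked_analyses
        ]
        assert [l.subcategory for l in got] == [
            "Publication Request", "Safety Data", "Meeting Request"
        ]
        # the safety rule also fired on sentence 1; priority decided
        safety = next(r for r in demo["ruleset"] if r.id == "safety-adverse-pair")
        assert evaluate_rule(safety, worked_analyses[0], demo["pairs"])
        pub = next(r for r in demo["ruleset"] if r.id == got[0].rule_id)
        assert pub.priority < safety.priority


class TestRollup:
    @pytest.mark.parametrize(
        "sub, root",
        [("Formulation", "Dosage and Formulation"),
         ("Dosage and Administration", "Dosage and Formulation"),
         ("Publication Request", "Scientific Exchange")],
    )
    def test_known_parents(self, demo, sub, root):
        assert rollup(sub, demo["tree"]) == root

    def test_unknown_subcategory_raises(self, demo):
        with pytest.raises(KeyError):
            rollup("NotALabel", demo["tree"])

    def test_tree_has_23_trainable_subcategories(self, demo):
        assert len(demo["tree"]) == 23
        assert demo["tree"].fallback not in demo["tree"].parents


class TestLabelCorpus:
    def test_worked_example_three_trainable(self, demo, preprocess_config):
        _, ds = run_pipeline([RawInquiry("w", WORKED_EXAMPLE_TEXT)], demo,
                             preprocess_config)
        assert len(ds.trainable) == 3 and not ds.fallback

    def test_no_rule_fires_everything_fallback(self, demo, preprocess_config):
        _, ds = run_pipeline(
            [RawInquiry("c", "Thank you very much for your help.")],
            demo, preprocess_config,
        )
        assert not ds.trainable
        assert [l.subcategory for l in ds.fallback] == [demo["tree"].fallback]
        assert ds.fallback[0].rule_id is None

    def test_exactly_one_label_and_rollup_totality(self, demo,
                                                   preprocess_config):
        from medinq.synthetic import GeneratorConfig, generate_corpus

        corpus = generate_corpus(GeneratorConfig(n_inquiries=60, seed=11))
        _, ds = run_pipeline(corpus.inquiries, demo, preprocess_config)
        tree = demo["tree"]
        for lab in ds.labels:
            if lab.rule_id is None:
                assert lab.subcategory == tree.fallback
            else:
                assert lab.root == rollup(lab.subcategory, tree)
        assert len(ds.trainable) + len(ds.fallback) == len(ds.labels)

    def test_determinism_across_rule_order_permutations(self, demo,
                                                        preprocess_config):
        """Priority, not file order, decides the label."""
        rng = np.random.default_rng(5)
        from medinq.synthetic import GeneratorConfig, generate_corpus

        corpus = generate_corpus(GeneratorConfig(n_inquiries=40, seed=9))
        sents, base = run_pipeline(corpus.inquiries, demo, preprocess_config)
        rules = list(demo["ruleset"].rules)
        for _ in range(3):
            perm = [rules[i] for i in rng.permutation(len(rules))]
            shuffled = RuleSet(perm)
            ds = label_corpus(sents, shuffled, demo["pairs"], demo["lexicon"],
                              demo["tree"], nouns=demo["nouns"],
                              relation_config=demo["relation_config"])
            assert [l.subcategory for l in ds.labels] == \
                [l.subcategory for l in base.labels]

    def test_monotonicity_adding_low_priority_rule(self, demo,
                                                   preprocess_config):
        """A new rule never relabels sentences already matched by a
        strictly higher-priority rule."""
        sents, base = run_pipeline([RawInquiry("w", WORKED_EXAMPLE_TEXT)],
                                   demo, preprocess_config)
        grabby = Rule("grab-all", 999, "Efficacy",
                      ({"pred": "LEXICAL", "anchor": "the"},))
        extended = RuleSet(list(demo["ruleset"].rules) + [grabby])
        ds = label_corpus(sents, extended, demo["pairs"], demo["lexicon"],
                          demo["tree"], nouns=demo["nouns"],
                          relation_config=demo["relation_config"])
        assert [l.subcategory for l in ds.labels] == \
            [l.subcategory for l in base.labels]


class TestRuleSetValidation:
    def test_duplicate_ids_rejected(self):
        r = Rule("x", 1, "A", ({"pred": "LEXICAL", "anchor": "a"},))
        with pytest.raises(ValueError, match="duplicate"):
            RuleSet([r, r])

    def test_unknown_label_rejected(self, demo):
        rs = RuleSet([Rule("x", 1, "Nonexistent",
                           ({"pred": "LEXICAL", "anchor": "a"},))])
        with pytest.raises(ValueError, match="Nonexistent"):
            rs.validate(demo["tree"])

    def test_fallback_cannot_be_trainable(self):
        with pytest.raises(ValueError):
            CategoryTree({"General or Other": "Root"}, "General or Other")
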