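"""Shared fixtures: demo resources and the reference synthetic experiment."""

from __future__ import annotations

import numpy as np
import pytest

from medinq import resources as res
from medinq.preprocessing import PreprocessConfig, preprocess_corpus
from medinq.rule_engine import label_corpus
from medinq.synthetic import GeneratorConfig, generate_corpus

WORKED_EXAMPLE_TEXT = (
    "Would like to have any documentation available on allergies of "
    "Product-A. Are there any cases of having allergies after taking "
    "Product-A? I want MSL to meet me and discuss this further."
)


@pytest.fixture(scope="session")
def demo():
    """Demo knowledgebase, rules and word lists as one namespace."""
    ruleset, tree, rc = res.demo_rules()
    return {
        "lexicon": res.demo_lexicon(),
        "pairs": res.demo_pairs(),
        "ruleset": ruleset,
        "tree": tree,
        "relation_config": rc,
        "nouns": res.demo_nouns(),
        "stop_words": res.stop_words(),
        "dictionary": res.demo_spelling_dictionary(),
        "unigram": res.demo_unigram_model(),
    }


@pytest.fixture(scope="session")
def preprocess_config(demo):
    return PreprocessConfig(
        dictionary=demo["dictionary"],
        protected_terms=frozenset(demo["lexicon"].tokens()),
    )


def run_pipeline(inquiries, demo, preprocess_config):
    """preprocess + weak-label a list of inquiries."""
    sents = preprocess_corpus(inquiries, preprocess_config)
    ds = label_corpus(
        sents, demo["ruleset"], demo["pairs"], demo["lexicon"], demo["tree"],
        nouns=demo["nouns"], relation_config=demo["relation_config"],
    )
    return sents, ds


@pytest.fixture(scope="session")
def reference_experiment(demo, preprocess_config):
    """The 20,000-sentence imbalanced corpus (Zipf 1.2, seed 42), weak-labeled
    and TF-IDF-featurized — shared by the classifier-level checks."""
    from medinq.features import TfidfFeaturizer

    corpus = generate_corpus(GeneratorConfig(n_sentences=20000, seed=42))
    sents, ds = run_pipeline(corpus.inquiries, demo, preprocess_config)
    gold = {(g.inquiry_id, g.index): g.subcategory for g in corpus.gold}
    texts = [l.text for l in ds.trainable]
    yweak = [l.subcategory for l in ds.trainable]
    ygold = [gold.get((l.inquiry_id, l.index)) for l in ds.trainable]
    feat = TfidfFeaturizer(stop_words=demo["stop_words"])
    X = feat.fit_transform(texts)
    return {
        "corpus": corpus, "dataset": ds, "X": X, "texts": texts,
        "yweak": yweak, "ygold": ygold, "featurizer": feat,
        "labels": demo["tree"].subcategories,
    }
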