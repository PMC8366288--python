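"""Accessors for the packaged demo knowledgebase, rules and word lists.

The demo knowledgebase (entity lexicon + adverse-effect pairs) and the demo
rule set cover the worked three-sentence inquiry and all synthetic
templates; they stand in for the proprietary production resources, which
are not redistributable.

The demo spelling dictionary and unigram segmentation model are built
programmatically from the template vocabulary with a three-tier frequency
scheme (function words > template content words > entity surface tokens),
so spell correction and word segmentation see exactly the vocabulary the
generator can emit.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources as _ir

from .knowledgebase import EntityLexicon, RelationPairStore, load_lexicon, load_pairs
from .preprocessing import SpellingDictionary, UnigramModel
from .rule_engine import CategoryTree, RelationConfig, RuleSet, load_rule_config
from .templates import template_vocabulary

__all__ = [
    "resource_path",
    "demo_lexicon",
    "demo_pairs",
    "demo_rules",
    "demo_nouns",
    "stop_words",
    "demo_spelling_dictionary",
    "demo_unigram_model",
]


def resource_path(name: str):
    return _ir.files("medinq") / "data" / name


@lru_cache(maxsize=None)
def demo_lexicon() -> EntityLexicon:
    return load_lexicon(resource_path("lexicon.tsv"))


@lru_cache(maxsize=None)
def demo_pairs() -> RelationPairStore:
    return load_pairs(resource_path("pairs.tsv"))


@lru_cache(maxsize=None)
def demo_rules() -> tuple[RuleSet, CategoryTree, RelationConfig]:
    return load_rule_config(resource_path("rules.yaml"))


@lru_cache(maxsize=None)
def demo_nouns() -> frozenset[str]:
    text = resource_path("nouns.txt").read_text(encoding="utf-8")
    return frozenset(w.strip().lower() for w in text.split() if w.strip())


@lru_cache(maxsize=None)
def stop_words() -> frozenset[str]:
    text = resource_path("stopwords.txt").read_text(encoding="utf-8")
    return frozenset(w.strip().lower() for w in text.split() if w.strip())


@lru_cache(maxsize=None)
def demo_spelling_dictionary(max_edit_distance: int = 2) -> SpellingDictionary:
    """Term-frequency dictionary over the demo vocabulary.

    Frequencies are a fixed three-tier scheme standing in for corpus
    counts: stop/function words 1000, ordinary template words 200, entity
    surface tokens 100. The tiers only matter for tie-breaking among
    equally distant correction candidates and for segmentation costs.
    """
    lex_tokens = demo_lexicon().tokens()
    freqs: dict[str, int] = {}
    for word in sorted(template_vocabulary()):
        if word in stop_words():
            freqs[word] = 1000
        elif word in lex_tokens:
            freqs[word] = 100
        else:
            freqs[word] = 200
    for word in sorted(stop_words()):
        freqs.setdefault(word, 1000)
    return SpellingDictionary(freqs, max_edit_distance)


@lru_cache(maxsize=None)
def demo_unigram_model() -> UnigramModel:
    return UnigramModel.from_dictionary(demo_spelling_dictionary())
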