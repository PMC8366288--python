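"""Cleaning, splitting, spell correction and segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medinq.preprocessing import (
    CleanSentence,
    PreprocessConfig,
    RawInquiry,
    SpellingDictionary,
    UnigramModel,
    clean_text,
    correct_token,
    damerau_levenshtein,
    enumerate_segmentations,
    preprocess_corpus,
    segment_word,
    split_inquiry,
    tokenize,
)
from tests.conftest import WORKED_EXAMPLE_TEXT


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("<p>dose info</p>", "dose info"),
        ("ASCII only text", "ASCII only text"),
        ("café", "caf"),
        ("a  lot\tof\n whitespace", "a lot of whitespace"),
        ("<br/>x<b>y</b>", "x y"),
    ],
)
def test_clean_text(raw, expected):
    assert clean_text(raw) == expected


@pytest.mark.parametrize(
    "text, n",
    [
        (WORKED_EXAMPLE_TEXT, 3),
        ("", 0),
        ("Dose is 5 mg", 1),
        ("See Dr. Smith today. Thanks!", 2),  # abbreviation guard
        ("One. two stays joined. Three splits.", 2),  # lowercase continuation
    ],
)
def test_split_inquiry_boundaries(text, n):
    sentences = split_inquiry(RawInquiry("i1", text))
    assert len(sentences) == n
    assert [s.index for s in sentences] == list(range(n))


def test_tokenize_detaches_punctuation_keeps_product_codes():
    assert tokenize("allergies of Product-A.") == [
        "allergies", "of", "Product-A", "."
    ]
    assert tokenize("(see note), ok?") == ["(", "see", "note", ")", ",", "ok", "?"]


def test_clean_sentence_tokens_reconstruct_text():
    s = CleanSentence("i", 0, "a b c", ("a", "b", "c"))
    assert " ".join(s.tokens) == s.text
    with pytest.raises(ValueError):
        CleanSentence("i", 0, "a b", ("a",))


class TestDamerauLevenshtein:
    @pytest.mark.parametrize(
        "a, b, d",
        [("abc", "abc", 0), ("abc", "acb", 1), ("abc", "ab", 1),
         ("abc", "axc", 1), ("ca", "abc", 3), ("kitten", "sitting", 3)],
    )
    def test_known_distances(self, a, b, d):
        assert damerau_levenshtein(a, b) == d

    def test_cap_early_exit(self):
        assert damerau_levenshtein("aaaaaa", "bbbbbb", cap=2) == 3


class TestCorrectToken:
    def setup_method(self):
        self.dic = SpellingDictionary(
            {"allergies": 50, "product": 100, "allergen": 60}, max_edit_distance=2
        )

    def test_single_edit_correction(self):
        # "allergis" is distance 1 from "allergies" (one deletion) and
        # distance 2 from "allergen"; the closer term wins
        assert correct_token("allergis", self.dic) == ("allergies", 1)

    def test_exact_match_distance_zero(self):
        assert correct_token("product", self.dic) == ("product", 0)

    def test_no_candidate_returns_unchanged(self):
        assert correct_token("zzqqxx", self.dic) == ("zzqqxx", -1)

    def test_protected_term_untouched(self):
        assert correct_token("msl", self.dic, protected=frozenset({"msl"})) == ("msl", 0)

    def test_tie_broken_by_frequency_then_lexicographic(self):
        dic = SpellingDictionary({"cat": 5, "bat": 9, "aat": 9}, max_edit_distance=1)
        # all candidates at distance 1; higher frequency wins, then lexicographic
        assert correct_token("dat", dic) == ("aat", 1)

    def test_empty_token_rejected(self):
        with pytest.raises(ValueError):
            correct_token("", self.dic)

    def test_delete_index_invariant(self):
        # every <=2-char deletion variant of each term maps back to it
        for term in self.dic.frequencies:
            for i in range(len(term)):
                var = term[:i] + term[i + 1:]
                assert term in self.dic.delete_index[var]


@settings(max_examples=200, derandomize=True)
@given(st.text(alphabet="abcdefg", min_size=1, max_size=8))
def test_symmetric_delete_matches_bruteforce(query):
    """Index lookup returns exactly the brute-force scan's best candidate."""
    terms = {"abacus": 3, "bead": 7, "cabbage": 2, "decaf": 5, "egg": 9,
             "facade": 1, "gaffe": 4, "badge": 6, "adage": 8}
    dic = SpellingDictionary(terms, max_edit_distance=2)
    got = correct_token(query, dic)
    # brute force over the whole dictionary
    best = None
    for t in sorted(terms):
        d = damerau_levenshtein(query.lower(), t)
        if d <= 2 and (best is None or (d, -terms[t], t) < best):
            best = (d, -terms[t], t)
    if query.lower() in terms:
        assert got == (query, 0)
    elif best is None:
        assert got == (query, -1)
    else:
        assert got == (best[2], best[0])


class TestSegmentation:
    def setup_method(self):
        self.model = UnigramModel(
            {"any": 1000, "documentation": 200, "doc": 50, "um": 30,
             "entation": 1, "a": 500, "ny": 2}
        )

    def test_splits_concatenation(self):
        assert segment_word("anydocumentation", self.model) == [
            "any", "documentation"
        ]

    def test_known_word_kept_whole(self):
        assert segment_word("documentation", self.model) == ["documentation"]

    def test_unknown_word_not_split(self):
        assert segment_word("qqqq", self.model) == ["qqqq"]

    def test_dp_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        words = ["any", "doc", "um", "a", "ny", "documentation"]
        for _ in range(60):
            parts = [words[rng.integers(len(words))]
                     for _ in range(rng.integers(2, 4))]
            w = "".join(parts)
            if len(w) > 14:
                continue
            dp = segment_word(w, self.model)
            cost_dp = sum(self.model.cost(s) for s in dp)
            cost_best, _ = enumerate_segmentations(w, self.model)
            assert cost_dp == pytest.approx(cost_best)


class TestPipeline:
    def test_worked_example_preserves_key_phrases(self, preprocess_config):
        sents = preprocess_corpus(
            [RawInquiry("w", WORKED_EXAMPLE_TEXT)], preprocess_config
        )
        assert len(sents) == 3
        assert "any documentation" in sents[0].text
        assert "allergies" in sents[0].text
        assert "Product-A" in sents[0].text
        assert "MSL" in sents[2].text

    def test_empty_corpus(self, preprocess_config):
        assert preprocess_corpus([], preprocess_config) == []

    def test_idempotence(self, preprocess_config):
        first = preprocess_corpus(
            [RawInquiry("w", WORKED_EXAMPLE_TEXT)], preprocess_config
        )
        again = preprocess_corpus(
            [RawInquiry(s.inquiry_id, s.text) for s in first], preprocess_config
        )
        assert [s.text for s in again] == [s.text for s in first]

    def test_fixes_misspelling_and_concatenation(self, preprocess_config):
        sents = preprocess_corpus(
            [RawInquiry("n", "Would like anydocumentation on allerges of Product-A.")],
            preprocess_config,
        )
        text = sents[0].text
        assert "any documentation" in text
        assert "allergies" in text

    def test_sentence_count_invariant_to_html_noise(self, preprocess_config):
        from medinq.synthetic import GeneratorConfig, generate_corpus

        noisy = generate_corpus(
            GeneratorConfig(n_inquiries=100, seed=3, p_misspell=0, q_concat=0,
                            r_html=0.3)
        )
        sents = preprocess_corpus(noisy.inquiries, preprocess_config)
        assert len(sents) == noisy.n_sentences
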