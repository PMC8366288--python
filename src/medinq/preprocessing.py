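"""Turn raw inquiry text into clean, tokenized sentences.

Contact-center inquiries arrive as noisy free text: HTML residue from web
forms, non-ASCII artifacts from transcription, misspellings, and words run
together where spaces were dropped. This module normalizes that text into
sentence units suitable for the downstream rule engine and classifiers:

1. special-character cleanup (HTML tags and non-ASCII stripped),
2. sentence splitting with an abbreviation guard,
3. symmetric-delete spelling correction against a term-frequency dictionary,
4. dynamic-programming segmentation of concatenated words under a unigram
   cost model.

All steps are deterministic, and the composite pipeline is idempotent:
feeding its output back through it reproduces the output exactly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "RawInquiry",
    "CleanSentence",
    "SpellingDictionary",
    "UnigramModel",
    "clean_text",
    "split_inquiry",
    "tokenize",
    "damerau_levenshtein",
    "correct_token",
    "segment_word",
    "preprocess_corpus",
    "PreprocessConfig",
]


@dataclass(frozen=True)
class RawInquiry:
    """A raw inquiry record: free text plus identifying metadata."""

    id: str
    text: str
    language: str = "en"
    metadata: dict | None = None


@dataclass(frozen=True)
class CleanSentence:
    """One cleaned, tokenized sentence of an inquiry.

    ``text`` is the space-joined token sequence, so joining ``tokens`` with
    single spaces reconstructs it exactly.
    """

    inquiry_id: str
    index: int
    text: str
    tokens: tuple[str, ...]

    def __post_init__(self):
        if " ".join(self.tokens) != self.text:
            raise ValueError("tokens do not reconstruct text")


# ---------------------------------------------------------------------------
# cleaning and splitting
# ---------------------------------------------------------------------------

_HTML_TAG = re.compile(r"<[^<>]*>")
_HTML_ENTITY = re.compile(r"&[A-Za-z]+;|&#\d+;")
_NON_ASCII = re.compile(r"[^\x00-\x7f]")
_WS = re.compile(r"\s+")


def clean_text(text: str) -> str:
    """Remove HTML tags/entities and non-ASCII characters, collapse whitespace."""
    text = _HTML_TAG.sub(" ", text)
    text = _HTML_ENTITY.sub(" ", text)
    text = _NON_ASCII.sub("", text)
    return _WS.sub(" ", text).strip()


#: Abbreviations whose trailing period must not end a sentence.
ABBREVIATIONS = frozenset(
    {"dr", "mr", "mrs", "ms", "prof", "vs", "etc", "e.g", "i.e", "approx",
     "fig", "no", "inc", "ltd", "st"}
)

_BOUNDARY = re.compile(r"([.?!]+)(\s+)(?=[A-Z0-9])")


def split_inquiry(inquiry: RawInquiry) -> list[CleanSentence]:
    """Split an inquiry into ordered :class:`CleanSentence` units.

    Boundaries are terminal punctuation (``.``, ``?``, ``!``) followed by
    whitespace and an upper-case letter or digit; a guard list keeps common
    abbreviations from ending a sentence. Empty text yields an empty list.
    """
    text = clean_text(inquiry.text)
    if not text:
        return []
    pieces: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        prev_word = text[start:m.start()].rsplit(None, 1)[-1] if text[start:m.start()].strip() else ""
        if prev_word.rstrip(".").lower() in ABBREVIATIONS:
            continue
        pieces.append(text[start:m.end(1)])
        start = m.end()
    pieces.append(text[start:])
    sentences = []
    for i, piece in enumerate(p for p in pieces if p.strip()):
        toks = tokenize(piece)
        if not toks:
            continue
        sentences.append(
            CleanSentence(inquiry.id, i, " ".join(toks), tuple(toks))
        )
    # reindex contiguously in case a piece tokenized to nothing
    return [
        CleanSentence(s.inquiry_id, i, s.text, s.tokens)
        for i, s in enumerate(sentences)
    ]


_PUNCT = ".,;:!?()[]{}\"'"


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization with leading/trailing punctuation detached.

    Internal punctuation (hyphens in product codes like ``Product-A``,
    periods in abbreviations) is preserved.
    """
    tokens: list[str] = []
    for raw in text.split():
        lead = []
        while raw and raw[0] in _PUNCT:
            lead.append(raw[0])
            raw = raw[1:]
        trail = []
        while raw and raw[-1] in _PUNCT and raw.rstrip(".").lower() not in ABBREVIATIONS:
            trail.append(raw[-1])
            raw = raw[:-1]
        tokens.extend(lead)
        if raw:
            tokens.append(raw)
        tokens.extend(reversed(trail))
    return tokens


# ---------------------------------------------------------------------------
# symmetric-delete spelling correction
# ---------------------------------------------------------------------------


def damerau_levenshtein(a: str, b: str, cap: int | None = None) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance.

    Counts insertions, deletions, substitutions and adjacent transpositions;
    a transposed pair may not be edited further. When ``cap`` is given and
    the distance provably exceeds it, returns ``cap + 1`` early.
    """
    la, lb = len(a), len(b)
    if cap is not None and abs(la - lb) > cap:
        return cap + 1
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        if cap is not None and min(cur) > cap:
            return cap + 1
        prev2, prev = prev, cur
    return prev[lb]


def _deletes(word: str, max_distance: int) -> set[str]:
    """All variants of ``word`` with up to ``max_distance`` characters deleted."""
    out = {word}
    frontier = {word}
    for _ in range(max_distance):
        nxt = set()
        for w in frontier:
            for i in range(len(w)):
                nxt.add(w[:i] + w[i + 1:])
        out |= nxt
        frontier = nxt
    return out


class SpellingDictionary:
    """Term-frequency dictionary with a symmetric-delete candidate index.

    The index maps every deletion variant (up to ``max_edit_distance``
    characters removed) of every dictionary term back to the terms that
    produced it, so candidate lookup is a set union over the query's own
    deletion variants rather than a scan of the dictionary.
    """

    def __init__(self, frequencies: dict[str, int], max_edit_distance: int = 2):
        if any(f <= 0 for f in frequencies.values()):
            raise ValueError("all term frequencies must be positive")
        self.frequencies = {t.lower(): f for t, f in frequencies.items()}
        self.max_edit_distance = int(max_edit_distance)
        self.delete_index: dict[str, set[str]] = {}
        for term in self.frequencies:
            for var in _deletes(term, self.max_edit_distance):
                self.delete_index.setdefault(var, set()).add(term)

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.frequencies

    def __len__(self) -> int:
        return len(self.frequencies)

    def candidates(self, token: str) -> set[str]:
        """Dictionary terms sharing a deletion variant with ``token``."""
        out: set[str] = set()
        for var in _deletes(token.lower(), self.max_edit_distance):
            out |= self.delete_index.get(var, set())
        return out

    @classmethod
    def from_tsv(cls, path, max_edit_distance: int = 2) -> "SpellingDictionary":
        """Load a two-column (term, frequency) TSV."""
        freqs: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                freqs[parts[0]] = int(parts[1])
        return cls(freqs, max_edit_distance)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term in sorted(self.frequencies):
                fh.write(f"{term}\t{self.frequencies[term]}\n")


def correct_token(
    token: str,
    dictionary: SpellingDictionary,
    protected: frozenset[str] | set[str] = frozenset(),
) -> tuple[str, int]:
    """Correct one token against the dictionary.

    Returns ``(corrected, distance)`` where ``corrected`` is the dictionary
    term with minimum Damerau-Levenshtein distance within the dictionary's
    ``max_edit_distance`` (ties broken by higher frequency, then
    lexicographically). In-dictionary and ``protected`` tokens come back
    unchanged with distance 0; tokens with no candidate come back unchanged
    with distance -1.
    """
    if not token:
        raise ValueError("cannot correct an empty token")
    low = token.lower()
    if low in dictionary.frequencies or low in protected:
        return token, 0
    best: tuple[int, int, str] | None = None  # (distance, -freq, term)
    for cand in dictionary.candidates(token):
        d = damerau_levenshtein(low, cand, cap=dictionary.max_edit_distance)
        if d > dictionary.max_edit_distance:
            continue
        key = (d, -dictionary.frequencies[cand], cand)
        if best is None or key < best:
            best = key
    if best is None:
        return token, -1
    return best[2], best[0]


# ---------------------------------------------------------------------------
# concatenated-word segmentation
# ---------------------------------------------------------------------------


class UnigramModel:
    """Word costs (negative log relative frequency) for segmentation.

    Unknown segments cost ``unknown_cost_per_char`` per character; the
    default is chosen strictly above the largest known-word cost so a split
    into known words always beats leaving characters unexplained, while an
    all-unknown token is never split (no split reduces its cost).
    """

    def __init__(self, frequencies: dict[str, int],
                 unknown_cost_per_char: float | None = None):
        total = sum(frequencies.values())
        self.costs = {
            w.lower(): -math.log(f / total) for w, f in frequencies.items()
        }
        max_cost = max(self.costs.values(), default=1.0)
        if unknown_cost_per_char is None:
            unknown_cost_per_char = max_cost + 1.0
        if unknown_cost_per_char <= 0:
            raise ValueError("unknown_cost_per_char must be positive")
        self.unknown_cost_per_char = float(unknown_cost_per_char)

    def cost(self, segment: str) -> float:
        c = self.costs.get(segment.lower())
        if c is not None:
            return c
        return self.unknown_cost_per_char * len(segment)

    @classmethod
    def from_dictionary(cls, dictionary: SpellingDictionary) -> "UnigramModel":
        return cls(dictionary.frequencies)


def segment_word(word: str, model: UnigramModel) -> list[str]:
    """Split a concatenated word into the minimum-cost segment sequence.

    Dynamic program over split points: ``best[i]`` is the cheapest
    segmentation of the first ``i`` characters. Ties prefer fewer segments
    (resolved implicitly by strict improvement), so an in-vocabulary word
    comes back whole.
    """
    if not word:
        return []
    n = len(word)
    best = [0.0] + [math.inf] * n
    back = [0] * (n + 1)
    for i in range(1, n + 1):
        for j in range(i):
            c = best[j] + model.cost(word[j:i])
            if c < best[i]:
                best[i] = c
                back[i] = j
    segments: list[str] = []
    i = n
    while i > 0:
        segments.append(word[back[i]:i])
        i = back[i]
    return segments[::-1]


def enumerate_segmentations(word: str, model: UnigramModel) -> tuple[float, list[str]]:
    """Exhaustive minimum over all 2^(L-1) split placements (oracle).

    Pure enumeration by recursion over the first segment's end (no
    memoization, no pruning); intended for short words only, to validate
    :func:`segment_word` independently of its dynamic program.
    """
    n = len(word)
    best_cost = math.inf
    best_split: list[str] = [word]

    def rec(i: int, cost: float, segs: list[str]) -> None:
        nonlocal best_cost, best_split
        if i == n:
            if cost < best_cost:
                best_cost = cost
                best_split = list(segs)
            return
        for j in range(i + 1, n + 1):
            segs.append(word[i:j])
            rec(j, cost + model.cost(word[i:j]), segs)
            segs.pop()

    rec(0, 0.0, [])
    return best_cost, best_split


# ---------------------------------------------------------------------------
# composite pipeline
# ---------------------------------------------------------------------------


@dataclass
class PreprocessConfig:
    """Resources and knobs for the preprocessing pipeline."""

    dictionary: SpellingDictionary
    unigram: UnigramModel | None = None
    protected_terms: frozenset[str] = frozenset()
    min_correct_len: int = 3  # very short tokens are left alone
    segment_min_len: int = 6  # shorter unknowns are not split

    def __post_init__(self):
        if self.unigram is None:
            self.unigram = UnigramModel.from_dictionary(self.dictionary)


_ALPHA = re.compile(r"^[A-Za-z][A-Za-z-]*$")


def _process_token(token: str, cfg: PreprocessConfig) -> list[str]:
    if not _ALPHA.match(token):
        return [token]
    low = token.lower()
    if low in cfg.dictionary.frequencies or low in cfg.protected_terms:
        return [token]
    if len(token) >= cfg.min_correct_len:
        corrected, dist = correct_token(token, cfg.dictionary, cfg.protected_terms)
        if dist >= 0:
            return [corrected]
    if len(token) >= cfg.segment_min_len:
        segments = segment_word(token, cfg.unigram)
        if len(segments) > 1 and all(s.lower() in cfg.unigram.costs for s in segments):
            return segments
    return [token]


def preprocess_corpus(
    inquiries: list[RawInquiry], config: PreprocessConfig
) -> list[CleanSentence]:
    """clean -> split -> per-token spell correction -> segmentation.

    Deterministic and idempotent: tokens already in the dictionary or the
    protected set pass through untouched, so re-running on the output is the
    identity.
    """
    out: list[CleanSentence] = []
    for inquiry in inquiries:
        for sent in split_inquiry(inquiry):
            tokens: list[str] = []
            for tok in sent.tokens:
                tokens.extend(_process_token(tok, config))
            if tokens:
                out.append(
                    CleanSentence(
                        sent.inquiry_id, sent.index, " ".join(tokens), tuple(tokens)
                    )
                )
    return out
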