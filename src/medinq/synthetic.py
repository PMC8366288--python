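"""Synthetic inquiry corpora with ground-truth labels and transcription noise.

The generator emulates the statistical shape of a medical-information
contact-center corpus: multi-sentence inquiries (1-4 sentences each), 23
imbalanced subcategory labels drawn from a Zipf distribution, a fraction of
chit-chat sentences no rule matches (gold label = fallback), and
transcription-style noise injected after gold assignment — per-token random
character edits (misspellings), dropped inter-word spaces (concatenations),
and HTML/non-ASCII residue. Because gold labels are fixed before noise,
recovery rates through preprocessing and rule labeling measure noise
robustness directly.

Everything is driven by one ``numpy`` generator seeded from the config, so
corpora are bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocessing import RawInquiry
from .templates import FALLBACK_TEMPLATES, FILLERS, LABEL_ORDER, TEMPLATES, Template

__all__ = ["GeneratorConfig", "SyntheticCorpus", "GoldLabel",
           "generate_corpus", "inject_noise", "zipf_probabilities"]

_HTML_SNIPPETS = ["<p>", "</p>", "<br>", "<br/>", "<b>", "</b>", "&nbsp;"]
_NON_ASCII_CHARS = "éüä•°’®"
_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``zipf_exponent`` shapes the label imbalance (0 = uniform); the noise
    rates are per-token probabilities of a random character edit (``p``),
    of deleting the following space (``q``), and of injecting an HTML tag
    or non-ASCII character (``r``). ``fallback_fraction`` is the share of
    sentences drawn from templates no rule matches. When ``n_sentences``
    is set, inquiries are generated until exactly that many sentences
    exist (the last inquiry is truncated to fit) and ``n_inquiries`` is
    ignored.
    """

    n_inquiries: int = 1000
    n_sentences: int | None = None
    min_sentences: int = 1
    max_sentences: int = 4
    zipf_exponent: float = 1.2
    p_misspell: float = 0.03
    q_concat: float = 0.02
    r_html: float = 0.01
    fallback_fraction: float = 0.1
    mix_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for name in ("p_misspell", "q_concat", "r_html", "fallback_fraction",
                     "mix_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_inquiries <= 0:
            raise ValueError("n_inquiries must be positive")


@dataclass(frozen=True)
class GoldLabel:
    inquiry_id: str
    index: int
    subcategory: str
    root: str


@dataclass
class SyntheticCorpus:
    inquiries: list[RawInquiry]
    gold: list[GoldLabel]
    manifest: dict = field(default_factory=dict)

    @property
    def n_sentences(self) -> int:
        return len(self.gold)


def zipf_probabilities(n: int, exponent: float) -> np.ndarray:
    """P(rank r) proportional to (r+1)^-exponent, r = 0..n-1."""
    w = (np.arange(1, n + 1, dtype=float)) ** (-float(exponent))
    return w / w.sum()


def _edit(word: str, rng: np.random.Generator) -> str:
    """One random character edit: insert, delete, substitute or transpose."""
    ops = ["insert", "substitute", "transpose", "delete"]
    if len(word) <= 2:
        ops = ["insert", "substitute"]
    op = ops[rng.integers(len(ops))]
    i = int(rng.integers(len(word)))
    c = _LETTERS[rng.integers(len(_LETTERS))]
    if op == "insert":
        return word[:i] + c + word[i:]
    if op == "delete":
        return word[:i] + word[i + 1:]
    if op == "substitute":
        return word[:i] + c + word[i + 1:]
    j = min(i + 1, len(word) - 1)
    if i == j:
        return word
    return word[:i] + word[j] + word[i] + word[j + 1:]


def inject_noise(sentence: str, rates: tuple[float, float, float],
                 rng: np.random.Generator) -> str:
    """Apply transcription-style noise to one sentence.

    Per token: with probability ``p`` one random character edit (alphabetic
    tokens only, terminal punctuation kept intact); with probability ``q``
    the following space is deleted (never across the sentence boundary);
    with probability ``r`` an HTML snippet or non-ASCII character is
    inserted after the token.
    """
    p, q, r = rates
    tokens = sentence.split()
    out: list[str] = []
    joined_prev = False
    for k, tok in enumerate(tokens):
        core = tok.rstrip(".,?!")
        tail = tok[len(core):]
        if p and core.isalpha() and rng.random() < p:
            core = _edit(core, rng)
        tok = core + tail
        if r and rng.random() < r:
            noise = (_HTML_SNIPPETS[rng.integers(len(_HTML_SNIPPETS))]
                     if rng.random() < 0.5
                     else _NON_ASCII_CHARS[rng.integers(len(_NON_ASCII_CHARS))])
            tok = tok + noise
        if joined_prev:
            out[-1] = out[-1] + tok
            joined_prev = False
        else:
            out.append(tok)
        # never join across the terminal token
        if q and k < len(tokens) - 2 and not tail and rng.random() < q:
            joined_prev = True
    return " ".join(out)


def _render(template: Template, rng: np.random.Generator) -> str:
    """Fill a template's typed slots with distinct lexicon surfaces."""
    used: dict[str, str] = {}
    text = template.pattern
    for etype, key in template.slots:
        pool = [f for f in FILLERS[etype] if f not in used.values()]
        filler = pool[rng.integers(len(pool))]
        used[key] = filler
        text = text.replace("{" + key + "}", filler, 1)
    return text


def _compose(primary: str, secondary: str) -> str:
    """Join two single-topic clauses into one multi-topic sentence."""
    head = primary.rstrip(".?!")
    tail = secondary[:1].lower() + secondary[1:]
    return f"{head} and also {tail}"


def _sample_sentence(rng: np.random.Generator, probs: np.ndarray,
                     mix_fraction: float,
                     label_priorities: dict[str, int]) -> tuple[str, str]:
    """One trainable sentence: (gold label, text).

    With probability ``mix_fraction`` the sentence carries a second topic
    (drawn uniformly, the way minor topics surface as passing mentions);
    the gold label is the component whose rule has the smallest priority
    number — the same resolution the rule engine's prioritization applies
    to multi-topic sentences.
    """
    label = LABEL_ORDER[rng.choice(len(LABEL_ORDER), p=probs)]
    tmpl = TEMPLATES[label][rng.integers(len(TEMPLATES[label]))]
    text = _render(tmpl, rng)
    if rng.random() < mix_fraction:
        other = LABEL_ORDER[rng.integers(len(LABEL_ORDER))]
        tmpl2 = TEMPLATES[other][rng.integers(len(TEMPLATES[other]))]
        text = _compose(text, _render(tmpl2, rng))
        if label_priorities[other] < label_priorities[label]:
            label = other
    return label, text


def generate_corpus(config: GeneratorConfig,
                    tree_parents: dict[str, str] | None = None,
                    label_priorities: dict[str, int] | None = None,
                    fallback_label: str = "General or Other") -> SyntheticCorpus:
    """Generate a corpus of inquiries with per-sentence gold labels.

    Sentences are drawn label-first (Zipf over :data:`LABEL_ORDER`, or the
    fallback with probability ``fallback_fraction``), then a template for
    the label, then slot fillers; a ``mix_fraction`` share of trainable
    sentences additionally carries a uniformly drawn secondary topic, with
    gold resolved by rule priority. Noise is injected after the gold label
    is recorded. ``tree_parents`` and ``label_priorities`` default to the
    packaged demo tree and rule set.
    """
    if tree_parents is None or label_priorities is None:
        from .resources import demo_rules

        ruleset, tree, _ = demo_rules()
        if tree_parents is None:
            tree_parents = tree.parents
        if label_priorities is None:
            label_priorities = {}
            for rule in ruleset:
                label_priorities.setdefault(rule.label, rule.priority)
    missing = [lbl for lbl in LABEL_ORDER if lbl not in tree_parents]
    if missing:
        raise ValueError(f"labels without a root category: {missing}")
    missing_p = [lbl for lbl in LABEL_ORDER if lbl not in label_priorities]
    if missing_p:
        raise ValueError(f"labels without a rule priority: {missing_p}")

    rng = np.random.default_rng(config.seed)
    probs = zipf_probabilities(len(LABEL_ORDER), config.zipf_exponent)
    rates = (config.p_misspell, config.q_concat, config.r_html)

    inquiries: list[RawInquiry] = []
    gold: list[GoldLabel] = []
    total = 0
    inquiry_no = 0
    while True:
        if config.n_sentences is not None:
            if total >= config.n_sentences:
                break
        elif inquiry_no >= config.n_inquiries:
            break
        n_sent = int(rng.integers(config.min_sentences, config.max_sentences + 1))
        if config.n_sentences is not None:
            n_sent = min(n_sent, config.n_sentences - total)
        iid = f"inq-{inquiry_no:06d}"
        texts: list[str] = []
        for idx in range(n_sent):
            if rng.random() < config.fallback_fraction:
                label = fallback_label
                sent = FALLBACK_TEMPLATES[rng.integers(len(FALLBACK_TEMPLATES))]
            else:
                label, sent = _sample_sentence(rng, probs, config.mix_fraction,
                                               label_priorities)
            root = tree_parents.get(label, fallback_label)
            gold.append(GoldLabel(iid, idx, label, root))
            texts.append(inject_noise(sent, rates, rng))
        inquiries.append(RawInquiry(iid, " ".join(texts), "en"))
        total += n_sent
        inquiry_no += 1

    manifest = {"config": asdict(config), "n_inquiries": len(inquiries),
                "n_sentences": total}
    return SyntheticCorpus(inquiries, gold, manifest)
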