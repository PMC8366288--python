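"""Heuristic weak labeling of inquiry sentences.

Each cleaned sentence is analyzed into key phrases (noun-phrase chunks and
lexicon matches), entity mentions (phrases resolved against the entity
lexicon) and shallow relations between them. A prioritized rule set is then
evaluated against that analysis; among all rules whose conditions hold, the
one with the smallest priority number assigns the sentence its subcategory.
Sentences matched by no rule fall back to the ``General or Other`` label and
are excluded from the trainable partition. Subcategories roll up to root
categories through a two-level category tree.

Rules are declarative conjunctions of four predicate kinds:

``ENTITY(type)``
    a mention of the given entity type is present;
``LEXICAL(anchor)``
    the anchor token sequence occurs in the sentence (case-insensitive);
``REL(kind, a, b)``
    a relation of the given kind (``modifies``, ``subject`` or ``cooccur``)
    links ``a`` to ``b``, where each argument is either ``entity:<Type>`` or
    ``token:<word>``;
``KB_PAIR(relation, type_a, type_b)``
    the mentioned surface pair of the two types is registered under the
    named relation in the knowledgebase.

Within one rule, arguments naming the same entity type refer to the same
mention: the evaluator searches for a consistent assignment of mentions to
the types the rule references.

Dependency parsing is approximated by a windowed pattern matcher (see
:func:`extract_relations`); a real parser can be plugged in by passing a
callable with the same signature to :func:`analyze_sentence`.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import yaml

from .knowledgebase import EntityLexicon, EntityMention, RelationPairStore
from .preprocessing import CleanSentence

__all__ = [
    "KeyPhrase",
    "Relation",
    "Rule",
    "RuleSet",
    "CategoryTree",
    "SentenceLabel",
    "SentenceAnalysis",
    "RelationConfig",
    "extract_key_phrases",
    "map_entities",
    "extract_relations",
    "analyze_sentence",
    "evaluate_rule",
    "label_sentence",
    "rollup",
    "label_corpus",
    "WeakLabeledDataset",
    "load_rule_config",
]

DETERMINERS = frozenset(
    {"a", "an", "the", "any", "some", "this", "that", "these", "those",
     "my", "your", "his", "her", "our", "their", "no", "each", "every"}
)

ADJECTIVES = frozenset(
    {"recommended", "new", "oral", "scientific", "medical", "clinical",
     "previous", "damaged", "possible", "pre-existing", "specific",
     "additional", "injectable"}
)


@dataclass(frozen=True)
class KeyPhrase:
    """A candidate argument phrase inside one sentence."""

    sentence_id: tuple[str, int]     # (inquiry_id, sentence index)
    token_start: int
    token_end: int                   # half-open token span
    text: str
    head_index: int                  # token index of the phrase head

    def __post_init__(self):
        if self.token_end <= self.token_start or not self.text:
            raise ValueError("empty key phrase")


@dataclass(frozen=True)
class Relation:
    """A shallow relation between mentions and/or literal tokens."""

    kind: str                        # modifies | subject | cooccur
    source: EntityMention | str
    target: EntityMention | str

    def __post_init__(self):
        if self.kind not in ("modifies", "subject", "cooccur"):
            raise ValueError(f"unknown relation kind {self.kind!r}")
        if self.source == self.target:
            raise ValueError("relation source and target must differ")


@dataclass(frozen=True)
class Rule:
    id: str
    priority: int
    label: str
    conditions: tuple[dict, ...]

    def __post_init__(self):
        if not self.conditions:
            raise ValueError(f"rule {self.id!r} has no conditions")


class RuleSet:
    """Uniquely identified rules, evaluated in (priority, id) order."""

    def __init__(self, rules: list[Rule], name: str = "ruleset",
                 version: str = "1"):
        ids = [r.id for r in rules]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate rule ids: {dup}")
        self.rules = sorted(rules, key=lambda r: (r.priority, r.id))
        self.name = name
        self.version = version

    def __iter__(self):
        return iter(self.rules)

    def __len__(self):
        return len(self.rules)

    def validate(self, tree: "CategoryTree") -> None:
        for r in self.rules:
            if r.label not in tree:
                raise ValueError(
                    f"rule {r.id!r} labels unknown subcategory {r.label!r}"
                )


class CategoryTree:
    """Two-level taxonomy: subcategory -> root, plus a fallback label."""

    def __init__(self, parents: dict[str, str],
                 fallback: str = "General or Other"):
        if fallback in parents:
            raise ValueError("fallback label cannot be a trainable subcategory")
        self.parents = dict(parents)
        self.fallback = fallback

    @property
    def subcategories(self) -> list[str]:
        return sorted(self.parents)

    @property
    def roots(self) -> list[str]:
        return sorted(set(self.parents.values()))

    def __contains__(self, subcategory: str) -> bool:
        return subcategory in self.parents

    def __len__(self):
        return len(self.parents)


def rollup(subcategory: str, tree: CategoryTree) -> str:
    """Parent root category of a subcategory (fallback maps to itself)."""
    if subcategory == tree.fallback:
        return tree.fallback
    try:
        return tree.parents[subcategory]
    except KeyError:
        raise KeyError(f"unknown subcategory {subcategory!r}") from None


@dataclass(frozen=True)
class SentenceLabel:
    inquiry_id: str
    index: int
    text: str
    subcategory: str
    root: str
    rule_id: str | None              # None for the fallback label


@dataclass
class RelationConfig:
    """Knobs of the windowed relation approximator."""

    window: int = 6
    connectives: frozenset[str] = frozenset(
        {"of", "on", "for", "with", "to", "in", "about", "after", "taking",
         "between", "during", "while", "by"}
    )
    modifier_tokens: frozenset[str] = frozenset({"available"})
    verb_tokens: frozenset[str] = frozenset(
        {"meet", "visit", "call", "contact"}
    )


@dataclass
class SentenceAnalysis:
    sentence: CleanSentence
    phrases: list[KeyPhrase]
    mentions: list[EntityMention]
    relations: list[Relation]


# ---------------------------------------------------------------------------
# key phrases
# ---------------------------------------------------------------------------


def _is_nounish(token: str, position: int, nouns: frozenset[str],
                lexicon_tokens: frozenset[str]) -> bool:
    low = token.lower()
    if low in nouns or low in lexicon_tokens:
        return True
    # product-code style tokens: internal hyphen or capital after position 0
    if "-" in token:
        return True
    return position > 0 and token[:1].isupper()


def extract_key_phrases(
    sentence: CleanSentence,
    lexicon: EntityLexicon,
    nouns: frozenset[str] = frozenset(),
) -> list[KeyPhrase]:
    """Maximal noun-phrase chunks plus all multi-token lexicon matches.

    The chunker is pattern-based: an optional determiner, any adjectives,
    then one or more noun-like tokens (known nouns, lexicon tokens,
    hyphenated product codes, or capitalized tokens after sentence start).
    """
    toks = sentence.tokens
    lex_tokens = frozenset(lexicon.tokens())
    sid = (sentence.inquiry_id, sentence.index)
    spans: set[tuple[int, int]] = set()

    i = 0
    while i < len(toks):
        start = i
        j = i
        if j < len(toks) and toks[j].lower() in DETERMINERS:
            j += 1
        while j < len(toks) and toks[j].lower() in ADJECTIVES:
            j += 1
        head_start = j
        while j < len(toks) and _is_nounish(toks[j], j, nouns, lex_tokens):
            j += 1
        if j > head_start:
            spans.add((start, j))
            i = j
        else:
            i += 1

    # lexicon surface matches (greedy longest at each position)
    max_len = lexicon.max_surface_tokens()
    for i in range(len(toks)):
        for L in range(min(max_len, len(toks) - i), 0, -1):
            surface = " ".join(t.lower() for t in toks[i:i + L])
            if surface in lexicon.entries:
                spans.add((i, i + L))
                break

    # keep maximal spans only (a lexicon match inside a chunk is not a
    # separate phrase; entity mapping still finds it via the head span)
    maximal = [
        (a, b) for a, b in spans
        if not any((c <= a and b <= d) and (a, b) != (c, d)
                   for c, d in spans)
    ]
    return [
        KeyPhrase(sid, a, b, " ".join(toks[a:b]), b - 1)
        for a, b in sorted(maximal)
    ]


# ---------------------------------------------------------------------------
# entity mapping
# ---------------------------------------------------------------------------


def map_entities(
    phrases: list[KeyPhrase], lexicon: EntityLexicon
) -> list[EntityMention]:
    """Resolve key phrases against the lexicon.

    For each phrase, the longest matching token suffix wins (the full phrase
    first, then with leading determiners/adjectives dropped, down to the
    head token). Phrases with no match yield no mention. Mentions are
    deduplicated by token span.
    """
    seen: dict[tuple[int, int], EntityMention] = {}
    for phrase in sorted(phrases, key=lambda p: (p.token_start, p.token_end)):
        toks = phrase.text.split()
        for drop in range(len(toks)):
            surface = " ".join(toks[drop:]).lower()
            etype = lexicon.get(surface)
            if etype is not None:
                span = (phrase.token_start + drop, phrase.token_end)
                if span not in seen:
                    seen[span] = EntityMention(
                        surface=surface,
                        entity_type=etype,
                        token_start=span[0],
                        token_end=span[1],
                        phrase_text=phrase.text,
                    )
                break
    return [seen[k] for k in sorted(seen)]


# ---------------------------------------------------------------------------
# relations
# ---------------------------------------------------------------------------


def extract_relations(
    sentence: CleanSentence,
    mentions: list[EntityMention],
    config: RelationConfig | None = None,
) -> list[Relation]:
    """Windowed approximation of the dependency relations rules consume.

    * ``modifies(A, B)`` for mentions A before B separated by at most
      ``window`` tokens, when they are adjacent or a connective token lies
      between them; also ``modifies(w, M)`` for each configured modifier
      token w within the window of a mention M (either side).
    * ``subject(A, v)`` for each configured verb token v and the closest
      mention A before it with no other mention in between.
    * ``cooccur(A, B)`` for every ordered mention pair (A before B).
    """
    cfg = config or RelationConfig()
    toks = [t.lower() for t in sentence.tokens]
    rels: list[Relation] = []

    ordered = sorted(mentions, key=lambda m: m.token_start)
    for a, b in itertools.combinations(ordered, 2):
        rels.append(Relation("cooccur", a, b))
        gap = toks[a.token_end:b.token_start]
        if len(gap) <= cfg.window and (
            not gap or any(t in cfg.connectives for t in gap)
        ):
            rels.append(Relation("modifies", a, b))

    for i, tok in enumerate(toks):
        if tok in cfg.modifier_tokens:
            for m in ordered:
                before_gap = m.token_start - (i + 1)
                after_gap = i - m.token_end
                if 0 <= before_gap <= cfg.window or 0 <= after_gap <= cfg.window:
                    rels.append(Relation("modifies", sentence.tokens[i].lower(), m))
        if tok in cfg.verb_tokens:
            prior = [m for m in ordered if m.token_end <= i]
            if prior:
                # closest preceding mention; no other mention intervenes
                rels.append(Relation("subject", prior[-1], tok))

    return rels


def analyze_sentence(
    sentence: CleanSentence,
    lexicon: EntityLexicon,
    nouns: frozenset[str] = frozenset(),
    relation_config: RelationConfig | None = None,
    relation_extractor=None,
) -> SentenceAnalysis:
    """Full shallow analysis of one sentence.

    ``relation_extractor`` may replace the built-in windowed approximator
    with a parser adapter of the same ``(sentence, mentions, config)``
    signature.
    """
    phrases = extract_key_phrases(sentence, lexicon, nouns)
    mentions = map_entities(phrases, lexicon)
    extractor = relation_extractor or extract_relations
    relations = extractor(sentence, mentions, relation_config)
    return SentenceAnalysis(sentence, phrases, mentions, relations)


# ---------------------------------------------------------------------------
# rule evaluation
# ---------------------------------------------------------------------------


def _arg_spec(spec: str) -> tuple[str, str]:
    kind, _, value = spec.partition(":")
    if kind not in ("entity", "token") or not value:
        raise ValueError(f"bad relation argument {spec!r}; "
                         "expected 'entity:<Type>' or 'token:<word>'")
    return kind, value


def _arg_matches(spec: str, actual, assignment: dict[str, EntityMention]) -> bool:
    kind, value = _arg_spec(spec)
    if kind == "token":
        return isinstance(actual, str) and actual == value.lower()
    return isinstance(actual, EntityMention) and actual is assignment.get(value)


def _lexical_match(anchor: str, tokens: tuple[str, ...]) -> bool:
    want = anchor.lower().split()
    low = [t.lower() for t in tokens]
    return any(low[i:i + len(want)] == want
               for i in range(len(low) - len(want) + 1))


def evaluate_rule(
    rule: Rule,
    analysis: SentenceAnalysis,
    kb: RelationPairStore | None = None,
    declared_types: set[str] | None = None,
) -> bool:
    """True iff some consistent mention assignment satisfies every condition.

    Entity types referenced by the rule become variables; each is bound to
    one mention of that type and all conditions are checked under the
    binding. The search is an exhaustive product over per-type candidates,
    which is cheap because sentences carry only a handful of mentions.
    """
    types_needed: list[str] = []
    for cond in rule.conditions:
        pred = cond["pred"]
        if pred == "ENTITY":
            types_needed.append(cond["type"])
        elif pred == "REL":
            for side in ("a", "b"):
                kind, value = _arg_spec(cond[side])
                if kind == "entity":
                    types_needed.append(value)
        elif pred == "KB_PAIR":
            types_needed.extend([cond["type_a"], cond["type_b"]])
        elif pred != "LEXICAL":
            raise ValueError(f"unknown predicate {pred!r} in rule {rule.id!r}")
    types_needed = sorted(set(types_needed))
    if declared_types is not None:
        unknown = [t for t in types_needed if t not in declared_types]
        if unknown:
            raise ValueError(
                f"rule {rule.id!r} references undeclared entity types {unknown}"
            )

    # lexical conditions do not depend on the assignment
    for cond in rule.conditions:
        if cond["pred"] == "LEXICAL":
            if not _lexical_match(cond["anchor"], analysis.sentence.tokens):
                return False

    candidates = {
        t: [m for m in analysis.mentions if m.entity_type == t]
        for t in types_needed
    }
    if any(not c for c in candidates.values()):
        return False

    for combo in itertools.product(*(candidates[t] for t in types_needed)):
        assignment = dict(zip(types_needed, combo))
        ok = True
        for cond in rule.conditions:
            pred = cond["pred"]
            if pred == "LEXICAL":
                continue
            if pred == "ENTITY":
                pass  # satisfied by the binding's existence
            elif pred == "REL":
                if not any(
                    r.kind == cond["kind"]
                    and _arg_matches(cond["a"], r.source, assignment)
                    and _arg_matches(cond["b"], r.target, assignment)
                    for r in analysis.relations
                ):
                    ok = False
                    break
            elif pred == "KB_PAIR":
                if kb is None:
                    ok = False
                    break
                a = assignment[cond["type_a"]]
                b = assignment[cond["type_b"]]
                if not kb.lookup(cond["relation"], a.surface, b.surface):
                    ok = False
                    break
        if ok:
            return True
    return False


def label_sentence(
    analysis: SentenceAnalysis,
    ruleset: RuleSet,
    kb: RelationPairStore | None,
    tree: CategoryTree,
) -> SentenceLabel | None:
    """Assign the highest-priority firing rule's subcategory, or None.

    Rules are tried in (priority, id) order, so the result is independent
    of the order rules were listed in the configuration file.
    """
    for rule in ruleset:
        if evaluate_rule(rule, analysis, kb):
            return SentenceLabel(
                inquiry_id=analysis.sentence.inquiry_id,
                index=analysis.sentence.index,
                text=analysis.sentence.text,
                subcategory=rule.label,
                root=rollup(rule.label, tree),
                rule_id=rule.id,
            )
    return None


@dataclass
class WeakLabeledDataset:
    """Weak labels for a corpus, partitioned by trainability."""

    labels: list[SentenceLabel]          # one per input sentence, in order
    trainable: list[SentenceLabel] = field(default_factory=list)
    fallback: list[SentenceLabel] = field(default_factory=list)
    counts: Counter = field(default_factory=Counter)


def label_corpus(
    sentences: list[CleanSentence],
    ruleset: RuleSet,
    kb: RelationPairStore | None,
    lexicon: EntityLexicon,
    tree: CategoryTree,
    nouns: frozenset[str] = frozenset(),
    relation_config: RelationConfig | None = None,
) -> WeakLabeledDataset:
    """Label every sentence; unmatched sentences get the fallback label."""
    ruleset.validate(tree)
    out = WeakLabeledDataset(labels=[])
    for sent in sentences:
        analysis = analyze_sentence(sent, lexicon, nouns, relation_config)
        label = label_sentence(analysis, ruleset, kb, tree)
        if label is None:
            label = SentenceLabel(
                sent.inquiry_id, sent.index, sent.text,
                tree.fallback, tree.fallback, None,
            )
            out.fallback.append(label)
        else:
            out.trainable.append(label)
        out.labels.append(label)
        out.counts[label.subcategory] += 1
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_rule_config(path) -> tuple[RuleSet, CategoryTree, RelationConfig]:
    """Load the one-document rule configuration (YAML).

    Schema: ``tree`` (subcategory -> root), ``fallback`` (label string),
    ``rules`` (list of {id, priority, label, conditions}), and an optional
    ``relation_config`` ({window, connectives, modifier_tokens,
    verb_tokens}).
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    tree = CategoryTree(doc["tree"], doc.get("fallback", "General or Other"))
    rules = [
        Rule(
            id=str(r["id"]),
            priority=int(r["priority"]),
            label=r["label"],
            conditions=tuple(r["conditions"]),
        )
        for r in doc["rules"]
    ]
    ruleset = RuleSet(rules, name=doc.get("name", "ruleset"),
                      version=str(doc.get("version", "1")))
    ruleset.validate(tree)
    rc = doc.get("relation_config", {})
    relation_config = RelationConfig(
        window=int(rc.get("window", 6)),
        connectives=frozenset(rc.get("connectives", RelationConfig().connectives)),
        modifier_tokens=frozenset(rc.get("modifier_tokens",
                                         RelationConfig().modifier_tokens)),
        verb_tokens=frozenset(rc.get("verb_tokens", RelationConfig().verb_tokens)),
    )
    return ruleset, tree, relation_config
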