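"""Entity lexicon and typed relation-pair store.

The lexicon maps surface forms (one or more tokens) to entity types such as
Treatment, Condition, Document or Professional; the pair store records which
ordered surface pairs stand in a named relation (for example, which
Condition-Treatment pairs are known adverse effects). Together they stand in
for the curated medical knowledgebase the weak-labeling rules consult.

Matching is case-insensitive exact on whitespace-normalized surfaces; no
stemming or fuzzy matching is applied, because the labeling rules depend on
exact anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EntityLexicon",
    "EntityMention",
    "RelationPairStore",
    "load_lexicon",
    "load_pairs",
]


def _norm(surface: str) -> str:
    return " ".join(surface.split()).lower()


@dataclass(frozen=True)
class EntityMention:
    """A lexicon hit inside one sentence."""

    surface: str          # the lexicon surface form (normalized)
    entity_type: str
    token_start: int      # token index span in the sentence, half-open
    token_end: int
    phrase_text: str      # the key-phrase text that produced the mention


class EntityLexicon:
    """Surface form -> entity type gazetteer (case-insensitive)."""

    def __init__(self, entries: dict[str, str] | None = None):
        self.entries: dict[str, str] = {}
        for surface, etype in (entries or {}).items():
            self.add(surface, etype)

    def add(self, surface: str, entity_type: str) -> None:
        key = _norm(surface)
        if not key:
            raise ValueError("empty surface form")
        existing = self.entries.get(key)
        if existing is not None and existing != entity_type:
            raise ValueError(
                f"surface {surface!r} already mapped to {existing!r}, "
                f"cannot remap to {entity_type!r}"
            )
        self.entries[key] = entity_type

    def get(self, surface: str) -> str | None:
        return self.entries.get(_norm(surface))

    def __contains__(self, surface: str) -> bool:
        return _norm(surface) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def types(self) -> set[str]:
        return set(self.entries.values())

    def surfaces_of(self, entity_type: str) -> list[str]:
        return sorted(s for s, t in self.entries.items() if t == entity_type)

    def max_surface_tokens(self) -> int:
        return max((len(s.split()) for s in self.entries), default=1)

    def tokens(self) -> set[str]:
        """Every individual token appearing in any surface form."""
        out: set[str] = set()
        for s in self.entries:
            out.update(s.split())
        return out

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for surface in sorted(self.entries):
                fh.write(f"{surface}\t{self.entries[surface]}\n")


def load_lexicon(path) -> EntityLexicon:
    """Load a two-column (surface, entity_type) TSV.

    Duplicate surfaces with conflicting types are a hard error, reported
    with the offending line number.
    """
    lex = EntityLexicon()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: expected 'surface<TAB>type'")
            try:
                lex.add(parts[0], parts[1].strip())
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return lex


class RelationPairStore:
    """Named relations over ordered (surface_a, surface_b) pairs."""

    def __init__(self):
        self._pairs: dict[str, set[tuple[str, str]]] = {}
        self.argument_types: dict[str, tuple[str, str]] = {}

    def add(self, relation: str, a: str, b: str,
            types: tuple[str, str] | None = None) -> None:
        self._pairs.setdefault(relation, set()).add((_norm(a), _norm(b)))
        if types is not None:
            self.argument_types[relation] = types

    def relations(self) -> set[str]:
        return set(self._pairs)

    def pairs(self, relation: str) -> set[tuple[str, str]]:
        if relation not in self._pairs:
            raise KeyError(f"unknown relation {relation!r}")
        return set(self._pairs[relation])

    def lookup(self, relation: str, a: str, b: str) -> bool:
        """True iff the ordered pair (a, b) is registered under relation."""
        if relation not in self._pairs:
            raise KeyError(f"unknown relation {relation!r}")
        return (_norm(a), _norm(b)) in self._pairs[relation]

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rel in sorted(self._pairs):
                for a, b in sorted(self._pairs[rel]):
                    fh.write(f"{rel}\t{a}\t{b}\n")


def lookup_pair(store: RelationPairStore, relation: str,
                a: EntityMention | str, b: EntityMention | str) -> bool:
    """Membership test for an ordered mention/surface pair under a relation."""
    sa = a.surface if isinstance(a, EntityMention) else a
    sb = b.surface if isinstance(b, EntityMention) else b
    return store.lookup(relation, sa, sb)


def load_pairs(path) -> RelationPairStore:
    """Load a three-column (relation, surface_a, surface_b) TSV."""
    store = RelationPairStore()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'relation<TAB>a<TAB>b'"
                )
            store.add(parts[0].strip(), parts[1], parts[2])
    return store
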