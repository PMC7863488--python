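"""Typed triple store for the drug / side-effect / target / indication graph.

The knowledge graph has four entity kinds (drug, side_effect, target,
indication) and three relations, each linking a drug to one attribute kind:

    (drug, has_side_effect, side_effect)
    (drug, has_target,      target)
    (drug, has_indication,  indication)

Triples are stored deduplicated, and every token (entity id or relation
name) is assigned a stable integer index: the three relation names first,
in canonical order, then entities by first appearance.  That index map is
the vocabulary the embedding model trains over, so its determinism is what
makes embeddings reproducible across loads of the same file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Canonical relation order; fixes the first three vocabulary indices.
RELATIONS: tuple[str, ...] = ("has_target", "has_indication", "has_side_effect")

#: Entity kind implied by each relation's tail position.
RELATION_TAIL_KIND: dict[str, str] = {
    "has_target": "target",
    "has_indication": "indication",
    "has_side_effect": "side_effect",
}

KINDS: tuple[str, ...] = ("drug", "side_effect", "target", "indication")


class TripleParseError(ValueError):
    """A triple file line could not be parsed."""


class KindConflictError(ValueError):
    """The same entity id was asserted with two different kinds."""


@dataclass(frozen=True, order=True)
class Triple:
    """One (head, relation, tail) assertion; head is always a drug."""

    head: str
    relation: str
    tail: str

    def __post_init__(self) -> None:
        if self.relation not in RELATION_TAIL_KIND:
            raise ValueError(f"unknown relation {self.relation!r}")


class KnowledgeGraph:
    """Deduplicated typed triples plus a deterministic token vocabulary.

    Parameters
    ----------
    triples:
        Iterable of :class:`Triple` (or (head, relation, tail) tuples).
        Duplicates are collapsed with a logged warning.
    kinds:
        Optional explicit ``id -> kind`` map.  When absent, kinds are
        inferred from position: heads are drugs, tails take the kind the
        relation implies.  An explicit map wins over inference, but a
        contradiction (either between the map and a triple position, or
        between two triples) raises :class:`KindConflictError`.
    """

    def __init__(
        self,
        triples: Iterable[Triple | tuple[str, str, str]] = (),
        kinds: Mapping[str, str] | None = None,
    ) -> None:
        self._triples: list[Triple] = []
        self._entities: dict[str, str] = {}
        # Relations are registered eagerly so empty graphs still have a
        # well-defined vocabulary and indices never shift as triples arrive.
        self._vocab: dict[str, int] = {r: i for i, r in enumerate(RELATIONS)}

        explicit = dict(kinds) if kinds else {}
        for k, v in explicit.items():
            if v not in KINDS:
                raise ValueError(f"unknown entity kind {v!r} for id {k!r}")

        self._explicit = set(explicit)
        seen: set[tuple[str, str, str]] = set()
        n_dupes = 0
        for t in triples:
            if not isinstance(t, Triple):
                t = Triple(*t)
            key = (t.head, t.relation, t.tail)
            if key in seen:
                n_dupes += 1
                continue
            seen.add(key)
            self._register(t.head, explicit.get(t.head, "drug"))
            self._register(t.tail, explicit.get(t.tail, RELATION_TAIL_KIND[t.relation]))
            self._check(t)
            self._triples.append(t)
        # Entities present in the kind map but in no triple are still part
        # of the graph (isolated nodes are legal, e.g. after edge holdout).
        for ent, kind in explicit.items():
            self._register(ent, kind)
        if n_dupes:
            logger.warning("collapsed %d duplicate triples", n_dupes)

    def _register(self, ent: str, kind: str) -> None:
        if not ent:
            raise ValueError("empty entity id")
        prev = self._entities.get(ent)
        if prev is None:
            if ent in self._vocab:
                raise KindConflictError(f"entity id {ent!r} collides with a relation name")
            self._entities[ent] = kind
            self._vocab[ent] = len(self._vocab)
        elif prev != kind:
            # Inferred kinds of shared drug-label terms resolve to
            # side_effect, independent of triple order; any other
            # disagreement — and any disagreement with an explicit kind
            # assertion — is a genuine conflict.
            if {prev, kind} == {"indication", "side_effect"} and ent not in self._explicit:
                self._entities[ent] = "side_effect"
            else:
                raise KindConflictError(
                    f"entity {ent!r} asserted as both {prev!r} and {kind!r}"
                )

    def _check(self, t: Triple) -> None:
        if self._entities[t.head] != "drug":
            raise KindConflictError(
                f"head {t.head!r} of {t.relation} must be a drug, got {self._entities[t.head]!r}"
            )
        want = RELATION_TAIL_KIND[t.relation]
        got = self._entities[t.tail]
        # A side-effect term may also be asserted as some drug's indication
        # (drug-label vocabularies share terms across the two relations);
        # such edges are legal here and resolved by split.exclude_conflicts.
        if t.relation == "has_indication" and got == "side_effect":
            return
        if got != want:
            raise KindConflictError(
                f"tail {t.tail!r} of {t.relation} must be {want!r}, got {self._entities[t.tail]!r}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def triples(self) -> tuple[Triple, ...]:
        return tuple(self._triples)

    @property
    def entities(self) -> dict[str, str]:
        """``id -> kind`` for every registered entity."""
        return dict(self._entities)

    @property
    def vocabulary(self) -> dict[str, int]:
        """``token -> index`` over relations and entity ids (0..n-1)."""
        return dict(self._vocab)

    @property
    def n(self) -> int:
        """Vocabulary size: entities plus relation tokens."""
        return len(self._vocab)

    def entities_of_kind(self, kind: str) -> list[str]:
        if kind not in KINDS:
            raise ValueError(f"unknown entity kind {kind!r}")
        return [e for e, k in self._entities.items() if k == kind]

    def pairs(self, relation: str) -> list[tuple[str, str]]:
        """(head, tail) pairs of one relation, in triple order."""
        if relation not in RELATION_TAIL_KIND:
            raise ValueError(f"unknown relation {relation!r}")
        return [(t.head, t.tail) for t in self._triples if t.relation == relation]

    def relation_counts(self) -> dict[str, int]:
        """Per-relation triple counts plus their total."""
        counts = {r: 0 for r in RELATIONS}
        for t in self._triples:
            counts[t.relation] += 1
        counts["total"] = len(self._triples)
        return counts

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, item: Triple | tuple[str, str, str]) -> bool:
        if isinstance(item, Triple):
            item = (item.head, item.relation, item.tail)
        return any((t.head, t.relation, t.tail) == item for t in self._triples)


# -- file I/O --------------------------------------------------------------


def read_kinds(path: str | Path) -> dict[str, str]:
    """Read an ``id<TAB>kind`` TSV into a kind map."""
    kinds: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise TripleParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            ent, kind = fields
            if ent in kinds and kinds[ent] != kind:
                raise KindConflictError(f"{path}:{lineno}: conflicting kind for {ent!r}")
            kinds[ent] = kind
    return kinds


def read_triples(
    path: str | Path, kinds: Mapping[str, str] | str | Path | None = None
) -> KnowledgeGraph:
    """Load a ``head<TAB>relation<TAB>tail`` TSV into a KnowledgeGraph.

    ``kinds`` may be a mapping or a path to a kind TSV.  Lines starting
    with ``#`` and blank lines are ignored.  Duplicate triples collapse.
    """
    if isinstance(kinds, (str, Path)):
        kinds = read_kinds(kinds)
    triples: list[Triple] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise TripleParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            try:
                triples.append(Triple(*fields))
            except ValueError as exc:
                raise TripleParseError(f"{path}:{lineno}: {exc}") from exc
    return KnowledgeGraph(triples, kinds=kinds)


def write_triples(kg: KnowledgeGraph, path: str | Path) -> None:
    """Write the graph as triple TSV; one line per stored triple."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in kg.triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def write_kinds(kg: KnowledgeGraph, path: str | Path) -> None:
    """Write the entity kind map as ``id<TAB>kind`` TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for ent, kind in kg.entities.items():
            fh.write(f"{ent}\t{kind}\n")
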