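"""Synthetic drug/attribute knowledge graphs with planted block structure.

Real pharmacovigilance graphs are unavailable at desk scale, so pipeline
behaviour is exercised on generated graphs that reproduce their shape: a
bipartite drug -> attribute multigraph over three attribute kinds (side
effect, target, indication), with a latent cluster assignment shared by
drugs and attributes so that a drug's targets and indications carry
information about its likely side effects.  Edges follow a stochastic
block model: probability ``p_in`` within a cluster, ``p_out`` across.

``generate_null`` produces the matched no-signal graph (``p_in == p_out``)
used to check that the pipeline's discrimination comes from the planted
structure and not from an artefact of the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kg import KnowledgeGraph, Triple

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "generate",
    "generate_null",
    "generate_scale_replica",
]

# attribute kinds with their id prefix, relation and count attribute
_ATTRIBUTE_SPECS = (
    ("side_effect", "S", "has_side_effect", "n_side_effects"),
    ("target", "T", "has_target", "n_targets"),
    ("indication", "I", "has_indication", "n_indications"),
)


@dataclass(frozen=True)
class GeneratorParams:
    """Sizes and block-model probabilities of a synthetic graph.

    Defaults keep the ratios of a drug-label graph (more side effects than
    drugs, fewer curated targets/indications) at a scale where exact
    softmax training completes in about a minute on one CPU.
    """

    n_drugs: int = 200
    n_side_effects: int = 300
    n_targets: int = 100
    n_indications: int = 100
    n_clusters: int = 5
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out <= p_in <= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        for name in ("n_drugs", "n_side_effects", "n_targets", "n_indications"):
            if getattr(self, name) < self.n_clusters:
                raise ValueError(f"{name} must be >= n_clusters")


@dataclass(frozen=True)
class GroundTruth:
    """Latent cluster label for every generated entity."""

    clusters: dict[str, int]

    def cluster_of(self, entity: str) -> int:
        return self.clusters[entity]


def _round_robin(prefix: str, count: int, n_clusters: int) -> tuple[list[str], dict[str, int]]:
    ids = [f"{prefix}{i:04d}" for i in range(count)]
    return ids, {e: i % n_clusters for i, e in enumerate(ids)}


def generate(params: GeneratorParams) -> tuple[KnowledgeGraph, GroundTruth]:
    """Sample a block-model knowledge graph; deterministic given the seed.

    Entities of every kind are assigned to clusters round-robin.  For each
    drug x attribute cell (each attribute kind independently) an edge is
    drawn with probability ``p_in`` when drug and attribute share a cluster
    and ``p_out`` otherwise.  A drug's attribute set under has_indication is
    kept disjoint from its has_side_effect set: were the same (drug,
    attribute) pair ever sampled under both relations, the indication edge
    would be dropped, mirroring the rule that a drug's indication cannot be
    its own side effect.
    """
    rng = np.random.default_rng(params.seed)
    drugs, drug_clusters = _round_robin("D", params.n_drugs, params.n_clusters)
    clusters: dict[str, int] = dict(drug_clusters)
    kinds: dict[str, str] = {d: "drug" for d in drugs}
    drug_c = np.array([drug_clusters[d] for d in drugs])

    triples: list[Triple] = []
    pairs_by_relation: dict[str, set[tuple[str, str]]] = {}
    for kind, prefix, relation, count_attr in _ATTRIBUTE_SPECS:
        attrs, attr_clusters = _round_robin(prefix, getattr(params, count_attr), params.n_clusters)
        clusters.update(attr_clusters)
        kinds.update({a: kind for a in attrs})
        attr_c = np.array([attr_clusters[a] for a in attrs])
        prob = np.where(drug_c[:, None] == attr_c[None, :], params.p_in, params.p_out)
        hit = rng.random(prob.shape) < prob
        pairs = {(drugs[i], attrs[j]) for i, j in zip(*np.nonzero(hit))}
        pairs_by_relation[relation] = pairs

    conflicts = pairs_by_relation["has_indication"] & pairs_by_relation["has_side_effect"]
    pairs_by_relation["has_indication"] -= conflicts

    for _, _, relation, _ in _ATTRIBUTE_SPECS:
        for head, tail in sorted(pairs_by_relation[relation]):
            triples.append(Triple(head, relation, tail))

    return KnowledgeGraph(triples, kinds=kinds), GroundTruth(clusters)


def generate_null(params: GeneratorParams) -> tuple[KnowledgeGraph, GroundTruth]:
    """The matched no-signal graph: identical procedure with p_in = p_out."""
    return generate(replace(params, p_in=params.p_out))


def _sample_unique_pairs(
    rng: np.random.Generator, n_a: int, n_b: int, k: int
) -> np.ndarray:
    """k distinct cells of an n_a x n_b grid, as a (k, 2) index array."""
    if k > n_a * n_b:
        raise ValueError("more pairs requested than grid cells")
    chosen = np.empty(0, dtype=np.int64)
    while len(chosen) < k:
        extra = rng.integers(0, n_a * n_b, size=int(1.2 * (k - len(chosen))) + 16)
        chosen = np.unique(np.concatenate([chosen, extra]))
    # unique() sorts; subsample without replacement to kill ordering bias
    chosen = chosen[rng.choice(len(chosen), size=k, replace=False)]
    return np.column_stack(np.divmod(chosen, n_b))


def generate_scale_replica(
    n_drugs: int = 3632,
    n_side_effects: int = 5589,
    n_targets: int = 4286,
    n_indications: int = 2598,
    n_side_effect_pairs: int = 126_791,
    n_target_pairs: int = 13_851,
    n_indication_pairs: int = 13_597,
    seed: int = 0,
) -> KnowledgeGraph:
    """A graph with exactly the published entity and pair counts.

    Edges are uniform random distinct (drug, attribute) pairs with no
    planted structure; the point is to reproduce the bookkeeping of the
    real drug-label graph (holdout sizes, retained counts, totals) at full
    scale, not its signal.  Unlinked entities are still registered so the
    per-kind entity counts match exactly.
    """
    rng = np.random.default_rng(seed)
    kinds: dict[str, str] = {f"D{i:04d}": "drug" for i in range(n_drugs)}
    triples: list[Triple] = []
    for kind, prefix, relation, n_attrs, n_pairs in (
        ("side_effect", "S", "has_side_effect", n_side_effects, n_side_effect_pairs),
        ("target", "T", "has_target", n_targets, n_target_pairs),
        ("indication", "I", "has_indication", n_indications, n_indication_pairs),
    ):
        kinds.update({f"{prefix}{j:04d}": kind for j in range(n_attrs)})
        for i, j in _sample_unique_pairs(rng, n_drugs, n_attrs, n_pairs):
            triples.append(Triple(f"D{i:04d}", relation, f"{prefix}{j:04d}"))
    return KnowledgeGraph(triples, kinds=kinds)
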