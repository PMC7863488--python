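"""Holdout protocol for embedding corpus and classifier train/test sets.

Observed drug-indication pairs serve as the classifier's negatives (a
drug's indication cannot simultaneously be its side effect), and observed
drug-side-effect pairs as positives.  The test set holds out 10% of the
indication pairs as negatives and an equal number of side-effect pairs as
positives; both held-out sets are excluded from the embedding corpus and
from classifier training, simulating unknown ADRs.  Retained indication
pairs are replicated tenfold among the training rows to offset the class
imbalance against the far more numerous side-effect pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .kg import KnowledgeGraph, Triple

logger = logging.getLogger(__name__)

__all__ = ["LabeledPair", "SplitBundle", "make_split", "exclude_conflicts", "write_split"]


@dataclass(frozen=True)
class LabeledPair:
    """A (drug, attribute) pair labelled 1 for has_side_effect, else 0."""

    drug: str
    attribute: str
    label: int


@dataclass(frozen=True)
class SplitBundle:
    """Embedding corpus plus labelled classifier train/test pairs."""

    embedding_corpus: KnowledgeGraph
    train_pairs: tuple[LabeledPair, ...]
    test_pairs: tuple[LabeledPair, ...]
    holdout_frac: float
    replication: int
    seed: int


def exclude_conflicts(kg: KnowledgeGraph) -> tuple[KnowledgeGraph, list[tuple[str, str]]]:
    """Drop indication edges that contradict a same-drug side-effect edge.

    A pair asserted under both has_indication and has_side_effect for the
    same drug is contradictory; the side-effect assertion is kept (the
    safety-conservative reading) and the indication edge removed.  Returns
    the cleaned graph and the list of removed (drug, attribute) pairs.
    """
    se_pairs = set(kg.pairs("has_side_effect"))
    removed = []
    kept = []
    for t in kg.triples:
        if t.relation == "has_indication" and (t.head, t.tail) in se_pairs:
            removed.append((t.head, t.tail))
        else:
            kept.append(t)
    if removed:
        logger.warning(
            "removed %d indication edges that conflict with same-drug side effects", len(removed)
        )
    return KnowledgeGraph(kept, kinds=kg.entities), removed


def make_split(
    kg: KnowledgeGraph,
    holdout_frac: float = 0.1,
    replication: int = 10,
    seed: int = 0,
) -> SplitBundle:
    """Build the embedding corpus and classifier train/test pair sets.

    The holdout count is ``floor(holdout_frac * #indication pairs)``; test
    negatives are drawn uniformly without replacement from the indication
    pairs and test positives, in equal number, from the side-effect pairs.
    Held-out edges vanish from the embedding corpus; every retained
    side-effect pair becomes a training positive, every retained indication
    pair ``replication`` identical training negatives.  Sampling of
    negatives and positives uses independent streams derived from the seed,
    so changing one pool does not perturb the other draw.
    """
    if not 0.0 < holdout_frac < 1.0:
        raise ValueError("holdout_frac must be in (0, 1)")
    if replication < 1:
        raise ValueError("replication must be >= 1")
    ind_pairs = kg.pairs("has_indication")
    se_pairs = kg.pairs("has_side_effect")
    n_hold = math.floor(holdout_frac * len(ind_pairs))
    if n_hold == 0:
        raise ValueError("holdout too small: no indication pairs would be held out")
    if len(se_pairs) < n_hold:
        raise ValueError(
            f"need at least {n_hold} side-effect pairs for test positives, have {len(se_pairs)}"
        )

    neg_rng, pos_rng = (np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2))
    test_neg_idx = set(neg_rng.choice(len(ind_pairs), size=n_hold, replace=False).tolist())
    test_pos_idx = set(pos_rng.choice(len(se_pairs), size=n_hold, replace=False).tolist())

    held_out: set[tuple[str, str, str]] = set()
    test_pairs: list[LabeledPair] = []
    for i in sorted(test_pos_idx):
        d, a = se_pairs[i]
        held_out.add((d, "has_side_effect", a))
        test_pairs.append(LabeledPair(d, a, 1))
    for i in sorted(test_neg_idx):
        d, a = ind_pairs[i]
        held_out.add((d, "has_indication", a))
        test_pairs.append(LabeledPair(d, a, 0))

    corpus_triples = [t for t in kg.triples if (t.head, t.relation, t.tail) not in held_out]
    # Keep all entities registered so vectors exist even for nodes that
    # lost their last edge to the holdout (their vectors stay near init).
    corpus = KnowledgeGraph(corpus_triples, kinds=kg.entities)

    train_pairs: list[LabeledPair] = []
    for t in corpus_triples:
        if t.relation == "has_side_effect":
            train_pairs.append(LabeledPair(t.head, t.tail, 1))
    neg_template = [
        LabeledPair(t.head, t.tail, 0) for t in corpus_triples if t.relation == "has_indication"
    ]
    train_pairs.extend(neg_template * replication)

    logger.info(
        "split: %d test pos, %d test neg, %d train pos, %d train neg rows, corpus %d triples",
        n_hold,
        n_hold,
        sum(p.label for p in train_pairs),
        len(train_pairs) - sum(p.label for p in train_pairs),
        len(corpus_triples),
    )
    return SplitBundle(
        embedding_corpus=corpus,
        train_pairs=tuple(train_pairs),
        test_pairs=tuple(test_pairs),
        holdout_frac=holdout_frac,
        replication=replication,
        seed=seed,
    )


def write_split(bundle: SplitBundle, outdir: str | Path) -> None:
    """Write corpus triples, train pairs, test pairs and metadata as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .kg import write_triples

    write_triples(bundle.embedding_corpus, outdir / "corpus.tsv")
    for name, pairs in (("train_pairs.tsv", bundle.train_pairs), ("test_pairs.tsv", bundle.test_pairs)):
        with open(outdir / name, "w", encoding="utf-8") as fh:
            for p in pairs:
                fh.write(f"{p.drug}\t{p.attribute}\t{p.label}\n")
    counts = bundle.embedding_corpus.relation_counts()
    with open(outdir / "split_meta.tsv", "w", encoding="utf-8") as fh:
        fh.write(f"holdout_frac\t{bundle.holdout_frac}\n")
        fh.write(f"replication\t{bundle.replication}\n")
        fh.write(f"seed\t{bundle.seed}\n")
        fh.write(f"n_train\t{len(bundle.train_pairs)}\n")
        fh.write(f"n_test\t{len(bundle.test_pairs)}\n")
        for k, v in counts.items():
            fh.write(f"corpus_{k}\t{v}\n")
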