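"""End-to-end orchestration: split -> embed -> fit -> evaluate, repeats, sweeps.

The repeat protocol mirrors the original evaluation: for each repeat the
data are re-split with a fresh derived seed and the embedding and
classifier are retrained from scratch, so every repeat's test set is
disjoint from everything that repeat trained on.  The sweep harness holds
the split fixed and varies only embedding hyperparameters (iterations,
vector size), isolating their effect on held-out AUC.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from .embedding import TripleCBOW
from .kg import KnowledgeGraph
from .metrics import EvalReport, evaluate
from .split import LabeledPair, SplitBundle, exclude_conflicts, make_split

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_once", "run_experiment", "run_sweep", "run_rank", "read_pairs"]

_METRIC_COLS = ["precision", "recall", "f_score", "auc"]


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration for a full pipeline run.

    Defaults follow the published parameterisation (vector size 800, 2500
    embedding iterations, 10% indication holdout with tenfold negative
    replication, C=1 logistic regression capped at 10,000 iterations,
    classification threshold 0.5).
    """

    size: int = 800
    iters: int = 2500
    mode: str = "full_softmax"
    combiner: str = "sum"
    lr_initial: float = 0.025
    lr_final: float = 1e-4
    batch_size: int = 256
    holdout_frac: float = 0.1
    replication: int = 10
    C: float = 1.0
    max_iter: int = 10000
    threshold: float = 0.5
    seed: int = 0
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _embedder(config: RunConfig, seed: int) -> TripleCBOW:
    return TripleCBOW(
        size=config.size,
        iters=config.iters,
        mode=config.mode,
        combiner=config.combiner,
        lr_initial=config.lr_initial,
        lr_final=config.lr_final,
        batch_size=config.batch_size,
        random_state=seed,
    )


def run_once(
    kg: KnowledgeGraph, config: RunConfig, seed: int | None = None
) -> tuple[EvalReport, TripleCBOW, clf.DifferencePairClassifier, SplitBundle]:
    """One split -> embed -> fit -> evaluate pass; returns all artifacts."""
    seed = config.seed if seed is None else seed
    kg, removed = exclude_conflicts(kg)
    if removed:
        logger.info("dropped %d conflicting indication edges before splitting", len(removed))
    bundle = make_split(
        kg, holdout_frac=config.holdout_frac, replication=config.replication, seed=seed
    )
    logger.info(
        "seed %d: corpus %d triples, %d train rows, %d test pairs",
        seed,
        len(bundle.embedding_corpus),
        len(bundle.train_pairs),
        len(bundle.test_pairs),
    )
    embedder = _embedder(config, seed).fit(bundle.embedding_corpus)
    vectors = embedder.vectors()
    model = clf.fit(
        bundle.train_pairs, vectors, C=config.C, max_iter=config.max_iter, seed=seed
    )
    preds = clf.score_pairs(model, vectors, bundle.test_pairs)
    report = evaluate(
        [p.probability for p in preds],
        [p.label for p in bundle.test_pairs],
        threshold=config.threshold,
    )
    logger.info("seed %d: AUC %.4f", seed, report.auc)
    return report, embedder, model, bundle


def run_experiment(kg: KnowledgeGraph, config: RunConfig) -> pd.DataFrame:
    """Repeat the full pipeline ``n_repeats`` times plus a mean row.

    Repeat r runs with seed ``config.seed + r`` and an independent
    re-split, re-embedding and re-fit.  The returned frame has one row per
    repeat (labelled ``repeat_1`` ...) and a final ``mean`` row holding the
    arithmetic mean of each metric column.
    """
    rows = []
    for r in range(config.n_repeats):
        seed_r = config.seed + r
        report, _, _, _ = run_once(kg, config, seed=seed_r)
        rows.append(
            {
                "experiment": f"repeat_{r + 1}",
                "seed": seed_r,
                **{k: getattr(report, k) for k in _METRIC_COLS},
            }
        )
    frame = pd.DataFrame(rows)
    mean_row = {"experiment": "mean", "seed": pd.NA}
    mean_row.update({k: frame[k].mean() for k in _METRIC_COLS})
    return pd.concat([frame, pd.DataFrame([mean_row])], ignore_index=True)


def run_sweep(
    kg: KnowledgeGraph,
    grid: Iterable[tuple[int, int]],
    config: RunConfig,
) -> pd.DataFrame:
    """Held-out AUC per (iters, size) grid cell on one shared split.

    The split and every seed are fixed across cells so that only the
    embedding hyperparameters differ; duplicate cells produce duplicate
    rows.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("sweep grid is empty")
    kg, _ = exclude_conflicts(kg)
    bundle = make_split(
        kg, holdout_frac=config.holdout_frac, replication=config.replication, seed=config.seed
    )
    rows = []
    for iters, size in grid:
        cell_cfg = replace(config, iters=iters, size=size)
        embedder = _embedder(cell_cfg, config.seed).fit(bundle.embedding_corpus)
        vectors = embedder.vectors()
        model = clf.fit(
            bundle.train_pairs, vectors, C=config.C, max_iter=config.max_iter, seed=config.seed
        )
        preds = clf.score_pairs(model, vectors, bundle.test_pairs)
        report = evaluate(
            [p.probability for p in preds],
            [p.label for p in bundle.test_pairs],
            threshold=config.threshold,
        )
        logger.info("sweep iters=%d size=%d: AUC %.4f", iters, size, report.auc)
        rows.append({"iters": iters, "size": size, "auc": report.auc})
    return pd.DataFrame(rows)


def run_rank(
    model: clf.DifferencePairClassifier,
    vectors: Mapping[str, np.ndarray],
    adr: str,
    drugs: Sequence[str],
    out: str | Path | None = None,
    top: int | None = None,
) -> pd.DataFrame:
    """Score every drug against one ADR, descending; optionally write CSV."""
    preds = clf.rank_drugs_for_adr(model, vectors, adr, drugs, top=top)
    frame = pd.DataFrame(
        {
            "drug_id": [p.drug for p in preds],
            "adr_id": [p.adr for p in preds],
            "probability": [round(p.probability, 6) for p in preds],
        }
    )
    if out is not None:
        frame.to_csv(out, index=False, float_format="%.6f")
    return frame


def read_pairs(path: str | Path) -> list[LabeledPair]:
    """Read a ``drug<TAB>attribute<TAB>label`` TSV written by write_split."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            pairs.append(LabeledPair(fields[0], fields[1], int(fields[2])))
    return pairs
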