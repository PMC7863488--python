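"""Logistic-regression link predictor on embedding differences.

A candidate (drug, ADR) link is scored from the single feature vector
x = v_ADR - v_drug through the standard logistic link

    P(link) = sigma(w . x + b),  sigma(t) = 1 / (1 + exp(-t)),

with w and b fitted by minimising the mean cross-entropy over labelled
training pairs plus an L2 penalty of strength 1/C (bias unpenalised).
One model scores every (drug, ADR) combination; there is no per-ADR
classifier.  Ranking and group-averaging helpers support the literature-
screening workflow (order all drugs by predicted probability of a given
ADR) and cohort summaries (mean predicted probability per annotation
group).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .split import LabeledPair

__all__ = [
    "DifferencePairClassifier",
    "Prediction",
    "feature_vector",
    "predict_probability",
    "fit",
    "score_pairs",
    "rank_drugs_for_adr",
    "group_mean_probability",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class Prediction:
    """Predicted probability that ``drug`` causes ``adr``."""

    drug: str
    adr: str
    probability: float


def feature_vector(drug_vec: np.ndarray, adr_vec: np.ndarray) -> np.ndarray:
    """Classifier input for one pair: ``adr_vec - drug_vec``."""
    drug_vec = np.asarray(drug_vec, dtype=np.float64)
    adr_vec = np.asarray(adr_vec, dtype=np.float64)
    if drug_vec.shape != adr_vec.shape:
        raise ValueError(f"vector length mismatch: {drug_vec.shape} vs {adr_vec.shape}")
    return adr_vec - drug_vec


def predict_probability(model: "DifferencePairClassifier", feature: np.ndarray) -> float:
    """sigma(w . feature + b) for one feature vector."""
    feature = np.asarray(feature, dtype=np.float64)
    if not np.isfinite(feature).all():
        raise ValueError("feature vector contains non-finite values")
    if feature.shape != (model.w_.shape[0],):
        raise ValueError(f"expected feature of length {model.w_.shape[0]}")
    z = float(model.w_ @ feature + model.b_)
    return float(1.0 / (1.0 + np.exp(-z)))


class DifferencePairClassifier(ClassifierMixin, BaseEstimator):
    """L2-regularised logistic regression over pair-difference features.

    Thin estimator over :class:`sklearn.linear_model.LogisticRegression`
    (SAG solver, the convex optimiser used throughout) exposing the fitted
    weight vector ``w_`` and bias ``b_``, plus pair-level helpers that take
    a ``token -> vector`` map and labelled (drug, attribute) pairs.

    Parameters
    ----------
    C : float, default=1.0
        Inverse regularisation strength of the L2 penalty.
    max_iter : int, default=10000
        Solver iteration cap.
    solver : str, default="sag"
        Any sklearn LogisticRegression solver name.
    random_state : int or None
        Seed for the stochastic solver.
    """

    def __init__(
        self,
        C: float = 1.0,
        max_iter: int = 10000,
        solver: str = "sag",
        random_state: int | None = None,
    ) -> None:
        self.C = C
        self.max_iter = max_iter
        self.solver = solver
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: Sequence[int]) -> "DifferencePairClassifier":
        """Fit on precomputed difference features X (m, size), labels y."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        labels = set(np.unique(y).tolist())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be 0/1, got {sorted(labels)}")
        if len(labels) < 2:
            raise ValueError("training data must contain both classes")
        lr = LogisticRegression(
            C=self.C,
            solver=self.solver,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        lr.fit(X, y)
        self._sk = lr
        self.w_ = lr.coef_[0].copy()
        self.b_ = float(lr.intercept_[0])
        self.classes_ = lr.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def fit_pairs(
        self, pairs: Iterable[LabeledPair], vectors: Mapping[str, np.ndarray]
    ) -> "DifferencePairClassifier":
        """Fit from labelled (drug, attribute) pairs and an embedding map."""
        X, y = _pair_features(pairs, vectors)
        if len(X) == 0:
            raise ValueError("no training pairs supplied")
        return self.fit(X, y)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return X @ self.w_ + self.b_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.0).astype(int)


def _pair_features(
    pairs: Iterable[LabeledPair], vectors: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    feats = []
    labels = []
    missing: list[str] = []
    for p in pairs:
        bad = [tok for tok in (p.drug, p.attribute) if tok not in vectors]
        if bad:
            missing.extend(bad)
            continue
        feats.append(feature_vector(vectors[p.drug], vectors[p.attribute]))
        labels.append(p.label)
    if missing:
        raise KeyError(f"no embedding vector for tokens: {sorted(set(missing))[:10]}")
    return np.asarray(feats), np.asarray(labels)


def fit(
    train_pairs: Iterable[LabeledPair],
    vectors: Mapping[str, np.ndarray],
    C: float = 1.0,
    max_iter: int = 10000,
    seed: int | None = None,
) -> DifferencePairClassifier:
    """Fit the link predictor from labelled pairs and an embedding map."""
    return DifferencePairClassifier(C=C, max_iter=max_iter, random_state=seed).fit_pairs(
        train_pairs, vectors
    )


def score_pairs(
    model: DifferencePairClassifier,
    vectors: Mapping[str, np.ndarray],
    pairs: Iterable[tuple[str, str] | LabeledPair],
) -> list[Prediction]:
    """One Prediction per (drug, attribute) pair, in input order."""
    out: list[Prediction] = []
    for p in pairs:
        drug, attr = (p.drug, p.attribute) if isinstance(p, LabeledPair) else p
        for tok in (drug, attr):
            if tok not in vectors:
                raise KeyError(f"no embedding vector for token {tok!r}")
        prob = predict_probability(model, feature_vector(vectors[drug], vectors[attr]))
        out.append(Prediction(drug, attr, prob))
    return out


def rank_drugs_for_adr(
    model: DifferencePairClassifier,
    vectors: Mapping[str, np.ndarray],
    adr: str,
    drugs: Sequence[str],
    top: int | None = None,
) -> list[Prediction]:
    """Drugs ordered by descending probability of causing ``adr``.

    Ties break by drug id so the ranking is deterministic.
    """
    if adr not in vectors:
        raise KeyError(f"no embedding vector for ADR {adr!r}")
    preds = score_pairs(model, vectors, [(d, adr) for d in drugs])
    preds.sort(key=lambda p: (-p.probability, p.drug))
    return preds if top is None else preds[:top]


def group_mean_probability(
    predictions: Iterable[Prediction], grouping: Mapping[str, str]
) -> dict[str, float]:
    """Arithmetic mean predicted probability per drug group."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for p in predictions:
        if p.drug not in grouping:
            raise KeyError(f"drug {p.drug!r} has no group assignment")
        g = grouping[p.drug]
        sums[g] = sums.get(g, 0.0) + p.probability
        counts[g] = counts.get(g, 0) + 1
    return {g: sums[g] / counts[g] for g in sums}


def save_model(model: DifferencePairClassifier, path: str | Path) -> None:
    """Persist size, C, b and the weight coordinates as plain text."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"size\t{model.w_.shape[0]}\n")
        fh.write(f"C\t{model.C}\n")
        fh.write(f"b\t{model.b_!r}\n")
        for x in model.w_:
            fh.write(f"{float(x)!r}\n")


def load_model(path: str | Path) -> DifferencePairClassifier:
    """Load a model written by :func:`save_model`."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    header = dict(ln.split("\t") for ln in lines[:3])
    size = int(header["size"])
    w = np.array([float(x) for x in lines[3:]])
    if len(w) != size:
        raise ValueError(f"{path}: expected {size} weights, found {len(w)}")
    model = DifferencePairClassifier(C=float(header["C"]))
    model.w_ = w
    model.b_ = float(header["b"])
    model.classes_ = np.array([0, 1])
    model.n_features_in_ = size
    return model
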