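"""CBOW-style softmax embedding of a knowledge graph treated as a corpus.

Every triple (head, relation, tail) is read as a three-token sentence, and
each token in turn is predicted from the other two: the two context one-hot
vectors are projected through an input matrix ``W1`` (n x size), combined
(summed by default), multiplied by an output matrix ``W2`` (size x n) and
pushed through a softmax,

    p(. | c1, c2) = softmax((x_c1 + x_c2) . W1 . W2),

and training minimises the summed negative log-probability of the held-out
token over all samples.  After training, the rows of ``W1`` are the entity
(and relation) vectors.

Two output objectives are provided: exact full softmax, faithful to the
model equations and feasible for vocabularies up to a few tens of
thousands, and negative sampling for larger graphs.  Optimisation is
plain minibatch SGD: per-sample gradients are summed within a minibatch
and applied with a linearly decaying learning rate, which reproduces
classic per-sample word2vec SGD up to within-batch staleness.
"""

from __future__ import annotations

import numbers
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .kg import KnowledgeGraph

__all__ = [
    "TripleCBOW",
    "build_corpus",
    "expand_samples",
    "expand_corpus",
    "forward_probabilities",
    "sample_loss",
    "corpus_loss_gradients",
    "save_vectors",
    "load_vectors",
]


def build_corpus(kg: KnowledgeGraph) -> np.ndarray:
    """Turn a graph into a (T, 3) array of (head, relation, tail) indices."""
    vocab = kg.vocabulary
    corpus = np.empty((len(kg), 3), dtype=np.int64)
    for i, t in enumerate(kg.triples):
        corpus[i] = (vocab[t.head], vocab[t.relation], vocab[t.tail])
    return corpus


def expand_samples(sentence: Sequence[int]) -> list[tuple[tuple[int, int], int]]:
    """The three (context pair, target) samples of one 3-token sentence."""
    if len(sentence) != 3:
        raise ValueError("a sentence is exactly three tokens")
    h, r, t = (int(x) for x in sentence)
    return [((r, t), h), ((h, t), r), ((h, r), t)]


def expand_corpus(corpus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`expand_samples` over a (T, 3) corpus.

    Returns ``(contexts, targets)`` with shapes (3T, 2) and (3T,); sample
    order is sentence-major, target position h, r, t within each sentence.
    """
    corpus = np.asarray(corpus)
    if corpus.ndim != 2 or corpus.shape[1] != 3:
        raise ValueError("corpus must have shape (T, 3)")
    h, r, t = corpus[:, 0], corpus[:, 1], corpus[:, 2]
    contexts = np.empty((3 * len(corpus), 2), dtype=np.int64)
    targets = np.empty(3 * len(corpus), dtype=np.int64)
    contexts[0::3] = np.column_stack([r, t])
    targets[0::3] = h
    contexts[1::3] = np.column_stack([h, t])
    targets[1::3] = r
    contexts[2::3] = np.column_stack([h, r])
    targets[2::3] = t
    return contexts, targets


def _combine(W1: np.ndarray, contexts: np.ndarray, combiner: str) -> np.ndarray:
    hidden = W1[contexts[:, 0]] + W1[contexts[:, 1]]
    if combiner == "mean":
        hidden *= 0.5
    elif combiner != "sum":
        raise ValueError(f"unknown context combiner {combiner!r}")
    return hidden


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    np.exp(shifted, out=shifted)
    shifted /= shifted.sum(axis=1, keepdims=True)
    return shifted


def forward_probabilities(
    W1: np.ndarray, W2: np.ndarray, context: Sequence[int], combiner: str = "sum"
) -> np.ndarray:
    """Length-n softmax output distribution for one context pair."""
    c1, c2 = (int(c) for c in context)
    n = W1.shape[0]
    if not (0 <= c1 < n and 0 <= c2 < n):
        raise IndexError(f"context index out of range for vocabulary of size {n}")
    logits = _combine(W1, np.array([[c1, c2]]), combiner) @ W2
    return _softmax_rows(logits.astype(np.float64, copy=False))[0]


def sample_loss(
    W1: np.ndarray,
    W2: np.ndarray,
    context: Sequence[int],
    target: int,
    combiner: str = "sum",
) -> float:
    """Negative log-probability of the target token given its context."""
    p = forward_probabilities(W1, W2, context, combiner)
    target = int(target)
    if not 0 <= target < W1.shape[0]:
        raise IndexError("target index out of range")
    return float(-np.log(p[target]))


def corpus_loss_gradients(
    W1: np.ndarray,
    W2: np.ndarray,
    contexts: np.ndarray,
    targets: np.ndarray,
    combiner: str = "sum",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Summed cross-entropy loss and its exact gradients over samples.

    Returns ``(loss, dW1, dW2)`` for the full-softmax objective; the same
    routine drives both training minibatches and gradient verification.
    """
    contexts = np.asarray(contexts)
    targets = np.asarray(targets)
    hidden = _combine(W1, contexts, combiner)
    logits = hidden @ W2
    # log-softmax, numerically stable
    shifted = logits - logits.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1))
    rows = np.arange(len(targets))
    loss = float((logz - shifted[rows, targets]).sum())

    err = _softmax_rows(logits)  # (B, n)
    err[rows, targets] -= 1.0
    dW2 = hidden.T @ err
    dhidden = err @ W2.T
    if combiner == "mean":
        dhidden *= 0.5
    dW1 = np.zeros_like(W1)
    np.add.at(dW1, contexts.ravel(), np.repeat(dhidden, 2, axis=0))
    return loss, dW1, dW2


class TripleCBOW(TransformerMixin, BaseEstimator):
    """Knowledge-graph embedding by context-sum softmax prediction on triples.

    Parameters
    ----------
    size : int, default=800
        Embedding dimension (rows of ``W_in_``).
    iters : int, default=2500
        Training epochs over the corpus; 0 returns the seeded
        initialisation unchanged.
    mode : {"full_softmax", "negative_sampling"}, default="full_softmax"
        Output objective.  Full softmax is exact; negative sampling
        approximates it with ``negative`` noise tokens per sample drawn
        from the unigram^(3/4) distribution.
    combiner : {"sum", "mean"}, default="sum"
        How the two context projections are combined; the model equations
        sum them, some reference trainers average.
    negative : int, default=5
        Noise samples per positive in negative-sampling mode.
    lr_initial, lr_final : float
        Linear learning-rate schedule over total minibatch updates.
    batch_size : int, default=256
        Samples per SGD update (gradients summed within a batch).
    dtype : {"float32", "float64"}, default="float32"
        Weight precision; single precision is the word-embedding norm.
    random_state : int or None
        Seed for initialisation, shuffling and noise draws.

    Attributes
    ----------
    W_in_ : ndarray of shape (n, size)
        Input matrix; row i is the vector of vocabulary token i.
    W_out_ : ndarray of shape (size, n)
        Output (softmax) matrix.
    vocab_ : dict[str, int]
        Token to row-index map (present when fitted on a KnowledgeGraph).
    loss_history_ : list[float]
        Mean training-sample loss per epoch, recorded before each update.
    """

    def __init__(
        self,
        size: int = 800,
        iters: int = 2500,
        mode: str = "full_softmax",
        combiner: str = "sum",
        negative: int = 5,
        lr_initial: float = 0.025,
        lr_final: float = 1e-4,
        batch_size: int = 256,
        dtype: str = "float32",
        random_state: int | None = None,
    ) -> None:
        self.size = size
        self.iters = iters
        self.mode = mode
        self.combiner = combiner
        self.negative = negative
        self.lr_initial = lr_initial
        self.lr_final = lr_final
        self.batch_size = batch_size
        self.dtype = dtype
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X: KnowledgeGraph | np.ndarray, y: None = None) -> "TripleCBOW":
        """Train on a KnowledgeGraph or a pre-built (T, 3) index corpus."""
        if isinstance(X, KnowledgeGraph):
            self.vocab_ = X.vocabulary
            n = X.n
            corpus = build_corpus(X)
        else:
            corpus = np.asarray(X, dtype=np.int64)
            if corpus.ndim != 2 or corpus.shape[1] != 3:
                raise ValueError("corpus must have shape (T, 3)")
            self.vocab_ = None
            n = int(corpus.max()) + 1 if corpus.size else 0
        if len(corpus) == 0:
            raise ValueError("cannot train on an empty corpus")
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if self.iters < 0:
            raise ValueError("iters must be >= 0")
        if self.mode not in ("full_softmax", "negative_sampling"):
            raise ValueError(f"unknown mode {self.mode!r}")

        dtype = np.dtype(self.dtype)
        rng = np.random.default_rng(self.random_state)
        self.n_ = n
        self.W_in_ = rng.uniform(-0.5 / self.size, 0.5 / self.size, size=(n, self.size)).astype(
            dtype
        )
        self.W_out_ = np.zeros((self.size, n), dtype=dtype)
        self.loss_history_ = []

        contexts, targets = expand_corpus(corpus)
        if self.iters == 0:
            return self
        if self.mode == "full_softmax":
            self._sgd_softmax(contexts, targets, rng)
        else:
            self._sgd_negative(contexts, targets, rng)
        if not (np.isfinite(self.W_in_).all() and np.isfinite(self.W_out_).all()):
            raise FloatingPointError("non-finite weights after training; lower the learning rate")
        return self

    def _lr(self, update: int, total: int) -> float:
        frac = update / max(total - 1, 1)
        return self.lr_initial + (self.lr_final - self.lr_initial) * frac

    def _sgd_softmax(self, contexts: np.ndarray, targets: np.ndarray, rng) -> None:
        W1, W2 = self.W_in_, self.W_out_
        S = len(targets)
        bs = min(self.batch_size, S)
        n_batches = (S + bs - 1) // bs
        total = n_batches * self.iters
        rows_full = np.arange(bs)
        u = 0
        for _ in range(self.iters):
            order = rng.permutation(S)
            epoch_loss = 0.0
            for b in range(n_batches):
                sel = order[b * bs : (b + 1) * bs]
                ctx = contexts[sel]
                tgt = targets[sel]
                hidden = _combine(W1, ctx, self.combiner)
                logits = hidden @ W2
                logits -= logits.max(axis=1, keepdims=True)
                np.exp(logits, out=logits)
                z = logits.sum(axis=1, keepdims=True)
                rows = rows_full[: len(sel)]
                p_target = logits[rows, tgt] / z[:, 0]
                epoch_loss -= float(np.log(np.maximum(p_target, 1e-30)).sum())
                err = logits
                err /= z
                err[rows, tgt] -= 1.0
                lr = self._lr(u, total)
                dhidden = err @ W2.T
                W2 -= lr * (hidden.T @ err)
                if self.combiner == "mean":
                    dhidden *= 0.5
                np.subtract.at(W1, ctx.ravel(), lr * np.repeat(dhidden, 2, axis=0))
                u += 1
            mean_loss = epoch_loss / S
            if not np.isfinite(mean_loss):
                raise FloatingPointError("non-finite training loss; lower the learning rate")
            self.loss_history_.append(mean_loss)

    def _sgd_negative(self, contexts: np.ndarray, targets: np.ndarray, rng) -> None:
        W1, W2 = self.W_in_, self.W_out_
        S = len(targets)
        n = self.n_
        # unigram^0.75 noise distribution over target occurrences
        freq = np.bincount(targets, minlength=n).astype(np.float64)
        noise = freq**0.75
        noise /= noise.sum()
        bs = min(self.batch_size, S)
        n_batches = (S + bs - 1) // bs
        total = n_batches * self.iters
        k = self.negative
        u = 0
        for _ in range(self.iters):
            order = rng.permutation(S)
            epoch_loss = 0.0
            for b in range(n_batches):
                sel = order[b * bs : (b + 1) * bs]
                ctx = contexts[sel]
                tgt = targets[sel]
                B = len(sel)
                hidden = _combine(W1, ctx, self.combiner)  # (B, size)
                neg = rng.choice(n, size=(B, k), p=noise)
                cols = np.concatenate([tgt[:, None], neg], axis=1)  # (B, 1+k)
                # scores s_ij = hidden_i . W2[:, cols_ij]
                wcols = W2.T[cols]  # (B, 1+k, size)
                scores = np.einsum("bs,bks->bk", hidden, wcols)
                labels = np.zeros_like(scores)
                labels[:, 0] = 1.0
                sig = 1.0 / (1.0 + np.exp(-scores))
                eps = 1e-12
                epoch_loss -= float(
                    np.log(np.maximum(sig[:, 0], eps)).sum()
                    + np.log(np.maximum(1.0 - sig[:, 1:], eps)).sum()
                )
                err = sig - labels  # (B, 1+k)
                lr = self._lr(u, total)
                dhidden = np.einsum("bk,bks->bs", err, wcols)
                dcols = err[:, :, None] * hidden[:, None, :]  # (B, 1+k, size)
                np.subtract.at(W2.T, cols.ravel(), lr * dcols.reshape(-1, self.size))
                if self.combiner == "mean":
                    dhidden *= 0.5
                np.subtract.at(W1, ctx.ravel(), lr * np.repeat(dhidden, 2, axis=0))
                u += 1
            mean_loss = epoch_loss / S
            if not np.isfinite(mean_loss):
                raise FloatingPointError("non-finite training loss; lower the learning rate")
            self.loss_history_.append(mean_loss)

    # -- lookups -----------------------------------------------------------

    def _index(self, token: str | int) -> int:
        if isinstance(token, str):
            if not self.vocab_:
                raise KeyError("model was fitted without a vocabulary; use integer indices")
            if token not in self.vocab_:
                raise KeyError(f"unknown token {token!r}")
            return self.vocab_[token]
        if isinstance(token, numbers.Integral):
            idx = int(token)
            if not 0 <= idx < self.n_:
                raise KeyError(f"index {idx} out of range for vocabulary of size {self.n_}")
            return idx
        raise TypeError(f"token must be str or int, got {type(token).__name__}")

    def entity_vector(self, token: str | int) -> np.ndarray:
        """The token's row of the input matrix ``W_in_``."""
        return self.W_in_[self._index(token)].copy()

    def transform(self, X: Iterable[str | int]) -> np.ndarray:
        """Stack entity vectors for a sequence of tokens, (len(X), size)."""
        idx = [self._index(tok) for tok in X]
        return self.W_in_[idx].copy()

    def vectors(self) -> dict[str, np.ndarray]:
        """All token vectors keyed by token string."""
        if not self.vocab_:
            raise ValueError("model was fitted without a vocabulary")
        return {tok: self.W_in_[i].copy() for tok, i in self.vocab_.items()}

    def predict_proba_context(self, context: Sequence[str | int]) -> np.ndarray:
        """Softmax output distribution for a two-token context."""
        c = [self._index(t) for t in context]
        return forward_probabilities(self.W_in_, self.W_out_, c, self.combiner)


# -- word2vec text format --------------------------------------------------


def save_vectors(model: TripleCBOW, path: str | Path) -> None:
    """Write entity vectors in word2vec text format (header ``n size``)."""
    if not getattr(model, "vocab_", None):
        raise ValueError("model has no token vocabulary to export")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{model.n_} {model.size}\n")
        inv = sorted(model.vocab_.items(), key=lambda kv: kv[1])
        for tok, i in inv:
            coords = " ".join(repr(float(x)) for x in model.W_in_[i])
            fh.write(f"{tok} {coords}\n")


def load_vectors(path: str | Path) -> dict[str, np.ndarray]:
    """Read a word2vec text file into ``token -> vector``."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        n, size = (int(x) for x in header)
        out: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split(" ")
            if len(fields) != size + 1:
                raise ValueError(f"{path}:{lineno}: expected {size + 1} fields, got {len(fields)}")
            out[fields[0]] = np.array([float(x) for x in fields[1:]])
    if len(out) != n:
        raise ValueError(f"{path}: header promises {n} rows, found {len(out)}")
    return out
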