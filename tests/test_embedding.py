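import math

import numpy as np
import pytest

from kgadr.embedding import (
    TripleCBOW,
    build_corpus,
    corpus_loss_gradients,
    expand_corpus,
    expand_samples,
    forward_probabilities,
    load_vectors,
    sample_loss,
    save_vectors,
)
from kgadr.kg import KnowledgeGraph


def brute_force_probabilities(W1, W2, c1, c2, combiner="sum"):
    """Independent elementwise evaluation of the softmax chain."""
    n, size = W1.shape
    hidden = [W1[c1][k] + W1[c2][k] for k in range(size)]
    if combiner == "mean":
        hidden = [h / 2 for h in hidden]
    logits = [sum(hidden[k] * W2[k][j] for k in range(size)) for j in range(n)]
    exps = [math.exp(v) for v in logits]
    z = sum(exps)
    return np.array([e / z for e in exps])


@pytest.fixture
def hand_model():
    """4-token, size-2 model with small integer-valued weights."""
    W1 = np.array([[0.1, -0.2], [0.3, 0.0], [-0.1, 0.2], [0.0, 0.4]])
    W2 = np.array([[0.5, -0.3, 0.2, 0.0], [-0.1, 0.4, 0.0, 0.3]])
    return W1, W2


class TestCorpus:
    def test_one_sentence_per_triple_in_order(self, tiny_kg):
        corpus = build_corpus(tiny_kg)
        assert corpus.shape == (3, 3)
        vocab = tiny_kg.vocabulary
        assert corpus[0].tolist() == [vocab["D1"], vocab["has_side_effect"], vocab["S1"]]

    def test_expand_samples_enumerates_each_target_once(self):
        samples = expand_samples((7, 1, 9))
        assert samples == [((1, 9), 7), ((7, 9), 1), ((7, 1), 9)]
        assert len({target for _, target in samples}) == 3

    def test_expand_corpus_matches_per_sentence_expansion(self):
        corpus = np.array([[3, 1, 4], [3, 1, 4], [5, 2, 6]])
        contexts, targets = expand_corpus(corpus)
        assert len(targets) == 9  # duplicates kept
        flat = [
            (tuple(ctx), tgt)
            for sentence in corpus
            for ctx, tgt in expand_samples(sentence)
        ]
        assert [(tuple(c), t) for c, t in zip(contexts, targets)] == flat

    def test_sentence_must_have_three_tokens(self):
        with pytest.raises(ValueError):
            expand_samples((1, 2))


class TestForward:
    def test_zero_model_is_uniform(self):
        W1 = np.zeros((5, 3))
        W2 = np.zeros((3, 5))
        p = forward_probabilities(W1, W2, (0, 4))
        np.testing.assert_allclose(p, 0.2)

    def test_identical_output_columns_tie(self, rng):
        W1 = rng.normal(size=(6, 4))
        W2 = rng.normal(size=(4, 6))
        W2[:, 3] = W2[:, 5]
        p = forward_probabilities(W1, W2, (1, 2))
        assert p[3] == pytest.approx(p[5], abs=1e-15)

    @pytest.mark.parametrize("combiner", ["sum", "mean"])
    def test_matches_brute_force_oracle(self, hand_model, combiner):
        W1, W2 = hand_model
        for c1 in range(4):
            for c2 in range(4):
                got = forward_probabilities(W1, W2, (c1, c2), combiner)
                want = brute_force_probabilities(W1, W2, c1, c2, combiner)
                np.testing.assert_allclose(got, want, atol=1e-10)

    def test_probabilities_sum_to_one_fuzzed(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 30))
            size = int(rng.integers(1, 8))
            W1 = rng.normal(scale=3.0, size=(n, size))
            W2 = rng.normal(scale=3.0, size=(size, n))
            ctx = rng.integers(0, n, size=2)
            p = forward_probabilities(W1, W2, ctx)
            assert abs(p.sum() - 1.0) < 1e-12
            assert (p > 0).all()

    def test_index_out_of_range(self, hand_model):
        with pytest.raises(IndexError):
            forward_probabilities(*hand_model, (0, 9))


class TestSampleLoss:
    @pytest.mark.parametrize("n,expected", [(5, math.log(5)), (2, math.log(2))])
    def test_uniform_model_loss_is_log_n(self, n, expected):
        W1 = np.zeros((n, 3))
        W2 = np.zeros((3, n))
        assert sample_loss(W1, W2, (0, n - 1), 0) == pytest.approx(expected, rel=1e-12)

    def test_matches_negative_log_of_oracle(self, hand_model):
        W1, W2 = hand_model
        want = -math.log(brute_force_probabilities(W1, W2, 1, 2)[3])
        assert sample_loss(W1, W2, (1, 2), 3) == pytest.approx(want, rel=1e-10)


class TestGradients:
    @pytest.mark.parametrize("combiner", ["sum", "mean"])
    def test_analytic_gradient_matches_finite_differences(self, rng, combiner):
        """Exact gradients of the summed cross-entropy vs central differences."""
        n, size = 4, 2
        W1 = rng.normal(scale=0.5, size=(n, size))
        W2 = rng.normal(scale=0.5, size=(size, n))
        contexts = np.array([[0, 1], [2, 3], [1, 1], [0, 3]])
        targets = np.array([2, 0, 3, 1])

        def loss(W1x, W2x):
            return sum(
                sample_loss(W1x, W2x, ctx, tgt, combiner)
                for ctx, tgt in zip(contexts, targets)
            )

        got_loss, dW1, dW2 = corpus_loss_gradients(W1, W2, contexts, targets, combiner)
        assert got_loss == pytest.approx(loss(W1, W2), rel=1e-10)

        eps = 1e-6
        for M, dM in ((W1, dW1), (W2, dW2)):
            for idx in np.ndindex(M.shape):
                orig = M[idx]
                M[idx] = orig + eps
                up = loss(W1, W2)
                M[idx] = orig - eps
                down = loss(W1, W2)
                M[idx] = orig
                fd = (up - down) / (2 * eps)
                assert dM[idx] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestTraining:
    def _toy_corpus(self):
        kg = KnowledgeGraph(
            [
                ("D1", "has_side_effect", "S1"),
                ("D1", "has_target", "T1"),
                ("D2", "has_side_effect", "S1"),
            ]
        )
        return kg

    def test_zero_iters_returns_seeded_init(self):
        kg = self._toy_corpus()
        a = TripleCBOW(size=4, iters=0, random_state=7).fit(kg)
        b = TripleCBOW(size=4, iters=0, random_state=7).fit(kg)
        np.testing.assert_array_equal(a.W_in_, b.W_in_)
        assert (a.W_out_ == 0).all()
        assert a.loss_history_ == []

    def test_single_repeated_sentence_reaches_high_probability(self):
        corpus = np.tile(np.array([[0, 1, 2]]), (4, 1))
        model = TripleCBOW(
            size=2, iters=400, lr_initial=0.5, lr_final=0.05, dtype="float64", random_state=0
        ).fit(corpus)
        for ctx, tgt in expand_samples((0, 1, 2)):
            p = forward_probabilities(model.W_in_, model.W_out_, ctx)[tgt]
            assert p > 0.9

    def test_training_reduces_mean_corpus_loss(self):
        kg = self._toy_corpus()
        model = TripleCBOW(size=2, iters=200, dtype="float64", random_state=3).fit(kg)
        contexts, targets = expand_corpus(build_corpus(kg))
        rng = np.random.default_rng(3)
        W1_init = rng.uniform(-0.25, 0.25, size=model.W_in_.shape)
        init_loss = np.mean(
            [sample_loss(W1_init, np.zeros_like(model.W_out_), c, t) for c, t in zip(contexts, targets)]
        )
        final_loss = np.mean(
            [sample_loss(model.W_in_, model.W_out_, c, t) for c, t in zip(contexts, targets)]
        )
        assert final_loss < init_loss

    def test_full_batch_constant_lr_loss_monotone(self):
        """Full-batch descent with a small constant step never increases loss."""
        corpus = np.array([[0, 1, 2], [0, 1, 3], [4, 1, 2]])
        model = TripleCBOW(
            size=3,
            iters=60,
            lr_initial=0.05,
            lr_final=0.05,
            batch_size=1000,  # covers the whole corpus: full-batch descent
            dtype="float64",
            random_state=0,
        ).fit(corpus)
        diffs = np.diff(model.loss_history_)
        assert (diffs <= 1e-12).all()

    def test_bit_identical_given_seed(self):
        kg = self._toy_corpus()
        a = TripleCBOW(size=4, iters=30, random_state=11).fit(kg)
        b = TripleCBOW(size=4, iters=30, random_state=11).fit(kg)
        np.testing.assert_array_equal(a.W_in_, b.W_in_)
        np.testing.assert_array_equal(a.W_out_, b.W_out_)

    def test_negative_sampling_mode_learns(self):
        corpus = np.tile(np.array([[0, 1, 2], [3, 1, 4]]), (8, 1))
        model = TripleCBOW(
            size=4, iters=200, mode="negative_sampling", negative=3, random_state=5
        ).fit(corpus)
        assert model.loss_history_[-1] < model.loss_history_[0]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            TripleCBOW(size=2, iters=1).fit(np.empty((0, 3), dtype=int))

    def test_entity_vector_lookup(self):
        kg = self._toy_corpus()
        model = TripleCBOW(size=4, iters=0, random_state=0).fit(kg)
        np.testing.assert_array_equal(
            model.entity_vector("D1"), model.W_in_[kg.vocabulary["D1"]]
        )
        assert model.entity_vector("D1").shape == (4,)
        with pytest.raises(KeyError):
            model.entity_vector("nope")

    def test_distinct_tokens_get_distinct_vectors_after_training(self):
        kg = self._toy_corpus()
        model = TripleCBOW(size=2, iters=50, random_state=2).fit(kg)
        assert not np.allclose(model.entity_vector("D1"), model.entity_vector("S1"))


class TestVectorIO:
    def test_round_trip_within_tolerance(self, tmp_path, tiny_kg):
        model = TripleCBOW(size=2, iters=5, random_state=0).fit(tiny_kg)
        path = tmp_path / "vec.txt"
        save_vectors(model, path)
        assert len(path.read_text().splitlines()) == model.n_ + 1
        loaded = load_vectors(path)
        assert set(loaded) == set(model.vocab_)
        for tok, vec in loaded.items():
            np.testing.assert_allclose(vec, model.entity_vector(tok), atol=1e-6)

    def test_refuses_model_without_vocabulary(self, tmp_path):
        model = TripleCBOW(size=2, iters=0, random_state=0).fit(np.array([[0, 1, 2]]))
        with pytest.raises(ValueError):
            save_vectors(model, tmp_path / "vec.txt")

    def test_malformed_rows_rejected(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("2 3\ntok1 0.0 1.0 2.0\ntok2 0.0 1.0\n")
        with pytest.raises(ValueError, match=":3:"):
            load_vectors(path)
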