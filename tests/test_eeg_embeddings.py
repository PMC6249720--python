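"""Huffman coding, hierarchical softmax, and CBOW embedding training."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctxseize.eeg_embeddings import (
    ContextConfig,
    EEGSentence,
    EmbeddingMatrix,
    Vocabulary,
    build_huffman,
    context_vector,
    corpus_log_likelihood,
    load_embeddings,
    p_word_given_ctx,
    save_embeddings,
    temporal_feature,
    train_embeddings,
)
from ctxseize.channel_sdae import EEGWord


def optimal_code_lengths(freqs: dict[int, int]) -> float:
    """Exhaustive oracle: minimum weighted code length over all prefix-free
    (full binary tree) codes; feasible for |V| <= 5."""
    words = tuple(sorted(freqs))

    def best(subset: tuple) -> dict:
        if len(subset) == 1:
            return {subset[0]: 0}
        best_cost, best_assign = None, None
        # all ways to split into two non-empty subtrees (unordered)
        for r in range(1, len(subset)):
            for left in itertools.combinations(subset, r):
                right = tuple(w for w in subset if w not in left)
                if left > right:
                    continue
                la = best(left)
                ra = best(right)
                assign = {w: l + 1 for w, l in {**la, **ra}.items()}
                cost = sum(freqs[w] * assign[w] for w in subset)
                if best_cost is None or cost < best_cost:
                    best_cost, best_assign = cost, assign
        return best_assign

    assign = best(words)
    return sum(freqs[w] * assign[w] for w in words)


class TestHuffman:
    def test_two_words_get_one_bit_codes(self):
        tree = build_huffman(Vocabulary({0: 3, 1: 5}), dim=4)
        assert tree.code_length(0) == tree.code_length(1) == 1
        assert tree.n_internal == 1

    def test_code_lengths_follow_frequency_order(self):
        tree = build_huffman(Vocabulary({0: 5, 1: 3, 2: 1, 3: 1}), dim=4)
        assert tree.code_length(0) <= tree.code_length(1)
        assert tree.code_length(1) <= tree.code_length(2)
        assert tree.code_length(2) == tree.code_length(3)

    def test_codes_form_a_prefix_free_set(self):
        tree = build_huffman(Vocabulary({i: i + 1 for i in range(6)}), dim=3)
        codes = ["".join(map(str, tree.codes[w])) for w in tree.codes]
        assert len(set(codes)) == len(codes)
        for a, b in itertools.permutations(codes, 2):
            assert not a.startswith(b)

    @pytest.mark.parametrize("freqs", [
        {0: 1, 1: 1},
        {0: 5, 1: 3, 2: 1},
        {0: 7, 1: 1, 2: 1, 3: 1},
        {0: 4, 1: 3, 2: 2, 3: 1, 4: 1},
        {0: 1, 1: 1, 2: 1, 3: 1, 4: 1},
        {0: 10, 1: 6, 2: 2, 3: 1, 4: 1},
    ])
    def test_optimality_against_exhaustive_prefix_codes(self, freqs):
        """Huffman's weighted code length equals the exhaustive minimum."""
        tree = build_huffman(Vocabulary(freqs), dim=2)
        huff = sum(freqs[w] * tree.code_length(w) for w in freqs)
        assert huff == optimal_code_lengths(freqs)
        # some maximal-frequency word attains the minimal code length
        max_freq = max(freqs.values())
        min_len = min(tree.code_length(w) for w in freqs)
        assert any(freqs[w] == max_freq and tree.code_length(w) == min_len
                   for w in freqs)

    def test_expected_path_length_is_logarithmic(self):
        """Balanced frequencies give paths within ceil(log2 |V|) + 1."""
        for n in (4, 7, 13, 16):
            tree = build_huffman(Vocabulary({i: 1 for i in range(n)}), dim=2)
            mean_len = np.mean([tree.code_length(w) for w in range(n)])
            assert mean_len <= np.ceil(np.log2(n)) + 1

    def test_single_word_degenerate_tree(self):
        tree = build_huffman(Vocabulary({4: 10}), dim=3)
        assert tree.codes[4] == []
        assert p_word_given_ctx(tree, np.zeros(3), 4) == 1.0

    def test_internal_node_count(self):
        tree = build_huffman(Vocabulary({i: 1 for i in range(9)}), dim=2)
        assert tree.n_internal == 8


class TestHierarchicalSoftmax:
    def test_zero_parameters_give_power_of_two_probabilities(self):
        tree = build_huffman(Vocabulary({0: 4, 1: 2, 2: 1, 3: 1}), dim=3)
        ctx = np.ones(3)
        for w in range(4):
            assert p_word_given_ctx(tree, ctx, w) == pytest.approx(
                2.0 ** -tree.code_length(w))

    def test_two_word_probabilities_sum_exactly_to_one(self, rng):
        tree = build_huffman(Vocabulary({0: 1, 1: 1}), dim=4)
        tree.theta[:] = rng.normal(size=tree.theta.shape)
        ctx = rng.normal(size=4)
        total = p_word_given_ctx(tree, ctx, 0) + p_word_given_ctx(tree, ctx, 1)
        assert total == pytest.approx(1.0, abs=1e-15)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(vocab_size=st.integers(2, 16), seed=st.integers(0, 10_000))
    def test_distribution_normalizes_for_random_parameters(self, vocab_size, seed):
        """Sum over the vocabulary of p(w | ctx) is 1: Huffman-path sigmoids
        define a proper distribution."""
        rng = np.random.default_rng(seed)
        freqs = {w: int(rng.integers(1, 20)) for w in range(vocab_size)}
        tree = build_huffman(Vocabulary(freqs), dim=5)
        tree.theta[:] = rng.normal(scale=2.0, size=tree.theta.shape)
        ctx = rng.normal(size=5)
        total = sum(p_word_given_ctx(tree, ctx, w) for w in range(vocab_size))
        assert abs(total - 1.0) <= 1e-10


class TestContextVector:
    def test_identical_context_words_average_to_their_vector(self):
        emb = EmbeddingMatrix(np.arange(12, dtype=float).reshape(4, 3))
        s = EEGSentence([2, 2, 0, 2, 2])
        np.testing.assert_array_equal(
            context_vector(emb, s, 2, ContextConfig(window=2)),
            emb.vectors[2])

    def test_window_one_average(self):
        emb = EmbeddingMatrix(np.array([[1.0, 0.0], [0.0, 1.0], [5.0, 5.0]]))
        s = EEGSentence([0, 2, 1])
        np.testing.assert_array_equal(
            context_vector(emb, s, 1, ContextConfig(window=1)),
            [0.5, 0.5])

    def test_concat_mode_length(self, rng):
        emb = EmbeddingMatrix(rng.normal(size=(6, 4)))
        s = EEGSentence([0, 1, 2, 3, 4, 5])
        cfg = ContextConfig(window=2, integration="concat")
        assert context_vector(emb, s, 2, cfg).shape == (16,)

    def test_boundary_positions_are_skipped(self):
        emb = EmbeddingMatrix(np.ones((3, 2)))
        s = EEGSentence([0, 1, 2])
        cfg = ContextConfig(window=2)
        assert context_vector(emb, s, 0, cfg) is None
        assert context_vector(emb, s, 2, cfg) is None


class TestTraining:
    def _structured_corpus(self, rng, n_sent=20, length=30):
        """Markov-ish corpus: words 0/1 follow each other, as do 4/5."""
        sents = []
        for _ in range(n_sent):
            words, state = [], int(rng.integers(0, 2))
            for _ in range(length):
                if rng.random() < 0.1:
                    state = 1 - state
                base = 0 if state == 0 else 4
                words.append(base + int(rng.integers(0, 2)))
            sents.append(EEGSentence(words))
        return sents

    def test_objective_improves_with_training(self, rng):
        """Average log-likelihood after SGD exceeds its value at init,
        across seeds."""
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            sents = self._structured_corpus(r)
            cfg = ContextConfig(window=2, epochs=5, learning_rate=0.1,
                                seed=seed)
            vocab = Vocabulary.from_sentences(sents)
            tree0 = build_huffman(vocab, dim=8)
            init_rng = np.random.default_rng(seed)
            emb0 = EmbeddingMatrix(
                init_rng.uniform(-0.5 / 8, 0.5 / 8, size=(6, 8)))
            ll0 = corpus_log_likelihood(sents, emb0, tree0, cfg)
            emb, tree = train_embeddings(sents, cfg, q=8)
            ll1 = corpus_log_likelihood(sents, emb, tree, cfg)
            wins += ll1 > ll0
        assert wins >= 9

    def test_update_sparsity_contract(self):
        """One training example touches only the 2k context vectors and the
        path's theta nodes; everything else stays bitwise unchanged."""
        sent = EEGSentence([0, 1, 2, 3, 4])  # exactly one interior position
        # two epochs: theta starts at zero, so the context-vector gradient is
        # zero until the path parameters have moved once
        cfg = ContextConfig(window=2, epochs=2, learning_rate=0.1, seed=0)
        # reference: initial vectors are reproducible from the seed
        q, n_words = 6, 10
        rng = np.random.default_rng(cfg.seed)
        init = rng.uniform(-0.5 / q, 0.5 / q, size=(n_words, q))
        emb, tree = train_embeddings([sent], cfg, q=q, n_words=n_words)
        context_ids = {0, 1, 3, 4}
        for w in range(n_words):
            changed = not np.array_equal(emb.vectors[w], init[w])
            assert changed == (w in context_ids)
        path_nodes = set(tree.paths[2])
        for node in range(tree.n_internal):
            touched = not np.array_equal(tree.theta[node], np.zeros(q))
            assert touched == (node in path_nodes)

    def test_words_with_identical_contexts_embed_nearby(self, rng):
        """Words used interchangeably in the same contexts end up with
        higher cosine similarity than random word pairs."""
        sents = self._structured_corpus(rng, n_sent=40, length=40)
        cfg = ContextConfig(window=2, epochs=10, learning_rate=0.1, seed=3)
        emb, _ = train_embeddings(sents, cfg, q=10)

        def cos(a, b):
            return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

        sim_pair = cos(emb.vectors[0], emb.vectors[1])
        random_sims = []
        r = np.random.default_rng(0)
        for _ in range(200):
            a, b = r.normal(size=10), r.normal(size=10)
            random_sims.append(cos(a, b))
        assert sim_pair > np.percentile(random_sims, 95)

    def test_same_seed_reproducible(self, rng):
        sents = self._structured_corpus(rng)
        cfg = ContextConfig(epochs=2, seed=5)
        a, _ = train_embeddings(sents, cfg, q=6)
        b, _ = train_embeddings(sents, cfg, q=6)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_all_sentences_too_short_rejected(self):
        with pytest.raises(ValueError, match="interior"):
            train_embeddings([EEGSentence([0, 1])],
                             ContextConfig(window=2), q=4)


class TestTemporalFeature:
    def test_single_channel_word_maps_to_its_vector(self, rng):
        emb = EmbeddingMatrix(rng.normal(size=(8, 5)))
        feat = temporal_feature(emb, EEGWord(word_id=3, channel_id=0))
        np.testing.assert_array_equal(feat, emb.vectors[3])

    def test_channels_with_equal_words_match_single_channel(self, rng):
        emb = EmbeddingMatrix(rng.normal(size=(8, 5)))
        w = EEGWord(word_id=2, channel_id=0)
        np.testing.assert_allclose(temporal_feature(emb, [w, w]),
                                   temporal_feature(emb, w))

    def test_multi_channel_offsets_into_global_id_space(self, rng):
        emb = EmbeddingMatrix(rng.normal(size=(8, 5)))
        words = [EEGWord(word_id=1, channel_id=0),
                 EEGWord(word_id=2, channel_id=1)]
        feat = temporal_feature(emb, words, dictionary_size=4)
        expected = (emb.vectors[1] + emb.vectors[4 + 2]) / 2
        np.testing.assert_allclose(feat, expected)
        assert feat.shape == (5,)

    def test_out_of_matrix_word_rejected(self, rng):
        emb = EmbeddingMatrix(rng.normal(size=(4, 5)))
        with pytest.raises(KeyError):
            temporal_feature(emb, EEGWord(word_id=9, channel_id=0))


def test_embedding_persistence_roundtrip(tmp_path, rng):
    emb = EmbeddingMatrix(rng.normal(size=(12, 6)))
    path = tmp_path / "emb.txt"
    save_embeddings(emb, path, dictionary_size=4)
    header = path.read_text().splitlines()[0]
    assert header == "12 6"
    back = load_embeddings(path)
    np.testing.assert_allclose(back.vectors, emb.vectors, rtol=1e-6)
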