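"""Temporal features via CBOW embeddings of EEG words.

Each record's fragments, translated through the SDAE dictionary, form an
"EEG sentence" of word ids per channel.  Words are embedded in R^q
(default q = 20) by a continuous-bag-of-words objective: predict the word
at position t from the average of its 2k context-word vectors (default
k = 2).  The average log probability

    L = (1/T) sum_t log p(w_t | ctx(w_t))

is maximized by SGD, with p factored along a binary Huffman-tree path as a
product of sigmoid branch decisions (hierarchical softmax), so each update
touches only the 2k context vectors and the O(log |V|) path parameters.
The most frequent word gets the shortest path.

Word ids are global across channels: channel c's dictionary word u gets id
``c * dictionary_size + u``, so a single embedding space covers all
channels while preserving channel identity.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .channel_sdae import EEGWord, sigmoid

DEFAULT_DIM = 20


@dataclass
class EEGSentence:
    """Ordered word ids of one record (one channel's view of it)."""

    words: list[int]
    record_id: str = ""
    channel_id: int = 0

    def __post_init__(self) -> None:
        if len(self.words) < 1:
            raise ValueError("a sentence needs at least one word")

    def __len__(self) -> int:
        return len(self.words)


@dataclass
class Vocabulary:
    counts: dict[int, int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("word frequencies must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_sentences(cls, sentences: Iterable[EEGSentence]) -> "Vocabulary":
        counts: dict[int, int] = {}
        for s in sentences:
            for w in s.words:
                counts[w] = counts.get(w, 0) + 1
        if not counts:
            raise ValueError("no words in any sentence")
        return cls(counts)


@dataclass
class HuffmanTree:
    """Prefix codes and per-internal-node hierarchical-softmax parameters.

    ``paths[w]`` lists the internal-node indices from the root towards word
    w (excluding the leaf); ``codes[w]`` the branch bit taken *at* each of
    those nodes (0 = the branch whose sigmoid probability is f, 1 = 1 - f).
    ``theta`` holds one parameter vector per internal node; |V| - 1 rows.
    """

    paths: dict[int, list[int]]
    codes: dict[int, list[int]]
    theta: np.ndarray  # (n_internal, q), zero-initialized

    @property
    def n_internal(self) -> int:
        return self.theta.shape[0]

    def code_length(self, w: int) -> int:
        return len(self.codes[w])


@dataclass
class EmbeddingMatrix:
    """One q-dimensional vector per word id; rows index the global id space."""

    vectors: np.ndarray  # (n_words, q)

    @property
    def q(self) -> int:
        return self.vectors.shape[1]

    def __getitem__(self, word_id: int) -> np.ndarray:
        return self.vectors[word_id]


@dataclass
class ContextConfig:
    window: int = 2           # k context words on each side
    integration: str = "average"
    epochs: int = 5
    learning_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("context window must be >= 1")
        if self.integration not in ("average", "concat"):
            raise ValueError(f"unknown integration {self.integration!r}")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs and learning_rate must be positive")


def build_huffman(vocab: Vocabulary, dim: int = DEFAULT_DIM) -> HuffmanTree:
    """Classical Huffman construction over word frequencies.

    Deterministic: priority is (frequency, creation order), leaves ordered
    by word id, and at each merge the first-popped (lighter) node takes
    branch bit 0.  A single-word vocabulary gets an empty code.
    """
    words = sorted(vocab.counts)
    if len(words) == 1:
        return HuffmanTree(
            paths={words[0]: []}, codes={words[0]: []},
            theta=np.zeros((0, dim)),
        )
    # heap entries: (freq, tie_counter, node); leaf nodes are ('leaf', word),
    # internal are ('node', index, left, right)
    heap: list = []
    counter = 0
    for w in words:
        heap.append((vocab.counts[w], counter, ("leaf", w)))
        counter += 1
    heapq.heapify(heap)
    internal = []
    while len(heap) > 1:
        f1, _, n1 = heapq.heappop(heap)
        f2, _, n2 = heapq.heappop(heap)
        node = ("node", len(internal), n1, n2)
        internal.append(node)
        heapq.heappush(heap, (f1 + f2, counter, node))
        counter += 1
    root = heap[0][2]
    paths: dict[int, list[int]] = {}
    codes: dict[int, list[int]] = {}
    stack = [(root, [], [])]
    while stack:
        node, path, code = stack.pop()
        if node[0] == "leaf":
            paths[node[1]] = path
            codes[node[1]] = code
        else:
            idx = node[1]
            stack.append((node[2], path + [idx], code + [0]))
            stack.append((node[3], path + [idx], code + [1]))
    return HuffmanTree(paths=paths, codes=codes,
                       theta=np.zeros((len(internal), dim)))


def context_vector(
    emb: EmbeddingMatrix,
    sentence: EEGSentence,
    t: int,
    cfg: ContextConfig | None = None,
) -> np.ndarray | None:
    """Integrate the 2k context-word vectors around position t (0-based).

    Positions whose full context window does not fit inside the sentence
    are skipped (returns None), matching the interior summation range of
    the training objective.
    """
    cfg = cfg or ContextConfig()
    k = cfg.window
    T = len(sentence)
    if t - k < 0 or t + k > T - 1:
        return None
    ids = sentence.words[t - k : t] + sentence.words[t + 1 : t + k + 1]
    vecs = emb.vectors[ids]
    if cfg.integration == "average":
        return vecs.mean(axis=0)
    return vecs.ravel()


def p_word_given_ctx(tree: HuffmanTree, ctx: np.ndarray, w: int) -> float:
    """Hierarchical-softmax probability of word w given the context vector.

    Product along w's Huffman path of f(theta . ctx) for branch bit 0 and
    1 - f(theta . ctx) for bit 1, f the sigmoid.
    """
    if w not in tree.paths:
        raise KeyError(f"word {w} not in the vocabulary this tree was built on")
    p = 1.0
    for node, d in zip(tree.paths[w], tree.codes[w]):
        f = float(sigmoid(np.array(tree.theta[node] @ ctx)))
        p *= f if d == 0 else 1.0 - f
    return p


def _interior_positions(sentence: EEGSentence, k: int) -> range:
    return range(k, len(sentence) - k)


def corpus_log_likelihood(
    sentences: Sequence[EEGSentence],
    emb: EmbeddingMatrix,
    tree: HuffmanTree,
    cfg: ContextConfig,
) -> float:
    """Mean log p(w_t | ctx) over every interior position of every sentence."""
    total, count = 0.0, 0
    for s in sentences:
        for t in _interior_positions(s, cfg.window):
            ctx = context_vector(emb, s, t, cfg)
            p = p_word_given_ctx(tree, ctx, s.words[t])
            total += np.log(max(p, 1e-300))
            count += 1
    if count == 0:
        raise ValueError("no interior positions: all sentences shorter than 2k+1")
    return total / count


def train_embeddings(
    sentences: Sequence[EEGSentence],
    cfg: ContextConfig | None = None,
    q: int = DEFAULT_DIM,
    n_words: int | None = None,
) -> tuple[EmbeddingMatrix, HuffmanTree]:
    """SGD ascent on the CBOW objective with hierarchical softmax.

    Per training position only the 2k context-word vectors and the theta of
    the O(log |V|) path nodes are touched.  ``n_words`` sizes the embedding
    matrix (default: max word id + 1) so every dictionary word has a vector
    even if unseen in training.  Vectors start uniform in [-0.5/q, 0.5/q];
    theta starts at zero.  Fully seeded and reproducible.
    """
    cfg = cfg or ContextConfig()
    if cfg.integration != "average":
        raise NotImplementedError("training supports the average integration only")
    vocab = Vocabulary.from_sentences(sentences)
    k = cfg.window
    if all(len(s) <= 2 * k for s in sentences):
        raise ValueError(
            f"no sentence has an interior position for window k={k}; "
            "records are too short"
        )
    if n_words is None:
        n_words = max(vocab.counts) + 1
    tree = build_huffman(vocab, dim=q)
    rng = np.random.default_rng(cfg.seed)
    vectors = rng.uniform(-0.5 / q, 0.5 / q, size=(n_words, q))
    lr = cfg.learning_rate
    for _ in range(cfg.epochs):
        for s in sentences:
            words = s.words
            for t in _interior_positions(s, k):
                ids = words[t - k : t] + words[t + 1 : t + k + 1]
                ctx = vectors[ids].mean(axis=0)
                grad_ctx = np.zeros(len(ctx))
                for node, d in zip(tree.paths[words[t]], tree.codes[words[t]]):
                    theta = tree.theta[node]
                    f = sigmoid(np.array(theta @ ctx))
                    g = lr * (1.0 - d - f)  # d log p / d z for z = theta.ctx
                    grad_ctx += g * theta
                    tree.theta[node] = theta + g * ctx
                vectors[ids] += grad_ctx / (2 * k)
    return EmbeddingMatrix(vectors), tree


def temporal_feature(
    emb: EmbeddingMatrix,
    words: Sequence[EEGWord] | EEGWord,
    dictionary_size: int | None = None,
) -> np.ndarray:
    """Temporal feature of one fragment from its per-channel EEG words.

    A single word maps to its embedding vector; multiple channels average
    their word vectors (length stays q).  When ``dictionary_size`` is
    given, per-channel local word ids are offset to the global id space
    ``channel_id * dictionary_size + word_id``; otherwise word ids are used
    as-is.
    """
    if isinstance(words, EEGWord):
        words = [words]
    if not words:
        raise ValueError("need at least one word")
    rows = []
    for w in words:
        gid = w.word_id if dictionary_size is None else (
            w.channel_id * dictionary_size + w.word_id
        )
        if not 0 <= gid < emb.vectors.shape[0]:
            raise KeyError(f"word id {gid} outside the embedding matrix")
        rows.append(emb.vectors[gid])
    return np.mean(rows, axis=0)


# ---------------------------------------------------------------------------
# Persistence: word2vec-style text format
# ---------------------------------------------------------------------------

def save_embeddings(
    emb: EmbeddingMatrix, path: str | Path, dictionary_size: int | None = None
) -> None:
    """One line per word: global_id channel_id local_id followed by q floats."""
    n, q = emb.vectors.shape
    d = dictionary_size or n
    with open(path, "w") as fh:
        fh.write(f"{n} {q}\n")
        for gid in range(n):
            ch, local = divmod(gid, d)
            vals = " ".join(f"{v:.8g}" for v in emb.vectors[gid])
            fh.write(f"{gid} {ch} {local} {vals}\n")


def load_embeddings(path: str | Path) -> EmbeddingMatrix:
    with open(path) as fh:
        n, q = map(int, fh.readline().split())
        vectors = np.zeros((n, q))
        for line in fh:
            parts = line.split()
            vectors[int(parts[0])] = [float(v) for v in parts[3 : 3 + q]]
    return EmbeddingMatrix(vectors)
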