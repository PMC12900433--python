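"""Skip-gram with negative sampling (SGNS), trained by minibatch SGD.

This is the word2vec objective: for each (center, context) pair inside a
sliding window, maximize log sigma(u_c . v_w) and minimize it for a handful
of noise words drawn from the unigram^0.75 distribution. Both the drug
substructure-sentence embedder and the DeepWalk node embedder train
through this module, so determinism and vocabulary policy live in one
place. Training is single-threaded and fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


@dataclass
class SkipGramModel:
    """Token -> vector mapping learned from sentences."""

    vectors: dict[str, np.ndarray]
    dimension: int
    window: int
    seed: int
    vocab: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.vocab:
            self.vocab = list(self.vectors)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]


def _pairs_from_sentences(
    sentences: list[list[int]], window: int, rng: np.random.Generator
) -> np.ndarray:
    """(center, context) index pairs with word2vec-style window shrinking.

    Each center position draws an effective window b ~ Uniform{1..window};
    this downweights distant contexts exactly as the reference
    implementation does.
    """
    centers, contexts = [], []
    for sent in sentences:
        n = len(sent)
        if n < 2:
            continue
        spans = rng.integers(1, window + 1, size=n)
        for t in range(n):
            b = spans[t]
            lo, hi = max(0, t - b), min(n, t + b + 1)
            for j in range(lo, hi):
                if j != t:
                    centers.append(sent[t])
                    contexts.append(sent[j])
    if not centers:
        return np.empty((0, 2), dtype=np.int64)
    return np.column_stack([np.array(centers), np.array(contexts)])


def train_skipgram(
    sentences: list[list[str]],
    dimension: int = 100,
    window: int = 5,
    epochs: int = 5,
    learning_rate: float = 0.025,
    negative: int = 5,
    min_count: int = 1,
    seed: int = 0,
) -> SkipGramModel:
    """Train SGNS embeddings on tokenized sentences.

    Tokens occurring fewer than ``min_count`` times are dropped from the
    vocabulary (and from sentences) before pair extraction. Raises on an
    empty corpus or empty post-filter vocabulary.
    """
    if not sentences or all(not s for s in sentences):
        raise ValueError("empty corpus")
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(tok for tok, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError(f"no token reaches min_count={min_count}")
    index = {tok: i for i, tok in enumerate(vocab)}
    encoded = [
        [index[t] for t in sent if t in index] for sent in sentences
    ]

    rng = np.random.default_rng(seed)
    n_vocab = len(vocab)
    # noise distribution: unigram frequency ** 0.75
    freq = np.array([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    noise = freq / freq.sum()

    w_in = (rng.random((n_vocab, dimension)) - 0.5) / dimension
    w_out = np.zeros((n_vocab, dimension))

    for epoch in range(epochs):
        pairs = _pairs_from_sentences(encoded, window, rng)
        if len(pairs) == 0:
            break
        rng.shuffle(pairs, axis=0)
        lr = learning_rate * (1.0 - epoch / max(epochs, 1))
        lr = max(lr, learning_rate * 0.1)
        for start in range(0, len(pairs), 64):
            chunk = pairs[start : start + 64]
            c_idx, o_idx = chunk[:, 0], chunk[:, 1]
            neg_idx = rng.choice(n_vocab, size=(len(chunk), negative), p=noise)
            v = w_in[c_idx]  # (m, d)
            u_pos = w_out[o_idx]  # (m, d)
            u_neg = w_out[neg_idx]  # (m, neg, d)

            s_pos = expit(np.einsum("md,md->m", v, u_pos))
            s_neg = expit(np.einsum("md,mnd->mn", v, u_neg))

            g_pos = (s_pos - 1.0)[:, None]  # d L / d (v.u_pos)
            g_neg = s_neg[:, :, None]

            # summed gradients over a small chunk approximate per-pair
            # SGD; repeated indices within a chunk are normalized by
            # their multiplicity's square root to stay stable on tiny
            # vocabularies without starving large ones
            grad_v = g_pos * u_pos + np.einsum("mnd,mn->md", u_neg, s_neg)
            cnt_in = np.bincount(c_idx, minlength=n_vocab)
            scale_in = 1.0 / np.sqrt(np.maximum(cnt_in, 1))
            np.add.at(w_in, c_idx, -lr * scale_in[c_idx, None] * grad_v)

            cnt_out = np.bincount(o_idx, minlength=n_vocab) + np.bincount(
                neg_idx.ravel(), minlength=n_vocab
            )
            scale_out = 1.0 / np.sqrt(np.maximum(cnt_out, 1))
            np.add.at(w_out, o_idx, -lr * scale_out[o_idx, None] * (g_pos * v))
            np.add.at(
                w_out,
                neg_idx.ravel(),
                -lr
                * scale_out[neg_idx.ravel(), None]
                * (g_neg * v[:, None, :]).reshape(-1, dimension),
            )

    vectors = {tok: w_in[i].copy() for tok, i in index.items()}
    return SkipGramModel(vectors, dimension, window, seed, vocab)
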