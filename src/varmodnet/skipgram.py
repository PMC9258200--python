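"""Skip-gram with negative sampling (SGNS) over integer token sequences.

A compact word2vec-style trainer for the walk corpora produced by the
embedding module. Vocabularies here are tiny (a gene's variants), so the
implementation favours determinism and vectorised numpy over throughput
tricks:

- every token is kept (no min-count pruning, no frequent-word subsampling);
- a fixed symmetric context window (no random window shrinking);
- negatives drawn from the unigram distribution raised to 3/4;
- mini-batched SGD with a linearly decaying learning rate; duplicate index
  updates within a batch are accumulated exactly (``np.add.at``). The batch
  must stay small relative to the vocabulary: each node accumulates roughly
  batch/vocab pair-gradients per step, so large batches inflate the
  effective per-node step and collapse the embedding.

Given the same corpus and seed the result is bitwise reproducible on a
single thread.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _training_pairs(walks: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) token pairs for all in-bounds offsets up to `window`."""
    n_walks, length = walks.shape
    centers = []
    contexts = []
    for t in range(length):
        lo, hi = max(0, t - window), min(length, t + window + 1)
        for u in range(lo, hi):
            if u == t:
                continue
            centers.append(walks[:, t])
            contexts.append(walks[:, u])
    return np.concatenate(centers), np.concatenate(contexts)


def train_sgns(
    walks: np.ndarray,
    n_nodes: int,
    dim: int = 8,
    window: int = 5,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    alpha_min: float = 1e-4,
    batch: int = 128,
    seed: int = 0,
) -> np.ndarray:
    """Train SGNS embeddings; returns the (n_nodes, dim) input-vector matrix.

    `walks` is an integer array of shape (n_walks, walk_length) with token
    ids in [0, n_nodes).
    """
    rng = np.random.default_rng(seed)
    w_in = (rng.random((n_nodes, dim)) - 0.5) / dim
    w_out = np.zeros((n_nodes, dim))

    counts = np.bincount(walks.ravel(), minlength=n_nodes).astype(float)
    noise = counts**0.75
    noise /= noise.sum()

    centers, contexts = _training_pairs(walks, window)
    n_pairs = centers.size
    total = max(1, epochs * n_pairs)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch):
            idx = order[s : s + batch]
            c = centers[idx]
            o = contexts[idx]
            neg = rng.choice(n_nodes, size=(idx.size, negative), p=noise)
            lr = max(alpha_min, alpha * (1.0 - step / total))
            step += idx.size

            v = w_in[c]  # (B, d)
            u_pos = w_out[o]  # (B, d)
            u_neg = w_out[neg]  # (B, K, d)

            g_pos = _sigmoid(np.einsum("bd,bd->b", v, u_pos)) - 1.0
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", v, u_neg))
            # a sampled negative that happens to be the true context is skipped
            g_neg[neg == o[:, None]] = 0.0

            grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            np.add.at(w_in, c, -lr * grad_v)
            np.add.at(w_out, o, -lr * (g_pos[:, None] * v))
            np.add.at(
                w_out,
                neg.ravel(),
                (-lr * (g_neg[..., None] * v[:, None, :])).reshape(-1, dim),
            )
    return w_in
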