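"""Concept-graph embeddings: uniform random walks + skip-gram negative sampling.

This is the p = q = 1 special case of node2vec: walks are first-order uniform
random walks on the concept graph, and vectors are trained with skip-gram and
negative sampling (SGNS) in plain numpy. The trainer is deliberately
small-vocabulary scale — a few thousand concept codes at most — which is what
the synthetic ontology produces. Training is single-threaded and fully
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.special import expit


@dataclass
class EmbeddingTable:
    """Code -> fixed-dimension real vector, stored as a dense matrix."""

    codes: list[str]
    vectors: np.ndarray  # (n_codes, dim)

    def __post_init__(self) -> None:
        self.index = {c: i for i, c in enumerate(self.codes)}
        if self.vectors.shape[0] != len(self.codes):
            raise ValueError("vector matrix and code list disagree in length")

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __contains__(self, code: str) -> bool:
        return code in self.index

    def __getitem__(self, code: str) -> np.ndarray:
        return self.vectors[self.index[code]]

    def save(self, path) -> None:
        """Headerless text format: ``code v1 ... vd`` per line."""
        with open(path, "w") as fh:
            for code, vec in zip(self.codes, self.vectors):
                fh.write(code + " " + " ".join(f"{x:.6g}" for x in vec) + "\n")

    @classmethod
    def load(cls, path) -> "EmbeddingTable":
        """Read the headerless format; a word2vec-style count header is skipped."""
        codes: list[str] = []
        rows: list[np.ndarray] = []
        with open(path) as fh:
            first = fh.readline().split()
            if len(first) == 2 and all(t.isdigit() for t in first):
                pass  # word2vec text header "n_vectors dim"
            else:
                codes.append(first[0])
                rows.append(np.array(first[1:], dtype=float))
            for line in fh:
                parts = line.split()
                codes.append(parts[0])
                rows.append(np.array(parts[1:], dtype=float))
        return cls(codes=codes, vectors=np.vstack(rows))


def _adjacency_arrays(graph: nx.Graph, codes: list[str]):
    index = {c: i for i, c in enumerate(codes)}
    neighbors = [sorted(index[nb] for nb in graph.neighbors(c)) for c in codes]
    degrees = np.array([len(nb) for nb in neighbors])
    flat = np.concatenate([np.array(nb, dtype=np.int64) for nb in neighbors])
    offsets = np.concatenate([[0], np.cumsum(degrees)])
    return flat, offsets, degrees


def simulate_walks(
    graph: nx.Graph, n_walks: int, walk_len: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random walks, ``n_walks`` starts per node; (walks, walk_len) ints."""
    codes = sorted(graph.nodes())
    flat, offsets, degrees = _adjacency_arrays(graph, codes)
    starts = np.tile(np.arange(len(codes)), n_walks)
    walks = np.empty((len(starts), walk_len), dtype=np.int64)
    walks[:, 0] = starts
    cur = starts
    for step in range(1, walk_len):
        u = rng.random(len(cur))
        pick = offsets[cur] + np.floor(u * degrees[cur]).astype(np.int64)
        cur = flat[pick]
        walks[:, step] = cur
    return walks


def _skipgram_pairs(walks: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    L = walks.shape[1]
    for d in range(1, window + 1):
        if d >= L:
            break
        a = walks[:, :-d].ravel()
        b = walks[:, d:].ravel()
        centers.append(a)
        contexts.append(b)
        centers.append(b)
        contexts.append(a)
    return np.concatenate(centers), np.concatenate(contexts)


def train_embeddings(
    graph: nx.Graph,
    dim: int = 128,
    walk_len: int = 40,
    n_walks: int = 10,
    window: int = 5,
    seed: int = 0,
    n_negative: int = 5,
    lr: float = 0.025,
    min_lr: float = 1e-4,
    batch_size: int = 8192,
) -> EmbeddingTable:
    """Train one dim-length vector per concept code.

    Walk co-occurrence makes graph-adjacent codes get similar vectors, which
    is the property the patient-averaging representation relies on. The
    default dimension is 128, matching the size of the pretrained clinical
    concept embeddings this table stands in for.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if not nx.is_connected(graph):
        raise ValueError("graph must be connected: random walks cannot cover the vocabulary")

    rng = np.random.default_rng(seed)
    codes = sorted(graph.nodes())
    V = len(codes)

    walks = simulate_walks(graph, n_walks=n_walks, walk_len=walk_len, rng=rng)
    centers, contexts = _skipgram_pairs(walks, window)
    order = rng.permutation(len(centers))
    centers, contexts = centers[order], contexts[order]

    # unigram^0.75 negative-sampling distribution over walk tokens
    counts = np.bincount(walks.ravel(), minlength=V).astype(float)
    neg_probs = counts**0.75
    neg_probs /= neg_probs.sum()

    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    n_pairs = len(centers)
    n_batches = int(np.ceil(n_pairs / batch_size))
    for b in range(n_batches):
        sl = slice(b * batch_size, min((b + 1) * batch_size, n_pairs))
        c_idx = centers[sl]
        pos_idx = contexts[sl]
        m = len(c_idx)
        eta = max(min_lr, lr * (1.0 - b / n_batches))

        neg_idx = rng.choice(V, size=(m, n_negative), p=neg_probs)
        vc = W_in[c_idx]  # (m, dim)
        vpos = W_out[pos_idx]  # (m, dim)
        vneg = W_out[neg_idx]  # (m, k, dim)

        g_pos = expit(np.einsum("md,md->m", vc, vpos)) - 1.0  # (m,)
        g_neg = expit(np.einsum("md,mkd->mk", vc, vneg))  # (m, k)

        grad_c = g_pos[:, None] * vpos + np.einsum("mk,mkd->md", g_neg, vneg)
        np.add.at(W_in, c_idx, -eta * grad_c)
        np.add.at(W_out, pos_idx, -eta * g_pos[:, None] * vc)
        np.add.at(W_out, neg_idx.ravel(), -eta * (g_neg[:, :, None] * vc[:, None, :]).reshape(-1, dim))

    return EmbeddingTable(codes=codes, vectors=W_in)
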