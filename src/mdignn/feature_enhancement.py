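"""Topological node embeddings via random walks + skip-gram (node2vec).

Walks run on the symmetrized (undirected) view of the graph — directed
regulatory networks have many sink nodes where directed walks would die,
leaving genes under-sampled. With the unbiased defaults (return and in-out
parameters both 1) the walk is a simple uniform random walk. The walk
corpus is fed to a skip-gram model with negative sampling, implemented
with vectorized numpy mini-batches, yielding one 16-dimensional vector per
gene that is concatenated onto the biological+SYS block (58 + 16 = 74
columns in the pan-cancer configuration).

Embeddings are label-free, so they are computed once on the full graph
before any cross-validation split (transductive setting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import FeatureMatrix, GeneGraph

__all__ = ["WalkConfig", "simulate_walks", "embed_walks", "node2vec_embedding",
           "concat_features"]


@dataclass(frozen=True)
class WalkConfig:
    """Random-walk and skip-gram settings.

    ``q_walk`` is node2vec's in-out bias, distinct from the Laplacian's
    phase parameter q. Defaults: 16-dim embeddings, walk length 80,
    context window 5, 10 walks per node, unbiased walks.
    """

    dimensions: int = 16
    walk_length: int = 80
    context_size: int = 5
    walks_per_node: int = 10
    return_param: float = 1.0
    inout_param: float = 1.0  # q_walk
    sg_epochs: int = 5
    negatives: int = 5
    lr: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.dimensions <= 0:
            raise ValueError("embedding dimension must be positive")
        if self.walk_length < 1 or self.walks_per_node < 1:
            raise ValueError("walk length and walks per node must be >= 1")


def _undirected_adjacency(graph: GeneGraph) -> tuple[np.ndarray, np.ndarray]:
    """CSR-style (indptr, neighbors) of the symmetrized graph."""
    n = graph.n_nodes
    src, tgt = graph.edge_arrays()
    pairs = np.unique(
        np.concatenate(
            [np.stack([src, tgt], axis=1), np.stack([tgt, src], axis=1)], axis=0
        ),
        axis=0,
    ) if len(src) else np.empty((0, 2), dtype=np.int64)
    counts = np.bincount(pairs[:, 0], minlength=n) if len(pairs) else np.zeros(n, int)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    return indptr.astype(np.int64), pairs[:, 1].copy() if len(pairs) else np.empty(0, np.int64)


def simulate_walks(graph: GeneGraph, config: WalkConfig) -> list[list[int]]:
    """Uniform random walks on the symmetrized graph.

    ``walks_per_node`` walks start from every node; a walk stops early only
    at a dead end (isolated node → length-1 walk). Deterministic under a
    fixed seed, independent of node labelling (the RNG is consumed in
    canonical node order).
    """
    if graph.n_nodes == 0:
        raise ValueError("graph is empty")
    rng = np.random.default_rng(config.seed)
    indptr, neighbors = _undirected_adjacency(graph)
    n = graph.n_nodes
    walks: list[list[int]] = []
    for _ in range(config.walks_per_node):
        # advance all walks one start-node batch at a time, vectorized per step
        current = np.arange(n)
        alive = (indptr[1:] - indptr[:-1]) > 0
        rows = [current.copy()]
        for _step in range(config.walk_length - 1):
            nxt = current.copy()
            idx = np.flatnonzero(alive)
            if len(idx):
                lo, hi = indptr[current[idx]], indptr[current[idx] + 1]
                pick = lo + rng.integers(0, hi - lo)
                nxt[idx] = neighbors[pick]
            rows.append(nxt)
            current = nxt
        steps = np.stack(rows, axis=1)  # n × walk_length
        has_nb = (indptr[1:] - indptr[:-1]) > 0
        for i in range(n):
            walks.append(list(steps[i]) if has_nb[i] else [i])
    return walks


def _walk_pairs(walks: list[list[int]], window: int,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) pairs with word2vec's dynamic window shrinking.

    Walks are grouped by length so pair extraction is fully vectorized:
    for each offset d ≤ window, a center emits the context d steps to
    either side whenever its per-position window draw covers d.
    """
    by_len: dict[int, list[list[int]]] = {}
    for walk in walks:
        if len(walk) >= 2:
            by_len.setdefault(len(walk), []).append(walk)
    centers, contexts = [], []
    for ln in sorted(by_len):
        mat = np.asarray(by_len[ln], dtype=np.int64)
        spans = rng.integers(1, window + 1, size=mat.shape)
        for d in range(1, min(window, ln - 1) + 1):
            right = spans[:, :ln - d] >= d
            centers.append(mat[:, :ln - d][right])
            contexts.append(mat[:, d:][right])
            left = spans[:, d:] >= d
            centers.append(mat[:, d:][left])
            contexts.append(mat[:, :ln - d][left])
    if not centers:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def _mean_update(table: np.ndarray, index: np.ndarray, grad: np.ndarray,
                 lr: float) -> None:
    import scipy.sparse as sp

    n = table.shape[0]
    counts = np.bincount(index, minlength=n).astype(np.float64)
    counts[counts == 0] = 1.0
    weights = 1.0 / counts[index]
    M = sp.coo_matrix((weights, (index, np.arange(len(index)))),
                      shape=(n, len(index))).tocsr()
    table += lr * (M @ grad)


def embed_walks(walks: list[list[int]], n_nodes: int,
                config: WalkConfig) -> np.ndarray:
    """Skip-gram with negative sampling over the walk corpus.

    Negative contexts are drawn from the unigram distribution raised to
    3/4. Returns an N×dimensions real matrix; a node that never appears in
    the corpus keeps its (small) initial vector.
    """
    if not walks:
        raise ValueError("walk corpus is empty")
    rng = np.random.default_rng(config.seed + 1)
    dim = config.dimensions
    w_in = (rng.random((n_nodes, dim)) - 0.5) / dim
    w_out = np.zeros((n_nodes, dim))

    counts = np.bincount(
        np.concatenate([np.asarray(w) for w in walks]), minlength=n_nodes
    ).astype(np.float64)
    noise = counts ** 0.75
    noise /= noise.sum()

    centers, contexts = _walk_pairs(walks, config.context_size, rng)
    n_pairs = len(centers)
    if n_pairs == 0:
        return w_in
    batch = 16384
    k = config.negatives
    noise_cdf = np.cumsum(noise)
    for epoch in range(config.sg_epochs):
        lr = config.lr * (1.0 - epoch / config.sg_epochs)
        order = rng.permutation(n_pairs)
        all_neg = np.searchsorted(
            noise_cdf, rng.random((n_pairs, k))
        ).astype(np.int64)
        for start in range(0, n_pairs, batch):
            sel = order[start:start + batch]
            c, o = centers[sel], contexts[sel]
            neg = all_neg[sel]
            vc = w_in[c]                                  # b×d
            targets = np.concatenate([o[:, None], neg], axis=1)  # b×(1+k)
            vt = w_out[targets]                           # b×(1+k)×d
            score = np.einsum("bd,bkd->bk", vc, vt)
            sig = 1.0 / (1.0 + np.exp(-np.clip(score, -30, 30)))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            err = (label - sig)                           # b×(1+k)
            grad_c = np.einsum("bk,bkd->bd", err, vt)
            grad_t = err[:, :, None] * vc[:, None, :]
            # within-batch updates are averaged per node (a node hit many
            # times in one batch gets the mean step, not the sum), which
            # keeps the batched approximation of sequential SGD stable
            _mean_update(w_in, c, grad_c, lr)
            _mean_update(w_out, targets.ravel(), grad_t.reshape(-1, dim), lr)
    w_in[counts == 0] = 0.0
    return w_in


def node2vec_embedding(graph: GeneGraph, config: WalkConfig) -> np.ndarray:
    """Walk simulation + skip-gram in one call."""
    walks = simulate_walks(graph, config)
    return embed_walks(walks, graph.n_nodes, config)


def concat_features(bio_sys: FeatureMatrix, topo: np.ndarray,
                    enabled: bool = True) -> FeatureMatrix:
    """Append the topological block; ``enabled=False`` (ablation) returns
    the biological+SYS matrix unchanged."""
    if not enabled:
        return bio_sys
    topo = np.asarray(topo, dtype=np.float64)
    if topo.shape[0] != len(bio_sys.gene_order):
        raise ValueError(
            f"gene-order mismatch: {topo.shape[0]} embeddings for "
            f"{len(bio_sys.gene_order)} genes"
        )
    f0 = bio_sys.n_features
    blocks = dict(bio_sys.column_blocks)
    blocks["topological"] = (f0, f0 + topo.shape[1])
    names = None
    if bio_sys.column_names is not None:
        names = bio_sys.column_names + tuple(
            f"topo_{j}" for j in range(topo.shape[1])
        )
    return FeatureMatrix(
        values=np.hstack([bio_sys.values, topo]),
        gene_order=bio_sys.gene_order,
        column_blocks=blocks,
        column_names=names,
    )
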