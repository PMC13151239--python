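"""Node2vec topological embeddings of the heterogeneous graph.

Biased second-order random walks (return parameter ``p``, in-out parameter
``q``) generate node sequences over the bidirected graph treated as
undirected; a skip-gram model with negative sampling (SGNS) trained on the
walk corpus yields one low-dimensional vector per node.  Both stages are
implemented in numpy and fully seeded, so embeddings are reproducible.

Isolated nodes never appear in walks and receive an all-zero embedding row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .graph import HeteroGraph

__all__ = ["generate_walks", "node2vec_embed", "write_embedding", "read_embedding"]


def _neighbor_lists(g: HeteroGraph) -> tuple[np.ndarray, np.ndarray]:
    """CSR-style (indptr, indices) of the undirected adjacency."""
    a = g.adjacency()
    indptr = np.zeros(g.n_nodes + 1, dtype=np.int64)
    indices = []
    for v in range(g.n_nodes):
        nbrs = np.flatnonzero(a[v])
        indices.append(nbrs)
        indptr[v + 1] = indptr[v] + len(nbrs)
    return indptr, np.concatenate(indices) if indices else np.empty(0, np.int64)


def generate_walks(
    g: HeteroGraph,
    *,
    walk_len: int = 80,
    n_walks: int = 10,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Biased random walks, ``n_walks`` starts per non-isolated node.

    Each walk has at most ``walk_len`` nodes; consecutive walk entries are
    always edges of the graph.  With p = q = 1 the walk is a uniform
    first-order random walk and is generated fully vectorized.
    """
    rng = np.random.default_rng(seed)
    indptr, indices = _neighbor_lists(g)
    deg = np.diff(indptr)
    starts = np.repeat(np.flatnonzero(deg > 0), n_walks)
    rng.shuffle(starts)
    if len(starts) == 0:
        return []

    if p == 1.0 and q == 1.0:
        walks = np.empty((len(starts), walk_len), dtype=np.int64)
        walks[:, 0] = starts
        cur = starts.copy()
        for t in range(1, walk_len):
            u = rng.random(len(cur))
            off = (u * deg[cur]).astype(np.int64)
            cur = indices[indptr[cur] + off]
            walks[:, t] = cur
        return [w for w in walks]

    # second-order biased walks (per-walk loop; used off the default path)
    nbr_sets = [set(indices[indptr[v] : indptr[v + 1]].tolist()) for v in range(g.n_nodes)]
    out: list[np.ndarray] = []
    for s in starts:
        walk = [int(s)]
        prev = -1
        for _ in range(walk_len - 1):
            v = walk[-1]
            nbrs = indices[indptr[v] : indptr[v + 1]]
            if len(nbrs) == 0:
                break
            if prev < 0:
                nxt = int(rng.choice(nbrs))
            else:
                w = np.where(
                    nbrs == prev,
                    1.0 / p,
                    np.where([x in nbr_sets[prev] for x in nbrs], 1.0, 1.0 / q),
                )
                nxt = int(rng.choice(nbrs, p=w / w.sum()))
            prev = v
            walk.append(nxt)
        out.append(np.array(walk, dtype=np.int64))
    return out


def _cooccurrence(walks: list[np.ndarray], window: int, n: int) -> np.ndarray:
    """Symmetric (center, context) co-occurrence counts within the window."""
    cooc = np.zeros(n * n)
    for off in range(1, window + 1):
        flats = []
        for w in walks:
            if len(w) <= off:
                continue
            flats.append(w[:-off] * n + w[off:])
            flats.append(w[off:] * n + w[:-off])
        if flats:
            flat = np.concatenate(flats)
            cooc += np.bincount(flat, minlength=n * n)
    return cooc.reshape(n, n)


def node2vec_embed(
    g: HeteroGraph,
    dim: int = 64,
    *,
    p: float = 1.0,
    q: float = 1.0,
    walk_len: int = 80,
    n_walks: int = 10,
    window: int = 5,
    seed: int = 0,
    n_negative: int = 5,
    iters: int = 300,
    lr: float = 0.05,
) -> np.ndarray:
    """Node2vec embedding matrix of shape (n_nodes, dim).

    The skip-gram-with-negative-sampling objective is optimized in its
    expected (full-batch) form over the walk co-occurrence counts: maximize
    Σ_ij [ C_ij log σ(u_i·v_j) + N_ij log σ(−u_i·v_j) ], where C is the
    windowed co-occurrence matrix of the biased walks and N_ij the expected
    number of negative draws (``n_negative`` per observed center occurrence,
    noise ∝ unigram^(3/4)).  Adam for ``iters`` full-batch steps.
    Deterministic under ``seed``; isolated nodes receive a zero row.
    """
    if dim <= 0:
        raise ValueError("embedding dimension must be positive")
    rng = np.random.default_rng(seed)
    walks = generate_walks(
        g, walk_len=walk_len, n_walks=n_walks, p=p, q=q, seed=seed
    )
    n = g.n_nodes
    emb = np.zeros((n, dim))
    if not walks:
        return emb
    counts = np.bincount(np.concatenate(walks), minlength=n).astype(np.float64)
    cooc = _cooccurrence(walks, window, n)
    noise = counts**0.75
    noise /= noise.sum()
    negatives = n_negative * cooc.sum(axis=1, keepdims=True) * noise[None, :]
    scale = 1.0 / cooc.sum()

    vec_in = rng.normal(0.0, 1.0 / np.sqrt(dim), (n, dim))
    vec_out = rng.normal(0.0, 1.0 / np.sqrt(dim), (n, dim))
    m = [np.zeros_like(vec_in) for _ in range(2)]
    v = [np.zeros_like(vec_in) for _ in range(2)]
    b1, b2, eps = 0.9, 0.999, 1e-8
    for t in range(1, iters + 1):
        s = 0.5 * (1.0 + np.tanh(0.5 * (vec_in @ vec_out.T)))
        grad_logit = scale * (cooc * (s - 1.0) + negatives * s)
        grads = (grad_logit @ vec_out, grad_logit.T @ vec_in)
        for i, (w, gr) in enumerate(zip((vec_in, vec_out), grads)):
            m[i] = b1 * m[i] + (1 - b1) * gr
            v[i] = b2 * v[i] + (1 - b2) * gr**2
            w -= lr * (m[i] / (1 - b1**t)) / (np.sqrt(v[i] / (1 - b2**t)) + eps)

    active = counts > 0
    emb[active] = vec_in[active]
    return emb


def write_embedding(path, values: np.ndarray, labels) -> None:
    """Cache an embedding as a labeled TSV (one row per node)."""
    pd.DataFrame(values, index=list(labels)).to_csv(path, sep="\t", header=False)


def read_embedding(path, labels) -> np.ndarray:
    """Read a cached embedding, reordered to ``labels``."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=None)
    return df.loc[list(labels)].to_numpy(dtype=np.float64)
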