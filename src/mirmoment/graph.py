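"""Heterogeneous disease-miRNA graph, normalized adjacency, negative
sampling and association-level cross-validation folds.

Node order is diseases ``[0, n_D)`` followed by miRNAs ``[n_D, n_D + n_M)``.
Every known association contributes a disease->miRNA edge and its reverse, so
message passing runs in both directions; there are no within-type edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AssociationTable

__all__ = [
    "HeteroGraph",
    "NormalizedAdjacency",
    "SamplePartition",
    "build_graph",
    "normalize_adjacency",
    "sample_negatives",
    "make_folds",
]


@dataclass(frozen=True)
class HeteroGraph:
    """Bidirected bipartite graph over disease and miRNA nodes.

    ``associations`` is the (n_pairs, 2) array of (disease_index,
    mirna_index) pairs; each contributes two directed edges.
    """

    n_diseases: int
    n_mirnas: int
    associations: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return self.n_diseases + self.n_mirnas

    @property
    def n_edges(self) -> int:
        """Number of directed edges (2 per association)."""
        return 2 * self.associations.shape[0]

    def directed_edges(self) -> set[tuple[int, int]]:
        """All directed edges in global node indices."""
        out: set[tuple[int, int]] = set()
        for d, m in self.associations:
            g = int(m) + self.n_diseases
            out.add((int(d), g))
            out.add((g, int(d)))
        return out

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency over all nodes."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        if self.associations.size:
            d = self.associations[:, 0]
            m = self.associations[:, 1] + self.n_diseases
            a[d, m] = 1.0
            a[m, d] = 1.0
        return a


@dataclass
class NormalizedAdjacency:
    """Symmetrically degree-normalized adjacency a_ij / sqrt(deg_i deg_j)."""

    values: np.ndarray = field(repr=False)


def build_graph(assoc: AssociationTable) -> HeteroGraph:
    if assoc.n_pairs == 0:
        raise ValueError("cannot build a graph from an empty association table")
    return HeteroGraph(
        n_diseases=assoc.n_diseases,
        n_mirnas=assoc.n_mirnas,
        associations=assoc.pair_array(),
    )


def normalize_adjacency(
    g: HeteroGraph, *, exclude: np.ndarray | None = None
) -> NormalizedAdjacency:
    """Symmetric normalization D^{-1/2} A D^{-1/2} without self-loops.

    ``exclude`` is an optional (k, 2) array of (disease, mirna) pairs removed
    from the adjacency before normalization (strict-holdout mode).  Isolated
    nodes get all-zero rows rather than raising.
    """
    a = g.adjacency()
    if exclude is not None and len(exclude):
        ex = np.asarray(exclude, dtype=np.int64)
        d = ex[:, 0]
        m = ex[:, 1] + g.n_diseases
        a[d, m] = 0.0
        a[m, d] = 0.0
    deg = a.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    return NormalizedAdjacency(values=a * inv_sqrt[:, None] * inv_sqrt[None, :])


def sample_negatives(assoc: AssociationTable, n: int, seed: int) -> np.ndarray:
    """Sample ``n`` distinct unconfirmed (disease, mirna) pairs.

    Drawn uniformly without replacement from the global pool of pairs not in
    the association table, once, before any fold splitting.  Reproducible
    under ``seed``.
    """
    total = assoc.n_diseases * assoc.n_mirnas
    pos_flat = {i * assoc.n_mirnas + j for i, j in assoc.pairs}
    n_available = total - len(pos_flat)
    if n > n_available:
        raise ValueError(f"requested {n} negatives but only {n_available} available")
    rng = np.random.default_rng(seed)
    # rejection-free: sample from the explicit complement (universe <= ~10^6)
    pool = np.setdiff1d(
        np.arange(total, dtype=np.int64),
        np.fromiter(pos_flat, dtype=np.int64, count=len(pos_flat)),
        assume_unique=True,
    )
    chosen = rng.choice(pool, size=n, replace=False)
    return np.stack([chosen // assoc.n_mirnas, chosen % assoc.n_mirnas], axis=1)


@dataclass
class SamplePartition:
    """Balanced positive/negative samples with a k-fold assignment each.

    ``positives`` and ``negatives`` are (n, 2) index-pair arrays;
    ``fold_of_positive`` / ``fold_of_negative`` give each sample's fold in
    [0, k).  Positives and negatives are split with the same procedure so
    every fold is (near-)balanced.
    """

    positives: np.ndarray = field(repr=False)
    negatives: np.ndarray = field(repr=False)
    fold_of_positive: np.ndarray = field(repr=False)
    fold_of_negative: np.ndarray = field(repr=False)
    k: int = 5

    def fold_members(self, fold: int, which: str, train: bool) -> np.ndarray:
        """Index pairs of the train or test portion of a fold."""
        pairs, folds = (
            (self.positives, self.fold_of_positive)
            if which == "positive"
            else (self.negatives, self.fold_of_negative)
        )
        mask = (folds != fold) if train else (folds == fold)
        return pairs[mask]

    def to_frame(self, disease_ids, mirna_ids) -> pd.DataFrame:
        """Labeled export: disease, miRNA, label, fold."""
        rows = []
        for pairs, folds, label in (
            (self.positives, self.fold_of_positive, 1),
            (self.negatives, self.fold_of_negative, 0),
        ):
            for (i, j), f in zip(pairs, folds):
                rows.append((disease_ids[i], mirna_ids[j], label, int(f)))
        return pd.DataFrame(rows, columns=["disease", "mirna", "label", "fold"])


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold labels with near-equal sizes; earlier folds absorb the
    remainder (sizes differ by at most 1)."""
    sizes = np.full(k, n // k, dtype=np.int64)
    sizes[: n % k] += 1
    labels = np.repeat(np.arange(k), sizes)
    rng.shuffle(labels)
    return labels


def make_folds(
    positives: np.ndarray, negatives: np.ndarray, k: int = 5, seed: int = 0
) -> SamplePartition:
    """Association-level k-fold partition of positives and negatives."""
    positives = np.asarray(positives, dtype=np.int64)
    negatives = np.asarray(negatives, dtype=np.int64)
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(positives) < k or len(negatives) < k:
        raise ValueError("fewer samples than folds")
    rng = np.random.default_rng(seed)
    return SamplePartition(
        positives=positives,
        negatives=negatives,
        fold_of_positive=_fold_assignment(len(positives), k, rng),
        fold_of_negative=_fold_assignment(len(negatives), k, rng),
        k=k,
    )
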