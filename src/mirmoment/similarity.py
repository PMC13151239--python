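"""Gaussian interaction-profile (GIP) kernels, similarity integration and
initial node-feature assembly.

The GIP kernel scores two entities by the RBF similarity of their binary
interaction profiles: ``S[i, j] = exp(-gamma * ||y_i - y_j||^2)``.  The
bandwidth ``gamma`` is set from the data as ``n / sum_i ||y_i||^2`` (the
reciprocal of the mean squared profile norm), the standard normalization for
interaction-profile kernels, so kernel values are comparable across datasets
of different scale.

Integration keeps the curated similarity (semantic or functional) wherever it
is informative and falls back to the GIP value only where the curated entry
is zero, preserving prior knowledge while removing sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import BinaryProfileMatrix, SimilarityMatrix

__all__ = [
    "GipBandwidth",
    "NodeFeatureMatrix",
    "gip_bandwidth",
    "gip_kernel",
    "integrate_similarity",
    "build_node_features",
]


@dataclass(frozen=True)
class GipBandwidth:
    """Kernel bandwidth gamma > 0."""

    gamma: float

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


@dataclass
class NodeFeatureMatrix:
    """Raw node features, one row per graph node (diseases first).

    Column layout: [disease-similarity block | miRNA-similarity block |
    topological embedding | node-type one-hot].  Disease rows are zero in the
    miRNA-similarity block and vice versa; the one-hot is (1, 0) for disease
    nodes and (0, 1) for miRNA nodes.
    """

    node_labels: tuple[str, ...]
    n_diseases: int
    values: np.ndarray = field(repr=False)


def gip_bandwidth(profiles: BinaryProfileMatrix) -> GipBandwidth:
    """Bandwidth gamma = n_rows / sum_i ||y_i||^2 (1 / mean squared norm)."""
    sq = np.sum(profiles.values**2)
    if sq == 0:
        raise ValueError("all-zero profile matrix: bandwidth undefined")
    return GipBandwidth(gamma=profiles.values.shape[0] / sq)


def gip_kernel(profiles: BinaryProfileMatrix, bw: GipBandwidth) -> SimilarityMatrix:
    """GIP kernel matrix S[i, j] = exp(-gamma ||y_i - y_j||^2)."""
    y = profiles.values
    sq = np.sum(y**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (y @ y.T)
    np.maximum(d2, 0.0, out=d2)
    s = np.exp(-bw.gamma * d2)
    # enforce exact symmetry and unit diagonal against float round-off
    s = 0.5 * (s + s.T)
    np.fill_diagonal(s, 1.0)
    sim = SimilarityMatrix(labels=profiles.row_labels, values=s)
    sim.validate(atol=1e-9, unit_diagonal=True)
    return sim


def integrate_similarity(
    primary: SimilarityMatrix, gip: SimilarityMatrix
) -> SimilarityMatrix:
    """Entrywise preference: primary where primary > 0, else the GIP value.

    The diagonal is forced to 1.  Idempotent: integrating the result again
    with the same GIP matrix changes nothing.
    """
    if primary.labels != gip.labels:
        raise ValueError("label mismatch between primary and GIP matrices")
    out = np.where(primary.values > 0.0, primary.values, gip.values)
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(labels=primary.labels, values=out)


def build_node_features(
    integrated_disease: SimilarityMatrix,
    integrated_mirna: SimilarityMatrix,
    topo: np.ndarray,
) -> NodeFeatureMatrix:
    """Assemble raw (unprojected) node features in graph node order.

    ``topo`` must have one row per node, diseases first then miRNAs.  The raw
    feature width is n_D + n_M + embed_dim + 2; the learnable projection to
    the hidden width is a model parameter, trained per fold, and is not
    applied here.
    """
    n_d = len(integrated_disease.labels)
    n_m = len(integrated_mirna.labels)
    topo = np.asarray(topo, dtype=np.float64)
    if topo.shape[0] != n_d + n_m:
        raise ValueError(
            f"topological embedding has {topo.shape[0]} rows, expected {n_d + n_m}"
        )
    dim = topo.shape[1]
    width = n_d + n_m + dim + 2
    x = np.zeros((n_d + n_m, width))
    x[:n_d, :n_d] = integrated_disease.values
    x[n_d:, n_d : n_d + n_m] = integrated_mirna.values
    x[:, n_d + n_m : n_d + n_m + dim] = topo
    x[:n_d, -2] = 1.0  # disease one-hot
    x[n_d:, -1] = 1.0  # miRNA one-hot
    labels = integrated_disease.labels + integrated_mirna.labels
    return NodeFeatureMatrix(node_labels=labels, n_diseases=n_d, values=x)
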