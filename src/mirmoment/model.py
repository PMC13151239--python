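"""Two-layer moment-convolution network, pair scoring, five-fold
cross-validated training, metrics and candidate ranking.

The network projects raw node features to a hidden width, applies two
:class:`~mirmoment.layer.AdaptiveMomentConv` layers over the normalized
adjacency, splits the output into disease and miRNA blocks, and scores a
pair (d_i, m_j) as ``σ(wᵀ[h_i^D; h_j^M] + b)``.  Training minimizes mean
binary cross-entropy with Adam (full batch — the graph and sample set are
small) under an association-level k-fold protocol: only training-fold pairs
contribute to the loss; test-fold pairs are scored once at the end with the
deterministic inference path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .autodiff import Adam, Parameter, Tensor
from .data import AssociationTable, SimilarityMatrix, to_profile_matrix
from .embed import node2vec_embed
from .graph import (
    HeteroGraph,
    SamplePartition,
    build_graph,
    make_folds,
    normalize_adjacency,
    sample_negatives,
)
from .layer import AdaptiveMomentConv, LayerConfig, LayerState
from .similarity import (
    NodeFeatureMatrix,
    build_node_features,
    gip_bandwidth,
    gip_kernel,
    integrate_similarity,
)

__all__ = [
    "ModelConfig",
    "EmbedConfig",
    "MomentNet",
    "FoldResult",
    "CVResult",
    "score_pairs",
    "bce_loss",
    "compute_metrics",
    "train_fold",
    "run_cv",
    "rank_candidates",
    "prepare_inputs",
    "run_experiment",
    "order1_ablation",
]


@dataclass
class ModelConfig:
    """Model and training hyperparameters.

    Defaults follow the reference configuration: hidden width 64, two
    convolution layers, candidate order pool M_max = 10 with Top-K = 5,
    Adam at learning rate 5e-5 with weight decay 1e-3, dropout 0.3 (main)
    and 0.2 (node-level / feature-level), seed 1234.  The epoch budget is
    configurable (default 400 with early stop on a training-loss plateau).
    """

    hidden_dim: int = 64
    n_layers: int = 2
    m_max: int = 10
    top_k: int = 5
    lr: float = 5e-5
    weight_decay: float = 1e-3
    dropout_main: float = 0.3
    dropout_node: float = 0.2
    dropout_feat: float = 0.2
    epochs: int = 400
    patience: int = 50
    seed: int = 1234
    threshold: float = 0.5
    gate_gamma: float = 0.1
    gumbel_tau: float = 1.0
    clip: float = 10.0
    eps: float = 1e-6
    attention: str = "additive"

    def __post_init__(self) -> None:
        for name in ("hidden_dim", "n_layers", "m_max", "top_k", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def layer_config(self) -> LayerConfig:
        return LayerConfig(
            m_max=self.m_max,
            top_k=self.top_k,
            gate_gamma=self.gate_gamma,
            gumbel_tau=self.gumbel_tau,
            clip=self.clip,
            eps=self.eps,
            attention=self.attention,
        )


@dataclass
class EmbedConfig:
    """node2vec settings for the topological embedding stage."""

    dim: int = 64
    p: float = 1.0
    q: float = 1.0
    walk_len: int = 80
    n_walks: int = 10
    window: int = 5
    iters: int = 300


class MomentNet:
    """Input projection + stacked adaptive moment convolutions + pair scorer."""

    def __init__(self, in_dim: int, n_diseases: int, cfg: ModelConfig):
        self.cfg = cfg
        self.n_diseases = n_diseases
        rng = np.random.default_rng(cfg.seed)
        h = cfg.hidden_dim
        self.w_in = Parameter(rng.normal(0.0, np.sqrt(1.0 / in_dim), (in_dim, h)))
        self.b_in = Parameter(np.zeros(h))
        self.layers = [
            AdaptiveMomentConv(h, cfg.layer_config(), rng)
            for _ in range(cfg.n_layers)
        ]
        self.scorer_w = Parameter(rng.normal(0.0, np.sqrt(1.0 / (2 * h)), 2 * h))
        self.scorer_b = Parameter(np.zeros(()))

    def parameters(self) -> list[Parameter]:
        params = [self.w_in, self.b_in, self.scorer_w, self.scorer_b]
        for layer in self.layers:
            params.extend(layer.parameters())
        return params

    @staticmethod
    def _dropout(x: Tensor, p: float, rng: np.random.Generator, shape=None) -> Tensor:
        if p <= 0:
            return x
        mask = (rng.random(shape or x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    def forward(
        self,
        features: np.ndarray,
        adj: np.ndarray,
        *,
        mode: str = "infer",
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, list[LayerState]]:
        """Node embeddings (all nodes, hidden width) and per-layer states.

        Dropout (node-level and feature-level on the input, main dropout on
        hidden states between layers) is active only in 'train' mode.
        """
        x = Tensor(np.asarray(features, dtype=np.float64))
        training = mode == "train"
        if training:
            if rng is None:
                rng = np.random.default_rng()
            x = self._dropout(x, self.cfg.dropout_node, rng, (x.shape[0], 1))
            x = self._dropout(x, self.cfg.dropout_feat, rng)
        h = x @ self.w_in + self.b_in
        states: list[LayerState] = []
        for i, layer in enumerate(self.layers):
            if training and i > 0:
                h = self._dropout(h, self.cfg.dropout_main, rng)
            h, st = layer.forward(h, adj, mode=mode, rng=rng)
            states.append(st)
        return h, states

    def pair_logits(self, h: Tensor, pairs: np.ndarray) -> Tensor:
        """Unnormalized scores wᵀ[h_i^D; h_j^M] + b for (d, m) index pairs."""
        pairs = np.asarray(pairs, dtype=np.int64)
        hd = h.take_rows(pairs[:, 0])
        hm = h.take_rows(pairs[:, 1] + self.n_diseases)
        u = Tensor.concat([hd, hm], axis=1)
        return u @ self.scorer_w + self.scorer_b

    def split_embeddings(self, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return h[: self.n_diseases], h[self.n_diseases :]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"p{i}"], dtype=np.float64).reshape(p.shape)


def score_pairs(
    h_disease: np.ndarray,
    h_mirna: np.ndarray,
    pairs: np.ndarray,
    w: np.ndarray,
    b: float,
) -> np.ndarray:
    """Association probabilities σ(wᵀ[h_i^D; h_j^M] + b) for index pairs."""
    pairs = np.asarray(pairs, dtype=np.int64)
    if pairs.size and (
        pairs[:, 0].max() >= len(h_disease) or pairs[:, 1].max() >= len(h_mirna)
    ):
        raise IndexError("pair index out of range")
    u = np.concatenate([h_disease[pairs[:, 0]], h_mirna[pairs[:, 1]]], axis=1)
    logits = u @ np.asarray(w, float) + b
    return 0.5 * (1.0 + np.tanh(0.5 * logits))


def bce_loss(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy; probabilities clamped to [1e-7, 1−1e-7]."""
    y_hat = np.asarray(y_hat, float)
    y = np.asarray(y, float)
    if y_hat.shape != y.shape:
        raise ValueError("prediction/label length mismatch")
    p = np.clip(y_hat, 1e-7, 1.0 - 1e-7)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def compute_metrics(
    y_hat: np.ndarray, y: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """AUC, AUPR plus thresholded accuracy / precision / F1.

    AUC is the rank-based (Mann-Whitney) ROC area and AUPR the step-wise
    precision-recall integral, both via scikit-learn.  Requires both classes.
    """
    y_hat = np.asarray(y_hat, float)
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present")
    pred = (y_hat >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return {
        "auc": float(roc_auc_score(y, y_hat)),
        "aupr": float(average_precision_score(y, y_hat)),
        "accuracy": (tp + tn) / len(y),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
    }


@dataclass
class FoldResult:
    """Held-out predictions, metrics and mechanism snapshot of one fold."""

    fold_index: int
    test_pairs: np.ndarray = field(repr=False)
    test_labels: np.ndarray = field(repr=False)
    predictions: np.ndarray = field(repr=False)
    metrics: dict[str, float] = field(default_factory=dict)
    layer_states: list[LayerState] = field(default_factory=list, repr=False)
    train_losses: list[float] = field(default_factory=list, repr=False)
    model: "MomentNet | None" = field(default=None, repr=False)


@dataclass
class CVResult:
    folds: list[FoldResult]

    def metric_table(self) -> dict[str, tuple[float, float]]:
        """Per-metric (mean, SD) across folds."""
        names = self.folds[0].metrics.keys()
        out = {}
        for name in names:
            vals = np.array([f.metrics[name] for f in self.folds])
            out[name] = (float(vals.mean()), float(vals.std(ddof=0)))
        return out


def _fold_samples(
    partition: SamplePartition, fold: int, train: bool
) -> tuple[np.ndarray, np.ndarray]:
    pos = partition.fold_members(fold, "positive", train)
    neg = partition.fold_members(fold, "negative", train)
    pairs = np.concatenate([pos, neg], axis=0)
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return pairs, labels


def train_fold(
    partition: SamplePartition,
    fold: int,
    features: np.ndarray,
    adj: np.ndarray,
    cfg: ModelConfig,
    n_diseases: int,
) -> FoldResult:
    """Train on the fold's training samples and evaluate on its test samples.

    Full-graph forward per epoch, Adam on mean BCE (stable logits form),
    early stop when the training loss has not improved for ``cfg.patience``
    epochs.  Non-finite loss aborts with diagnostics.  Reproducible under
    ``cfg.seed`` (the fold index is mixed into the stream so folds are
    independent but deterministic).
    """
    if not (0 <= fold < partition.k):
        raise ValueError(f"fold must be in [0, {partition.k})")
    if not (np.isfinite(features).all() and np.isfinite(adj).all()):
        raise RuntimeError(
            "training diverged before it began: non-finite values in the "
            "node features or adjacency"
        )
    train_pairs, train_y = _fold_samples(partition, fold, train=True)
    test_pairs, test_y = _fold_samples(partition, fold, train=False)
    y_t = Tensor(train_y)

    model = MomentNet(features.shape[1], n_diseases, cfg)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng([cfg.seed, fold])

    losses: list[float] = []
    best, stale = np.inf, 0
    for epoch in range(cfg.epochs):
        h, _ = model.forward(features, adj, mode="train", rng=rng)
        logits = model.pair_logits(h, train_pairs)
        loss = (logits.softplus() - y_t * logits).mean()
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(
                f"training diverged at epoch {epoch} (fold {fold}): loss={value}"
            )
        losses.append(value)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if value < best - 1e-6:
            best, stale = value, 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    h, states = model.forward(features, adj, mode="infer")
    scores = 0.5 * (1.0 + np.tanh(0.5 * model.pair_logits(h, test_pairs).data))
    metrics = compute_metrics(scores, test_y, threshold=cfg.threshold)
    result = FoldResult(
        fold_index=fold,
        test_pairs=test_pairs,
        test_labels=test_y,
        predictions=scores,
        metrics=metrics,
        layer_states=states,
        train_losses=losses,
    )
    result.model = model  # kept for ranking / checkpointing
    return result


def run_cv(
    partition: SamplePartition,
    features: np.ndarray,
    adj: np.ndarray,
    cfg: ModelConfig,
    n_diseases: int,
    *,
    graph: HeteroGraph | None = None,
    strict_holdout: bool = False,
) -> CVResult:
    """Train/evaluate every fold.

    With ``strict_holdout`` the test-fold positive edges are also removed
    from the message-passing adjacency of that fold (off by default: labels
    are held out but the graph keeps all known associations).
    """
    folds = []
    for fold in range(partition.k):
        fold_adj = adj
        if strict_holdout:
            if graph is None:
                raise ValueError("strict_holdout requires the graph")
            test_pos = partition.fold_members(fold, "positive", train=False)
            fold_adj = normalize_adjacency(graph, exclude=test_pos).values
        folds.append(train_fold(partition, fold, features, fold_adj, cfg, n_diseases))
    return CVResult(folds=folds)


def rank_candidates(
    h_disease: np.ndarray,
    h_mirna: np.ndarray,
    disease_index: int,
    w: np.ndarray,
    b: float,
    top_n: int = 50,
) -> list[tuple[int, float]]:
    """All miRNAs scored against one disease, descending; ties break to the
    lower miRNA index.  Returns the top ``top_n`` (index, probability)."""
    if not (0 <= disease_index < len(h_disease)):
        raise IndexError(f"unknown disease index {disease_index}")
    pairs = np.stack(
        [np.full(len(h_mirna), disease_index), np.arange(len(h_mirna))], axis=1
    )
    scores = score_pairs(h_disease, h_mirna, pairs, w, b)
    order = np.argsort(-scores, kind="stable")
    return [(int(j), float(scores[j])) for j in order[:top_n]]


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------


@dataclass
class PreparedInputs:
    """Everything the trainer consumes, built once per dataset."""

    graph: HeteroGraph
    adjacency: np.ndarray = field(repr=False)
    features: NodeFeatureMatrix = field(repr=False)
    integrated_disease: SimilarityMatrix = field(repr=False)
    integrated_mirna: SimilarityMatrix = field(repr=False)


def prepare_inputs(
    assoc: AssociationTable,
    disease_sim: SimilarityMatrix,
    mirna_sim: SimilarityMatrix,
    *,
    embed: EmbedConfig | None = None,
    embed_seed: int = 0,
) -> PreparedInputs:
    """Similarity integration, graph construction and feature assembly.

    GIP kernels are computed once from the full association table (held
    fixed across folds); node2vec runs once on the full graph.
    """
    embed = embed or EmbedConfig()
    prof_d = to_profile_matrix(assoc, "disease")
    prof_m = to_profile_matrix(assoc, "mirna")
    gip_d = gip_kernel(prof_d, gip_bandwidth(prof_d))
    gip_m = gip_kernel(prof_m, gip_bandwidth(prof_m))
    integrated_d = integrate_similarity(disease_sim, gip_d)
    integrated_m = integrate_similarity(mirna_sim, gip_m)

    graph = build_graph(assoc)
    adj = normalize_adjacency(graph).values
    topo = node2vec_embed(
        graph,
        embed.dim,
        p=embed.p,
        q=embed.q,
        walk_len=embed.walk_len,
        n_walks=embed.n_walks,
        window=embed.window,
        iters=embed.iters,
        seed=embed_seed,
    )
    features = build_node_features(integrated_d, integrated_m, topo)
    return PreparedInputs(
        graph=graph,
        adjacency=adj,
        features=features,
        integrated_disease=integrated_d,
        integrated_mirna=integrated_m,
    )


def run_experiment(
    assoc: AssociationTable,
    disease_sim: SimilarityMatrix,
    mirna_sim: SimilarityMatrix,
    cfg: ModelConfig,
    *,
    k: int = 5,
    cv_seed: int | None = None,
    sampling_seed: int | None = None,
    embed: EmbedConfig | None = None,
    strict_holdout: bool = False,
) -> tuple[CVResult, PreparedInputs, SamplePartition]:
    """Full pipeline: similarities → graph → embedding → k-fold CV.

    Negatives are sampled once from the global pool of unconfirmed pairs
    (matched 1:1 to positives) before fold splitting; positives and
    negatives are then partitioned together.
    """
    cv_seed = cfg.seed if cv_seed is None else cv_seed
    sampling_seed = cfg.seed if sampling_seed is None else sampling_seed
    inputs = prepare_inputs(
        assoc, disease_sim, mirna_sim, embed=embed, embed_seed=sampling_seed
    )
    positives = assoc.pair_array()
    negatives = sample_negatives(assoc, len(positives), seed=sampling_seed)
    partition = make_folds(positives, negatives, k=k, seed=cv_seed)
    result = run_cv(
        partition,
        inputs.features.values,
        inputs.adjacency,
        cfg,
        assoc.n_diseases,
        graph=inputs.graph,
        strict_holdout=strict_holdout,
    )
    return result, inputs, partition


def order1_ablation(cfg: ModelConfig) -> ModelConfig:
    """Configuration restricted to mean aggregation only (M_max = K = 1)."""
    return replace(cfg, m_max=1, top_k=1)
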