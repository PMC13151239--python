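# Methods

`mirmoment` predicts disease–miRNA associations by link prediction on a
heterogeneous bipartite graph, using a graph convolution whose aggregation
step summarizes each node's neighborhood feature distribution with
*statistical moments* of several orders and learns which orders matter.
This note records the model, the numerical choices, the synthetic
benchmark, and the limitations a user should know about.

## Input representation

**Similarity integration.** Diseases come with a curated semantic
similarity matrix S^D, miRNAs with a functional similarity matrix S^M
(both consumed as labeled dense TSV; computing them is out of scope).
Both are typically sparse.  From the binary association profiles y_i the
package computes Gaussian interaction-profile (GIP) kernels

    K(i, j) = exp(−γ ‖y_i − y_j‖²),   γ = n / Σ_i ‖y_i‖²

with the bandwidth set to the reciprocal mean squared profile norm — the
standard normalization for interaction-profile kernels, so values are
comparable across datasets of different size.  Integration is an
entrywise hard preference: the curated value is kept wherever it is
nonzero, the GIP value fills the zeros, and the diagonal is forced to 1.
This preserves curated knowledge exactly rather than diluting it by
averaging.  GIP kernels are computed once from the full association table
and held fixed across cross-validation folds; a per-fold recompute flag
is deliberately *not* the default, matching the transductive protocol
(see Limitations).

**Node features.**  Each node's raw feature row is the concatenation of
its integrated-similarity row (diseases and miRNAs occupy disjoint
blocks, zero-padded crosswise), a 64-dimensional node2vec embedding of
the graph, and a 2-bit node-type one-hot.  The projection to the hidden
width is a trained model parameter, so it is fitted per fold.

**Topological embedding.**  Biased second-order random walks (return
parameter p, in-out parameter q, defaults 1/1; 10 walks of length 80 per
node, window 5) generate a co-occurrence matrix C over node pairs.  The
skip-gram-with-negative-sampling objective is optimized in its expected,
full-batch form

    max Σ_ij [ C_ij log σ(u_i·v_j) + N_ij log σ(−u_i·v_j) ],

where N_ij is the expected number of negative draws (5 per observed
center occurrence, noise distribution ∝ unigram^0.75).  Full-batch Adam
(300 iterations, lr 0.05) replaces stochastic per-pair updates: it is
deterministic under the seed, runs on BLAS, and on small graphs avoids
the degeneracies of batched stochastic updates.  Isolated nodes receive
a zero embedding row.

## The adaptive moment convolution

Let Ã be the symmetrically degree-normalized adjacency
(Ã = D^(−1/2) A D^(−1/2), no self-loops — the residual term in the node
update already carries self information).  For hidden features H the
layer computes a stack of per-order neighborhood summaries m_k,
k = 1..M_max (default 10):

* order 1 — the mean aggregation Ã·H, untouched;
* order 2 — the approximate neighborhood variance
  max(0, Ã·H² − (Ã·H)²), clamped elementwise at zero because the
  symmetric normalization is not row-stochastic and the raw difference
  can go slightly negative;
* orders k ≥ 3 — standardized central moments
  Σ_j ã_ij ((h_j − μ_i)/s_i)^k with μ = Ã·H and s = √(order-2 + ε),
  clipped to [−C, C] and compressed by sign(c)·log(1+|c|).

Clipping plus the signed log keep every order finite and on a common
scale even for feature magnitudes up to 10³.

**Numerical evaluation of the central moments.**  The centered sums are
evaluated through the exact binomial expansion in raw moments,
Σ_t C(k,t)·(Ã·H^t)·(−μ)^(k−t), which needs only BLAS matmuls instead of
an n×n×d intermediate.  The expansion cancels catastrophically when a
neighborhood is nearly constant relative to its feature magnitude: the
true centered sum then falls below the float64 round-off of the
expansion (≈1.5e−14 of the term-magnitude sum).  Entries below a 1e−13
relative floor are therefore set to zero.  The practical consequence:
neighborhoods whose spread is many orders of magnitude below their mean
report *no* high-order structure rather than round-off noise amplified
by 1/s^k.  This is the one place the implementation deviates from the
literal per-neighbor formula, and it is confined to that numerically
unresolvable regime; tests check equivalence with a direct per-neighbor
oracle on all resolvable entries.

**Order selection.**  A learnable logit vector over the M_max orders is
turned into weights W by Gumbel-Softmax sampling during training
(temperature 1.0, one categorical sample per layer per forward pass, no
annealing) and by a plain softmax at inference.  A small threshold
network (mean-pool over nodes → tanh(16) → sigmoid, scaled by
τ_scale = 2/M_max so τ lives on the softmax-weight scale) produces a
scalar τ, and each order is gated by g_k = σ((W_k − τ)/γ) with gating
temperature γ = 0.1.  A Top-K mask (K = 5; ties break to the lower
order) guarantees at least K orders survive; the effective weight is
w̃_k = g_k · mask_k (multiplying W in as well is exposed as a config
variant, off by default).

**Cross-order attention and update.**  Each weighted moment stack is
projected per order (z_k = (w̃_k m_k) U_k + b_k), scored per node with an
additive attention head (a·tanh(z); a linear variant is available), and
normalized by a softmax *restricted to retained orders* — masked orders
get exactly zero attention, so w̃_k = 0 implies no contribution.  The
node update is the residual form h' = relu(Σ_k attn_k z_k + h).  Two
such layers are stacked.

## Scoring, training, evaluation

A pair (d, m) is scored ŷ = σ(wᵀ[h_d; h_m] + b) — a logistic read-out on
the concatenated embeddings.  Training minimizes mean binary
cross-entropy (computed in the numerically stable logits form) with Adam
(reference defaults: lr 5e−5, weight decay 1e−3, hidden 64, dropout 0.3
main / 0.2 node-level on input rows / 0.2 feature-level, seed 1234),
full batch — the graphs involved are small.  The epoch budget defaults
to 400 with early stop after 50 epochs without training-loss
improvement; both are configurable.

Evaluation follows an association-level five-fold protocol: negatives
are sampled once, globally, from unconfirmed pairs (1:1 with positives),
then positives and negatives are partitioned into five near-equal folds
(earlier folds absorb any remainder).  Only training-fold samples enter
the loss; test-fold samples are scored once, at the end, on the
deterministic inference path.  AUC is the rank-based ROC area and AUPR
the step-integrated precision–recall area (scikit-learn); accuracy,
precision and F1 use a configurable 0.5 threshold.  Metrics are reported
as mean ± SD over folds.  By default the test-fold *edges* remain in the
message-passing graph (only the labels are held out); a strict mode that
also removes them from Ã is available (`strict_holdout`).

Determinism: everything is float64 numpy on a seeded generator stream;
two runs with the same seed produce bit-identical fold metrics.

## Synthetic benchmark

The generator plants a block structure: diseases and miRNAs are assigned
to contiguous near-equal blocks; a matched pair links with probability
p_in, an unmatched pair with p_out; similarity matrices are
sim_signal·(block indicator) + (1−sim_signal)·|N(0, noise_sd)|, clipped,
symmetrized, unit diagonal, with a sim_zero_frac fraction of entries
zeroed so the GIP-completion branch always has work.  Defaults: 100+100
nodes, 4 blocks, p_in 0.5, p_out 0.02, sim_signal 0.7, noise_sd 0.2,
sim_zero_frac 0.3.

What it emulates: the bipartite topology, block-correlated similarities,
sparse curated matrices, and a learnable link signal with an exact
ground truth in degenerate settings (p_in = 1, p_out = 0 gives a block
diagonal).  What it does not emulate: the heavy-tailed degree
distribution of curated association databases, miRNA sequence or
expression, and name-matching noise.  The degree point matters — see
Limitations.

Scaled-down run settings used for synthetic experiments (the package's
own choice of problem sizes): Adam lr 1e−3 (the reference 5e−5 targets
the much larger curated graph trained far longer), at most 150 epochs
for headline runs and 60–100 for multi-seed comparisons, and a shortened
node2vec schedule (10 walks × 40 steps, 200 optimizer iterations).

## Known limitations

**The additive ranking ceiling.**  The scoring head is linear in the
concatenated pair vector, so every test-pair score decomposes as
f(d) + g(m) for per-node scalars — no matter what the upstream network
computes.  An additive ranking can only exploit per-node propensity
signals (degree, popularity).  On curated databases, whose degree
distributions are heavy-tailed, that signal is strong.  On the
degree-homogeneous planted-block benchmark it is almost absent, so
held-out AUC sits near chance even though the data are perfectly
learnable by interaction-capable models; the acceptance script reports
exactly this.  Users who need block-matching behavior on homogeneous
data would have to replace the read-out with an interactive one
(bilinear or MLP), which this package intentionally does not do.

**Null behavior is slightly above 0.5.**  With p_in = p_out there is no
block signal, yet the measured AUC exceeds 0.5 by a few points: realized
node degrees vary binomially, a node's training labels predict its
test-positive count, and (in the default mode) test edges contribute to
graph degree.  Both effects feed the additive scorer.  The strict
holdout mode removes the second effect only.

**Transductive leakage by design.**  GIP kernels, node2vec embeddings
and the default message-passing graph are all built from the full
association table.  This matches the stated protocol of this family of
methods, but it means fold metrics measure transductive completion, not
inductive generalization to unseen nodes.

**Selection diagnostics depend on the counting rule.**  With a hard
Top-K the mask-based "orders selected per layer" is K by construction;
counting only retained orders whose gate exceeds 0.5 can be far lower
when the order weights sit near the threshold.  Both counts are
exported.

## Constants

| constant | value | where | why |
|---|---|---|---|
| ε (variance floor) | 1e−6 | stabilization | keeps s > 0 |
| C (clip) | 10 | stabilization | bounds standardized moments before log |
| cancellation floor | 1e−13 (relative) | stabilization | zeroes expansion round-off |
| γ (gate temperature) | 0.1 | gating | soft but decisive gates |
| τ_scale | 2/M_max | threshold net | τ on the softmax-weight scale |
| Gumbel temperature | 1.0 | order sampling | standard soft relaxation |
| BCE clamp | 1e−7 | probability-space loss | finiteness |
| metric threshold | 0.5 | acc/prec/F1 | conventional, configurable |
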