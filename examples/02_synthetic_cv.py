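"""Five-fold cross-validation on a planted-block synthetic dataset.

Generates a small bipartite dataset whose associations concentrate inside
matched disease/miRNA blocks, runs the full pipeline (similarity
integration, graph construction, node2vec, two adaptive moment-convolution
layers, pair scoring) and prints the held-out metrics per fold.
"""

from mirmoment import ModelConfig, SyntheticSpec, holdout_eval, synthetic_embed_config

spec = SyntheticSpec(
    n_diseases=40, n_mirnas=40, n_blocks=4, p_in=0.5, p_out=0.02, seed=1234
)
cfg = ModelConfig(lr=1e-3, epochs=60, seed=1234)
result = holdout_eval(spec, cfg, embed=synthetic_embed_config())

print("fold   auc    aupr   acc    prec   f1")
for f in result.folds:
    m = f.metrics
    print(
        f"{f.fold_index}    {m['auc']:.4f} {m['aupr']:.4f} {m['accuracy']:.4f} "
        f"{m['precision']:.4f} {m['f1']:.4f}"
    )
table = result.metric_table()
print("\nmean +/- sd over folds:")
for name, (mean, sd) in table.items():
    print(f"  {name:9s} {mean:.4f} +/- {sd:.4f}")
print(
    "\nNote: the pair scorer is a logistic read-out on concatenated node\n"
    "embeddings, so test-pair scores decompose additively per node; on a\n"
    "degree-homogeneous planted-block design this caps ranking performance\n"
    "near chance regardless of the upstream network (docs/methods.md)."
)
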