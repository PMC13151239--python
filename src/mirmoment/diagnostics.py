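"""Mechanism introspection: which moment orders the model actually uses.

After training, each fold's final deterministic inference pass leaves one
:class:`~mirmoment.layer.LayerState` per layer — order weights, threshold,
gates, Top-K mask and per-node attention.  This module turns those
snapshots into the two standard diagnostics: per-order selection
frequencies across folds and layers, and per-order attention-weight
distributions.

Because the counting rule behind "an order was selected" admits two
readings, both are exported: mask-based (the Top-K mask, always exactly K
ones) and gate-based (gate > 0.5, which can drop a retained-but-suppressed
order and so yields a mean below K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layer import LayerState
from .model import CVResult

__all__ = [
    "SelectionRecord",
    "collect_records",
    "selection_frequency",
    "attention_summary",
    "write_diagnostics",
    "plot_selection",
]


@dataclass
class SelectionRecord:
    """One (fold, layer) snapshot captured at end-of-training inference."""

    fold: int
    layer: int
    order_weights: np.ndarray = field(repr=False)
    gates: np.ndarray = field(repr=False)
    topk_mask: np.ndarray = field(repr=False)
    attention: np.ndarray = field(repr=False)  # (n_nodes, m_max)

    @classmethod
    def from_state(cls, fold: int, layer: int, st: LayerState) -> "SelectionRecord":
        return cls(
            fold=fold,
            layer=layer,
            order_weights=st.order_weights,
            gates=st.gates,
            topk_mask=st.topk_mask,
            attention=st.attention,
        )


def collect_records(result: CVResult) -> list[SelectionRecord]:
    """All (fold, layer) records of a cross-validation run."""
    records = []
    for f in result.folds:
        for layer, st in enumerate(f.layer_states):
            records.append(SelectionRecord.from_state(f.fold_index, layer, st))
    return records


def selection_frequency(
    records: list[SelectionRecord], *, mode: str = "mask"
) -> tuple[np.ndarray, float]:
    """Per-order selection counts and the mean number of selected orders
    per (fold, layer) record.

    ``mode='mask'`` counts the Top-K mask; ``mode='gate'`` counts orders
    whose mask is on *and* whose gate exceeds 0.5.
    """
    if not records:
        raise ValueError("no selection records")
    if mode == "mask":
        sel = np.stack([r.topk_mask for r in records])
    elif mode == "gate":
        sel = np.stack([r.topk_mask * (r.gates > 0.5) for r in records])
    else:
        raise ValueError(f"mode must be 'mask' or 'gate', got {mode!r}")
    counts = sel.sum(axis=0)
    return counts, float(sel.sum() / len(records))


def attention_summary(records: list[SelectionRecord]) -> pd.DataFrame:
    """Median/IQR of per-node attention weights per (layer, order).

    Pools nodes across folds of the same layer.  Orders masked in every
    contributing record report exactly 0 for all quantiles.
    """
    if not records:
        raise ValueError("no selection records")
    rows = []
    layers = sorted({r.layer for r in records})
    for layer in layers:
        attn = np.concatenate(
            [r.attention for r in records if r.layer == layer], axis=0
        )
        for k in range(attn.shape[1]):
            col = attn[:, k]
            rows.append(
                {
                    "layer": layer,
                    "order": k + 1,
                    "q25": float(np.quantile(col, 0.25)),
                    "median": float(np.quantile(col, 0.5)),
                    "q75": float(np.quantile(col, 0.75)),
                    "mean": float(col.mean()),
                }
            )
    return pd.DataFrame(rows)


def write_diagnostics(records: list[SelectionRecord], out_dir) -> None:
    """TSV exports: order-frequency table and attention-quantile table."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m_max = len(records[0].topk_mask)
    freq_rows = {"order": np.arange(1, m_max + 1)}
    for mode in ("mask", "gate"):
        counts, mean_sel = selection_frequency(records, mode=mode)
        freq_rows[f"count_{mode}"] = counts.astype(int)
    pd.DataFrame(freq_rows).to_csv(out / "order_frequency.tsv", sep="\t", index=False)
    attention_summary(records).to_csv(
        out / "attention_quantiles.tsv", sep="\t", index=False
    )


def plot_selection(records: list[SelectionRecord], path) -> None:
    """Optional bar plot of per-order selection counts (mask-based)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts, mean_sel = selection_frequency(records)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(np.arange(1, len(counts) + 1), counts, color="#d4803b")
    ax.set_xlabel("moment order")
    ax.set_ylabel("times selected")
    ax.set_title(f"order selection across folds/layers (mean {mean_sel:.1f}/layer)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
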