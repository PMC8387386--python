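"""Attention-map extraction and mean-aggregation for the per-base model.

For each queried substrate position, the output block's position-attention
layer yields a probability distribution over the 20 protospacer positions.
Averaging those distributions over test sequences *predicted to be edited*
at the queried position surfaces which positions (typically the target base
and its flanks) the model relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .perbase import PerBaseModel, encode_sequences
from .seqcore import PROTOSPACER_LEN, ProtospacerRecord, substrate_positions


@dataclass
class AttentionMap:
    """Mean position-attention rows per queried substrate position."""

    rows: dict[int, np.ndarray]           # queried position -> 20-vector, sums to 1
    n_sequences: dict[int, int]           # sequences aggregated per row
    threshold: float
    missing_positions: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {p: self.rows[p] for p in sorted(self.rows)},
            index=[f"pos{i}" for i in range(1, PROTOSPACER_LEN + 1)],
        ).T
        df.insert(0, "n", [self.n_sequences[p] for p in sorted(self.rows)])
        df.index.name = "queried_position"
        return df


def aggregate_attention(
    model: PerBaseModel,
    records: list[ProtospacerRecord],
    position: int,
    threshold: float = 0.5,
) -> tuple[np.ndarray | None, int]:
    """Mean attention row for one queried position over qualifying sequences.

    A sequence qualifies when it carries the substrate base at ``position``
    and the model's score there is >= ``threshold`` ("predicted to be
    edited"). Returns (mean 20-vector or None, number of sequences used).
    """
    if not model.trained:
        raise ValueError("model is not trained")
    qualifying = [r for r in records
                  if position in substrate_positions(r, model.editor)]
    if not qualifying:
        return None, 0
    probs, attn = model.predict_scores(
        encode_sequences([r.sequence for r in qualifying])
    )
    keep = probs[:, position - 1] >= threshold
    if not keep.any():
        return None, 0
    return attn[keep, position - 1].mean(axis=0), int(keep.sum())


def attention_report(
    model: PerBaseModel,
    records: list[ProtospacerRecord],
    threshold: float = 0.5,
) -> tuple[AttentionMap, float]:
    """Aggregated attention rows for every substrate position, plus flank focus.

    The summary statistic is the mean total attention weight on the queried
    position and its immediate neighbours {p-1, p, p+1} (clipped at the
    protospacer boundaries), averaged over rows; a uniform attention model
    yields 3/20 at interior positions.
    """
    rows: dict[int, np.ndarray] = {}
    ns: dict[int, int] = {}
    missing: list[int] = []
    for p in range(1, PROTOSPACER_LEN + 1):
        row, n = aggregate_attention(model, records, p, threshold)
        if row is None:
            missing.append(p)
        else:
            rows[p] = row
            ns[p] = n
    focus = []
    for p, row in rows.items():
        window = [q for q in (p - 1, p, p + 1) if 1 <= q <= PROTOSPACER_LEN]
        focus.append(sum(row[q - 1] for q in window))
    summary = float(np.mean(focus)) if focus else float("nan")
    return AttentionMap(rows, ns, threshold, missing), summary


def plot_attention_heatmap(amap: AttentionMap, path: str) -> None:
    """Companion heatmap figure (queried positions x protospacer positions)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = amap.to_frame()
    mat = df.drop(columns="n").to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(8, 0.4 * max(len(df), 4) + 1.5))
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_xticks(range(PROTOSPACER_LEN),
                  [str(i) for i in range(1, PROTOSPACER_LEN + 1)], fontsize=7)
    ax.set_yticks(range(len(df)),
                  [f"{p} (n={amap.n_sequences[p]})" for p in sorted(amap.rows)],
                  fontsize=7)
    ax.set_xlabel("protospacer position (PAM-distal first)")
    ax.set_ylabel("queried substrate position")
    fig.colorbar(im, ax=ax, label="mean attention weight")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
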