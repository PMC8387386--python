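"""Shared test builders (imported by test modules and conftest)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from bescreen.perbase import ModelConfig
from bescreen.screen_proc import PerBaseDataset
from bescreen.seqcore import ProtospacerRecord

TINY = ModelConfig(embedding_dim=16, n_heads=2, n_encoder_layers=1,
                   feedforward_dim=32, dropout_rate=0.0, learning_rate=2e-3,
                   batch_size=128, max_epochs=60, early_stop_patience=10, seed=5)


def rule_dataset(n, seed, shuffle_labels=False, permissive_prev="T"):
    """Separable fixture: a base is edited iff position in {5,6,7} and the
    preceding base is in ``permissive_prev``.

    Widening the permissive set raises the marginal truth probability at the
    window positions from 1/4 toward 1 while keeping labels a deterministic
    function of the sequence (used for the calibration-direction check).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    rows, records = [], {}
    for i in range(n):
        seq = "".join(bases[rng.integers(0, 4, size=20)])
        tid = f"s{i}"
        records[tid] = ProtospacerRecord(tid, seq, "AGG")
        for p in range(1, 21):
            if seq[p - 1] != "A":
                continue
            lab = int(p in (5, 6, 7) and seq[p - 2] in permissive_prev)
            rows.append({"target_id": tid, "position": p, "label": lab})
    examples = pd.DataFrame(rows)
    if shuffle_labels:
        examples["label"] = rng.permutation(examples["label"].to_numpy())
    ids = list(records)
    n_train = int(0.8 * len(ids))
    n_test = (len(ids) - n_train) // 2
    col = pd.Series(
        ["train"] * n_train + ["test"] * n_test
        + ["validation"] * (len(ids) - n_train - n_test),
        index=ids, name="run0",
    )
    return PerBaseDataset(records=records, examples=examples,
                          splits=col.to_frame(), run_seeds=[seed],
                          mean_efficiency=4.0)
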