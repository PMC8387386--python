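"""Per-base editing classifier: embeddings + Transformer encoder + position attention.

The model takes the 20-nt protospacer, embeds nucleotide identity and
position, passes the embeddings through a stack of multi-head self-attention
encoder layers (residual connections + layer normalization + position-wise
feed-forward), and scores each substrate position with an output block: a
position-attention layer builds, for each queried position, a distribution
over the 20 contextual vectors (query = projected positional embedding of
the queried position), forms a context vector, and a logistic classifier
maps it to the probability that the base is edited.

Training minimizes binary cross-entropy at substrate positions only, with
early stopping on validation AUPR. A per-position Bernoulli maximum-
likelihood majority-class predictor serves as the reference baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

from . import nn
from .seqcore import BASE_INDEX, PROTOSPACER_LEN, EditorSpec, ProtospacerRecord, substrate_positions
from .screen_proc import PerBaseDataset


@dataclass
class ModelConfig:
    """Architecture and optimization constants for the attention models."""

    embedding_dim: int = 64
    n_heads: int = 8
    n_encoder_layers: int = 2
    feedforward_dim: int = 128
    dropout_rate: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 100
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim % self.n_heads:
            raise ValueError("embedding_dim must be divisible by n_heads")
        for name in ("embedding_dim", "n_heads", "n_encoder_layers",
                     "feedforward_dim", "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def encode_sequences(seqs: list[str]) -> np.ndarray:
    """ACGT strings -> (N, 20) integer index array (A=0, C=1, G=2, T=3)."""
    arr = np.zeros((len(seqs), PROTOSPACER_LEN), dtype=np.int64)
    for i, s in enumerate(seqs):
        if len(s) != PROTOSPACER_LEN:
            raise ValueError(f"sequence {i} is not {PROTOSPACER_LEN} nt")
        try:
            arr[i] = [BASE_INDEX[b] for b in s]
        except KeyError as e:
            raise ValueError(f"non-ACGT symbol {e} in sequence {i}") from e
    return arr


class PerBaseModel:
    """The trainable per-base classifier (see module docstring)."""

    def __init__(self, config: ModelConfig, editor: EditorSpec):
        self.config = config
        self.editor = editor
        self.trained = False
        rng = np.random.default_rng(config.seed % (2**31))
        D = config.embedding_dim
        self.nuc_embed = nn.Tensor(rng.normal(0, 0.5, size=(4, D)))
        self.pos_embed = nn.Tensor(rng.normal(0, 0.5, size=(PROTOSPACER_LEN, D)))
        self.encoder = [
            nn.EncoderLayer(D, config.n_heads, config.feedforward_dim, rng)
            for _ in range(config.n_encoder_layers)
        ]
        # output block: single-head position attention + logistic classifier
        self.out_q = nn.Linear(D, D, rng)
        self.out_k = nn.Linear(D, D, rng)
        self.out_v = nn.Linear(D, D, rng)
        self.classifier = nn.Linear(D, 1, rng)
        self._drop_rng = np.random.default_rng((config.seed + 1) % (2**31))

    @property
    def params(self) -> list[nn.Tensor]:
        ps = [self.nuc_embed, self.pos_embed]
        for layer in self.encoder:
            ps.extend(layer.params)
        ps.extend([*self.out_q.params, *self.out_k.params, *self.out_v.params,
                   *self.classifier.params])
        return ps

    def embed(self, idx: np.ndarray) -> nn.Tensor:
        """Nucleotide embedding + positional embedding, per slot."""
        return nn.embedding(self.nuc_embed, idx) + self.pos_embed

    def forward(
        self, idx: np.ndarray, training: bool = False
    ) -> tuple[nn.Tensor, np.ndarray, list[np.ndarray]]:
        """Logits (B, 20), position-attention maps (B, 20, 20), encoder maps."""
        cfg = self.config
        x = self.embed(idx)
        enc_maps: list[np.ndarray] = []
        for layer in self.encoder:
            x, amap = layer(x, self._drop_rng, cfg.dropout_rate, training)
            enc_maps.append(amap)
        D = cfg.embedding_dim
        q = self.out_q(self.pos_embed)                      # (20, D)
        k = self.out_k(x)                                   # (B, 20, D)
        v = self.out_v(x)
        scores = (q @ k.transpose(0, 2, 1)).scale(1.0 / np.sqrt(D))  # (B, 20, 20)
        attn = nn.softmax(scores)
        ctx = (attn @ v) + x        # residual: queried slot's own contextual vector
        logits = self.classifier(ctx).reshape(idx.shape[0], PROTOSPACER_LEN)
        return logits, attn.data, enc_maps

    def predict_scores(self, idx: np.ndarray, batch: int = 512) -> tuple[np.ndarray, np.ndarray]:
        """Per-position probabilities (N, 20) and attention maps (N, 20, 20)."""
        probs, attns = [], []
        for i in range(0, len(idx), batch):
            logits, attn, _ = self.forward(idx[i : i + batch], training=False)
            probs.append(1.0 / (1.0 + np.exp(-logits.data)))
            attns.append(attn)
        return np.concatenate(probs), np.concatenate(attns)


@dataclass
class PerBasePrediction:
    """Probability score and attention distribution per substrate position."""

    target_id: str
    scores: dict[int, float]
    attention: dict[int, np.ndarray]


def predict_perbase(
    model: PerBaseModel, record: ProtospacerRecord, editor: EditorSpec | None = None
) -> PerBasePrediction:
    """Score every substrate position of one protospacer with a trained model."""
    if not model.trained:
        raise ValueError("model is not trained")
    editor = editor or model.editor
    if editor.substrate != model.editor.substrate:
        raise ValueError("editor does not match the model's training editor")
    positions = substrate_positions(record, editor)
    if not positions:
        return PerBasePrediction(record.id, {}, {})
    probs, attn = model.predict_scores(encode_sequences([record.sequence]))
    return PerBasePrediction(
        record.id,
        {p: float(probs[0, p - 1]) for p in positions},
        {p: attn[0, p - 1].copy() for p in positions},
    )


def dataset_arrays(
    dataset: PerBaseDataset, run: int, split: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """(X indices, labels, label mask, target ids) for one split of one run."""
    ids = dataset.split_ids(run, split)
    idset = set(ids)
    seqs = [dataset.records[t].sequence for t in ids]
    X = encode_sequences(seqs)
    row = {t: i for i, t in enumerate(ids)}
    Y = np.zeros((len(ids), PROTOSPACER_LEN))
    M = np.zeros((len(ids), PROTOSPACER_LEN))
    ex = dataset.examples
    for t, p, lab in zip(ex["target_id"], ex["position"], ex["label"]):
        if t in idset:
            Y[row[t], p - 1] = lab
            M[row[t], p - 1] = 1.0
    return X, Y, M, ids


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_aupr: float = float("nan")


def train_perbase(
    dataset: PerBaseDataset, config: ModelConfig, run: int = 0
) -> tuple[PerBaseModel, TrainingLog]:
    """Fit the per-base model on one run's train split.

    Binary cross-entropy at substrate (labelled) positions only; early
    stopping on validation AUPR with the configured patience; deterministic
    under config.seed + run.
    """
    Xtr, Ytr, Mtr, _ = dataset_arrays(dataset, run, "train")
    Xva, Yva, Mva, _ = dataset_arrays(dataset, run, "validation")
    if Ytr[Mtr > 0].min() == Ytr[Mtr > 0].max():
        raise ValueError("training split contains a single class")
    run_cfg = ModelConfig(**{**asdict(config), "seed": config.seed + 7919 * run})
    model = PerBaseModel(run_cfg, dataset_editor(dataset))
    opt = nn.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng((config.seed + 104729 * run) % (2**31))
    log = TrainingLog()
    best: list[np.ndarray] | None = None
    patience = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        tot, nb = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            b = order[i : i + config.batch_size]
            if Mtr[b].sum() == 0:
                continue
            opt.zero_grad()
            logits, _, _ = model.forward(Xtr[b], training=True)
            loss = nn.bce_with_logits(logits, Ytr[b], Mtr[b])
            loss.backward()
            opt.step()
            tot += float(loss.data)
            nb += 1
        probs, _ = model.predict_scores(Xva)
        val_aupr = float(average_precision_score(Yva[Mva > 0], probs[Mva > 0]))
        log.epochs.append({"epoch": epoch, "train_loss": tot / max(nb, 1),
                           "val_aupr": val_aupr})
        if not np.isfinite(log.best_val_aupr) or val_aupr > log.best_val_aupr:
            log.best_val_aupr = val_aupr
            log.best_epoch = epoch
            best = [p.data.copy() for p in model.params]
            patience = 0
        else:
            patience += 1
            if patience >= config.early_stop_patience:
                break
    if best is not None:
        for p, w in zip(model.params, best):
            p.data = w
    model.trained = True
    return model, log


def dataset_editor(dataset: PerBaseDataset) -> EditorSpec:
    """Infer the editor class from the dataset's labelled positions."""
    from .seqcore import ABE, CBE

    ex = dataset.examples.iloc[0]
    base = dataset.records[ex["target_id"]].sequence[int(ex["position"]) - 1]
    return ABE if base == "A" else CBE


@dataclass
class MajorityBaseline:
    """Per-position Bernoulli MLE predictor (ties predict non-edited)."""

    p_hat: dict[int, float]

    def score(self, position: int) -> float:
        if position not in self.p_hat:
            raise KeyError(f"position {position} had no training example")
        return self.p_hat[position]

    def predict(self, position: int) -> int:
        return int(self.score(position) > 0.5)


def majority_baseline(dataset: PerBaseDataset, run: int = 0) -> MajorityBaseline:
    """Fit the baseline on one run's train split: p̂(pos) = edited fraction."""
    _, Y, M, _ = dataset_arrays(dataset, run, "train")
    p_hat = {}
    for p in range(PROTOSPACER_LEN):
        m = M[:, p] > 0
        if m.any():
            p_hat[p + 1] = float(Y[m, p].mean())
    return MajorityBaseline(p_hat)


@dataclass
class EvalReport:
    """Per-run AUC/AUPR and per-position accuracy vs the majority baseline."""

    per_run: pd.DataFrame           # run, auc, aupr
    per_position: pd.DataFrame      # position, model_acc_mean/std, baseline_acc_mean, balanced, n_test
    mean_roc: pd.DataFrame          # fpr grid (101 points), mean interpolated tpr
    balanced_min_fraction: float


def evaluate(
    models: Mapping[int, PerBaseModel],
    dataset: PerBaseDataset,
    balanced_min_fraction: float = 0.2,
    split: str = "test",
) -> EvalReport:
    """AUC, AUPR and per-position accuracy across runs on the test splits.

    ROC curves are averaged across runs by interpolating the true-positive
    rate on a fixed 101-point false-positive-rate grid. Per-position
    accuracy is compared with the majority baseline; a position is flagged
    "balanced" when its minority class holds at least
    ``balanced_min_fraction`` of that position's test examples (pooled over
    runs). Positions whose test split has a single class get NaN accuracy.
    """
    runs = sorted(models)
    fpr_grid = np.linspace(0.0, 1.0, 101)
    tprs, run_rows = [], []
    pos_acc = {p: [] for p in range(1, PROTOSPACER_LEN + 1)}
    base_acc = {p: [] for p in range(1, PROTOSPACER_LEN + 1)}
    pos_labels: dict[int, list[np.ndarray]] = {p: [] for p in range(1, PROTOSPACER_LEN + 1)}
    for run in runs:
        X, Y, M, _ = dataset_arrays(dataset, run, split)
        probs, _ = models[run].predict_scores(X)
        y, s = Y[M > 0], probs[M > 0]
        if y.min() == y.max():
            run_rows.append({"run": run, "auc": float("nan"), "aupr": float("nan")})
        else:
            run_rows.append({"run": run, "auc": float(roc_auc_score(y, s)),
                             "aupr": float(average_precision_score(y, s))})
            fpr, tpr, _ = roc_curve(y, s)
            tprs.append(np.interp(fpr_grid, fpr, tpr))
        baseline = majority_baseline(dataset, run)
        for p in range(1, PROTOSPACER_LEN + 1):
            m = M[:, p - 1] > 0
            if not m.any() or p not in baseline.p_hat:
                continue
            yy = Y[m, p - 1]
            pos_labels[p].append(yy)
            pos_acc[p].append(float(((probs[m, p - 1] >= 0.5) == yy).mean()))
            base_acc[p].append(float((baseline.predict(p) == yy).mean()))
    pos_rows = []
    for p in range(1, PROTOSPACER_LEN + 1):
        if not pos_acc[p]:
            continue
        labels = np.concatenate(pos_labels[p])
        minority = min(labels.mean(), 1 - labels.mean())
        pos_rows.append({
            "position": p,
            "model_acc_mean": float(np.mean(pos_acc[p])),
            "model_acc_std": float(np.std(pos_acc[p])),
            "baseline_acc_mean": float(np.mean(base_acc[p])),
            "balanced": bool(minority >= balanced_min_fraction),
            "n_test": int(labels.size),
        })
    mean_roc = pd.DataFrame({
        "fpr": fpr_grid,
        "tpr_mean": np.mean(tprs, axis=0) if tprs else np.full(101, np.nan),
    })
    return EvalReport(
        per_run=pd.DataFrame(run_rows),
        per_position=pd.DataFrame(pos_rows),
        mean_roc=mean_roc,
        balanced_min_fraction=balanced_min_fraction,
    )


def save_model(model: PerBaseModel, path: str) -> None:
    """Single-file checkpoint: config + editor + weights (npz)."""
    meta = json.dumps({
        "config": asdict(model.config),
        "editor": {"name": model.editor.name, "substrate": model.editor.substrate,
                   "product": model.editor.product},
        "trained": model.trained,
        "kind": "perbase",
    })
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
             **{f"p{i}": p.data for i, p in enumerate(model.params)})


def load_model(path: str) -> PerBaseModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        model = PerBaseModel(ModelConfig(**meta["config"]), EditorSpec(**meta["editor"]))
        for i, p in enumerate(model.params):
            p.data = z[f"p{i}"].copy()
    model.trained = meta["trained"]
    return model
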