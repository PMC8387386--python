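"""Outcome-distribution ("bystander") model: encoder–decoder over editing outcomes.

The per-base classifier scores marginal editing probabilities; it cannot
capture co-occurrence of target and bystander edits. This module models the
full distribution over outcome sequences instead. An encoder (same blocks
as the per-base model) computes contextual vectors for the 20-nt
protospacer; a decoder with masked (causal) self-attention and
cross-attention to the encoder emits, slot by slot from the PAM-distal end,
a two-way conditional — substrate retained vs converted — at each substrate
position (non-substrate slots are forced identity). The probability of an
outcome sequence is the chain product of these conditionals, so the
distribution over all 2^k canonical outcomes (k = number of substrate
bases) is normalized by construction; predictions are renormalized over the
enumerated (possibly beam-truncated) set before being reported.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .perbase import ModelConfig, encode_sequences
from .seqcore import (
    BASE_INDEX,
    PROTOSPACER_LEN,
    EditorSpec,
    ProtospacerRecord,
    canonical_outcome_ok,
    substrate_positions,
)
from .screen_proc import TargetCounts

_BOS = 4  # decoder start token (vocabulary: A,C,G,T,BOS)


def enumerate_outcomes(
    protospacer: str, editor: EditorSpec, cap: int = 4096
) -> tuple[list[str], bool]:
    """All canonical-transition outcome sequences of a protospacer.

    Returns the 2^k outcomes (k = substrate positions) in canonical order —
    lexicographic by edited-position set, wild type first — when 2^k <= cap.
    Beyond the cap the list is truncated to the lexicographically first
    ``cap`` edit sets and the truncation flag is set (model-guided beam
    restriction lives in :func:`predict_distribution`).
    """
    positions = [i + 1 for i, b in enumerate(protospacer) if b == editor.substrate]
    k = len(positions)
    truncated = 2**k > cap

    sets: list[tuple[int, ...]] = []

    def grow(prefix: tuple[int, ...], start: int) -> None:
        if len(sets) >= cap and truncated:
            return
        sets.append(prefix)
        for j in range(start, k):
            grow(prefix + (positions[j],), j + 1)

    grow((), 0)
    outcomes = []
    for s in sets[: cap if truncated else None]:
        seq = list(protospacer)
        for p in s:
            seq[p - 1] = editor.product
        outcomes.append("".join(seq))
    return outcomes, truncated


@dataclass
class OutcomeDistribution:
    """Normalized probabilities over canonical outcome sequences of one target."""

    protospacer: ProtospacerRecord
    outcomes: list[tuple[str, float]]
    mode: Literal["all", "edited"]
    truncated: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(self.outcomes)

    def implied_marginals(self, editor: EditorSpec) -> dict[int, float]:
        """Per-substrate-position edit probability implied by the distribution."""
        out = {p: 0.0 for p in substrate_positions(self.protospacer, editor)}
        for seq, prob in self.outcomes:
            for p in out:
                if seq[p - 1] == editor.product:
                    out[p] += prob
        return out


class BystanderModel:
    """Encoder–decoder over canonical editing outcomes (see module docstring)."""

    def __init__(self, config: ModelConfig, editor: EditorSpec):
        self.config = config
        self.editor = editor
        self.trained = False
        rng = np.random.default_rng((config.seed + 17) % (2**31))
        D = config.embedding_dim
        self.nuc_embed = nn.Tensor(rng.normal(0, 0.5, size=(4, D)))
        self.pos_embed = nn.Tensor(rng.normal(0, 0.5, size=(PROTOSPACER_LEN, D)))
        self.encoder = [
            nn.EncoderLayer(D, config.n_heads, config.feedforward_dim, rng)
            for _ in range(config.n_encoder_layers)
        ]
        self.tok_embed = nn.Tensor(rng.normal(0, 0.5, size=(5, D)))
        self.dec_pos_embed = nn.Tensor(rng.normal(0, 0.5, size=(PROTOSPACER_LEN, D)))
        self.decoder = [
            nn.DecoderLayer(D, config.n_heads, config.feedforward_dim, rng)
            for _ in range(config.n_encoder_layers)
        ]
        self.head = nn.Linear(D, 2, rng)  # classes: 0 = retain, 1 = convert
        self._mask = nn.causal_mask(PROTOSPACER_LEN)
        self._drop_rng = np.random.default_rng((config.seed + 18) % (2**31))

    @property
    def params(self) -> list[nn.Tensor]:
        ps = [self.nuc_embed, self.pos_embed]
        for layer in self.encoder:
            ps.extend(layer.params)
        ps.extend([self.tok_embed, self.dec_pos_embed])
        for layer in self.decoder:
            ps.extend(layer.params)
        ps.extend(self.head.params)
        return ps

    def encode(self, idx: np.ndarray, training: bool = False) -> nn.Tensor:
        x = nn.embedding(self.nuc_embed, idx) + self.pos_embed
        for layer in self.encoder:
            x, _ = layer(x, self._drop_rng, self.config.dropout_rate, training)
        return x

    def decode_logits(
        self, enc: nn.Tensor, dec_in: np.ndarray, training: bool = False
    ) -> nn.Tensor:
        """Two-way conditional logits (B, 20, 2) given shifted outcome tokens."""
        x = nn.embedding(self.tok_embed, dec_in) + self.dec_pos_embed
        for layer in self.decoder:
            x, _ = layer(x, enc, self._mask, self._drop_rng,
                         self.config.dropout_rate, training)
        return self.head(x)

    # -- scoring -----------------------------------------------------------
    def _rows(
        self, protospacer: str, outcomes: list[str]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(encoder idx, decoder input, target classes, substrate mask) per outcome."""
        n = len(outcomes)
        enc_idx = np.repeat(encode_sequences([protospacer]), n, axis=0)
        out_idx = encode_sequences(outcomes)
        dec_in = np.concatenate(
            [np.full((n, 1), _BOS, dtype=np.int64), out_idx[:, :-1]], axis=1
        )
        proto_idx = encode_sequences([protospacer])[0]
        sub_mask = np.repeat(
            (proto_idx == BASE_INDEX[self.editor.substrate])[None, :].astype(float),
            n, axis=0,
        )
        targets = (out_idx != proto_idx[None, :]).astype(np.int64)
        return enc_idx, dec_in, targets, sub_mask

    def log_scores(self, protospacer: str, outcomes: list[str], batch: int = 1024) -> np.ndarray:
        """Chain-product log probability of each outcome sequence."""
        for o in outcomes:
            if not canonical_outcome_ok(protospacer, o, self.editor):
                raise ValueError(f"outcome {o!r} not reachable by canonical transitions")
        enc_idx, dec_in, targets, sub_mask = self._rows(protospacer, outcomes)
        out = np.empty(len(outcomes))
        for i in range(0, len(outcomes), batch):
            sl = slice(i, i + batch)
            enc = self.encode(enc_idx[sl])
            logits = self.decode_logits(enc, dec_in[sl]).data
            logp = logits - np.log(np.exp(logits - logits.max(-1, keepdims=True))
                                   .sum(-1, keepdims=True)) - logits.max(-1, keepdims=True)
            picked = np.take_along_axis(logp, targets[sl][..., None], axis=-1)[..., 0]
            out[sl] = (picked * sub_mask[sl]).sum(axis=1)  # forced identity off-substrate
        return out


def decode_score(model: BystanderModel, record: ProtospacerRecord, outcome: str) -> float:
    """Probability contribution of one outcome sequence (chain product)."""
    if not model.trained:
        raise ValueError("model is not trained")
    return float(np.exp(model.log_scores(record.sequence, [outcome])[0]))


def _beam_outcomes(
    model: BystanderModel, protospacer: str, beam_width: int, cap: int
) -> list[str]:
    """Model-guided beam over substrate positions for poly-substrate targets."""
    positions = [i + 1 for i, b in enumerate(protospacer)
                 if b == model.editor.substrate]
    beams = [protospacer]
    for p in positions:
        cands = set(beams)
        for seq in beams:
            edited = seq[: p - 1] + model.editor.product + seq[p:]
            cands.add(edited)
        cand_list = sorted(cands)
        lp = model.log_scores(protospacer, cand_list)
        order = np.argsort(lp)[::-1][:beam_width]
        beams = [cand_list[i] for i in order]
    return sorted(beams[:cap])


def predict_distribution(
    model: BystanderModel,
    record: ProtospacerRecord,
    mode: Literal["all", "edited"] = "all",
    cap: int = 4096,
    beam_width: int = 256,
) -> OutcomeDistribution:
    """Normalized outcome distribution for one protospacer.

    Full enumeration when 2^k <= cap, otherwise a model-guided beam over
    substrate positions (truncation flagged; normalization is then over the
    retained set). Edited-only mode drops the wild type before
    renormalizing, i.e. conditions the distribution on a non-wild-type read.
    """
    if not model.trained:
        raise ValueError("model is not trained")
    spacer = record.sequence
    k = spacer.count(model.editor.substrate)
    if 2**k <= cap:
        outcomes, truncated = enumerate_outcomes(spacer, model.editor, cap)
    else:
        outcomes, truncated = _beam_outcomes(model, spacer, beam_width, cap), True
    if mode == "edited":
        outcomes = [o for o in outcomes if o != spacer]
        if not outcomes:
            raise ValueError("edited-only mode needs at least one substrate base")
    lp = model.log_scores(spacer, outcomes)
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    return OutcomeDistribution(
        protospacer=record,
        outcomes=list(zip(outcomes, probs.tolist())),
        mode=mode,
        truncated=truncated,
    )


# --------------------------------------------------------------------------
# empirical tables and training


def empirical_outcome_table(
    counts: Iterable[TargetCounts], mode: Literal["all", "edited"] = "all",
    min_count: int = 1,
) -> pd.DataFrame:
    """Observed outcome frequencies per target, normalized per mode.

    Columns: target_id, outcome_sequence, count, frequency, depth. In
    edited-only mode wild-type reads are dropped before normalization.
    Frequencies are computed over all reads in the mode; rows with fewer
    than ``min_count`` reads are then dropped (a training-time noise trim),
    so with min_count > 1 the retained frequencies may sum below 1.
    """
    rows = []
    for tc in counts:
        wt = tc.record.sequence
        items = [(o, n) for o, n in tc.outcome_counts.items()
                 if mode == "all" or o != wt]
        total = sum(n for _, n in items)
        if total == 0:
            continue
        for o, n in items:
            if n < min_count:
                continue
            rows.append({"target_id": tc.target_id, "outcome_sequence": o,
                         "count": n, "frequency": n / total, "depth": tc.total_reads})
    return pd.DataFrame(rows, columns=["target_id", "outcome_sequence", "count",
                                       "frequency", "depth"])


def split_targets(
    ids: list[str], seed: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> dict[str, list[str]]:
    """Deterministic 8:1:1 target-level split into train/test/validation."""
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2**31), 811]))
    order = list(ids)
    rng.shuffle(order)
    n = len(order)
    n_train = int(round(fractions[0] * n))
    n_test = int(round(fractions[1] * n))
    return {
        "train": sorted(order[:n_train]),
        "test": sorted(order[n_train : n_train + n_test]),
        "validation": sorted(order[n_train + n_test :]),
    }


def train_bystander(
    table: pd.DataFrame,
    records: Mapping[str, ProtospacerRecord],
    config: ModelConfig,
    editor: EditorSpec,
    splits: dict[str, list[str]] | None = None,
    depth_weighting: bool = True,
) -> tuple[BystanderModel, dict]:
    """Fit the outcome-distribution model on an empirical outcome table.

    Minimizes the cross-entropy between predicted chain probabilities and
    empirical outcome frequencies; each (target, outcome) row is weighted by
    its frequency times, when ``depth_weighting``, log10 of the target's
    read depth (damps shallow-target noise). Early stopping monitors the
    weighted negative log-likelihood on the validation targets.
    Deterministic under config.seed.
    """
    if table.empty:
        raise ValueError("empty outcome table")
    ids = sorted(table["target_id"].unique())
    if splits is None:
        splits = split_targets(ids, config.seed)
    model = BystanderModel(config, editor)

    def build_rows(split_ids: list[str]):
        sub = table[table["target_id"].isin(set(split_ids))]
        enc_l, dec_l, tgt_l, msk_l, w_l = [], [], [], [], []
        for tid, grp in sub.groupby("target_id"):
            spacer = records[tid].sequence
            outs = list(grp["outcome_sequence"])
            enc_idx, dec_in, targets, sub_mask = model._rows(spacer, outs)
            w = grp["frequency"].to_numpy(dtype=float)
            if depth_weighting:
                w = w * np.log10(np.maximum(grp["depth"].to_numpy(dtype=float), 10.0))
            enc_l.append(enc_idx); dec_l.append(dec_in)
            tgt_l.append(targets); msk_l.append(sub_mask); w_l.append(w)
        return (np.concatenate(enc_l), np.concatenate(dec_l),
                np.concatenate(tgt_l), np.concatenate(msk_l), np.concatenate(w_l))

    Etr, Dtr, Ttr, Mtr, Wtr = build_rows(splits["train"])
    Eva, Dva, Tva, Mva, Wva = build_rows(splits["validation"])

    def val_nll() -> float:
        tot, nb = 0.0, 0
        for i in range(0, len(Eva), config.batch_size):
            sl = slice(i, i + config.batch_size)
            enc = model.encode(Eva[sl])
            logits = model.decode_logits(enc, Dva[sl])
            loss = nn.weighted_softmax_xent(logits, Tva[sl], Mva[sl],
                                            Wva[sl][:, None])
            w = (Wva[sl][:, None] * Mva[sl]).sum()
            tot += float(loss.data) * w
            nb += w
        return tot / max(nb, 1e-12)

    opt = nn.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng((config.seed + 65537) % (2**31))
    log: dict = {"epochs": [], "splits": splits}
    best, best_nll, patience = None, float("inf"), 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Etr))
        tot, nb = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            b = order[i : i + config.batch_size]
            opt.zero_grad()
            enc = model.encode(Etr[b], training=True)
            logits = model.decode_logits(enc, Dtr[b], training=True)
            loss = nn.weighted_softmax_xent(logits, Ttr[b], Mtr[b], Wtr[b][:, None])
            loss.backward()
            opt.step()
            tot += float(loss.data)
            nb += 1
        nll = val_nll()
        log["epochs"].append({"epoch": epoch, "train_loss": tot / max(nb, 1),
                              "val_nll": nll})
        if nll < best_nll - 1e-6:
            best_nll, patience = nll, 0
            best = [p.data.copy() for p in model.params]
        else:
            patience += 1
            if patience >= config.early_stop_patience:
                break
    if best is not None:
        for p, w in zip(model.params, best):
            p.data = w
    model.trained = True
    log["best_val_nll"] = best_nll
    return model, log


def predicted_vs_empirical(
    model: BystanderModel,
    table: pd.DataFrame,
    records: Mapping[str, ProtospacerRecord],
    ids: Iterable[str],
    mode: Literal["all", "edited"] = "all",
    cap: int = 4096,
) -> pd.DataFrame:
    """Matched (target, outcome) pairs: predicted probability vs observed frequency."""
    rows = []
    idset = set(ids)
    for tid, grp in table.groupby("target_id"):
        if tid not in idset:
            continue
        rec = records[tid]
        if mode == "edited" and rec.sequence.count(model.editor.substrate) == 0:
            continue
        pred = predict_distribution(model, rec, mode=mode, cap=cap).as_dict()
        for o, f in zip(grp["outcome_sequence"], grp["frequency"]):
            rows.append({"target_id": tid, "outcome_sequence": o,
                         "observed": float(f), "predicted": pred.get(o, 0.0)})
    return pd.DataFrame(rows, columns=["target_id", "outcome_sequence",
                                       "observed", "predicted"])


def marginal_consistency(
    bystander_model: BystanderModel,
    perbase_model,
    record: ProtospacerRecord,
    cap: int = 4096,
) -> pd.DataFrame:
    """Diagnostic: bystander-implied marginals vs per-base scores, per position.

    The two models need not agree — the per-base classifier scores
    dichotomized labels and cannot represent co-occurrence — so this is
    emitted for inspection, not asserted.
    """
    from .perbase import predict_perbase

    dist = predict_distribution(bystander_model, record, mode="all", cap=cap)
    implied = dist.implied_marginals(bystander_model.editor)
    scores = predict_perbase(perbase_model, record).scores
    return pd.DataFrame(
        [{"position": p, "bystander_marginal": implied[p],
          "perbase_score": scores.get(p, float("nan"))}
         for p in sorted(implied)]
    )


def save_model(model: BystanderModel, path: str) -> None:
    """Single-file checkpoint: config + editor + weights (npz)."""
    import json as _json

    meta = _json.dumps({
        "config": asdict(model.config),
        "editor": {"name": model.editor.name, "substrate": model.editor.substrate,
                   "product": model.editor.product},
        "trained": model.trained,
        "kind": "bystander",
    })
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
             **{f"p{i}": p.data for i, p in enumerate(model.params)})


def load_model(path: str) -> BystanderModel:
    import json as _json

    with np.load(path) as z:
        meta = _json.loads(bytes(z["_meta"]).decode())
        model = BystanderModel(ModelConfig(**meta["config"]), EditorSpec(**meta["editor"]))
        for i, p in enumerate(model.params):
            p.data = z[f"p{i}"].copy()
    model.trained = meta["trained"]
    return model


def evaluate_proportions(
    predicted: np.ndarray | pd.Series,
    observed: np.ndarray | pd.Series,
    correlation: Literal["pearson", "spearman"] = "pearson",
) -> dict:
    """Pooled correlation between predicted and observed outcome proportions."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape:
        raise ValueError("predicted/observed shape mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 matched pairs")
    if correlation == "pearson":
        r, p = stats.pearsonr(x, y)
    elif correlation == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation {correlation!r}")
    return {"correlation": correlation, "r": float(r), "p_value": float(p), "n": int(x.size)}
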