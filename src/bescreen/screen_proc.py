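"""Screen quantification: read assignment, efficiencies, filters, datasets.

This is the layer that turns raw screen observations (reads or outcome
counts) into per-position editing efficiencies, filtered locus sets,
dichotomized per-base training examples, per-position activity profiles and
trinucleotide-motif proportion tables.

Conventions (shared package-wide): protospacer positions are 1-based,
PAM-distal first. Editing percentage at a position is
100 x (reads carrying the canonical transition at that position) / total
reads of the target; overall editing percentage is
100 x (non-wild-type reads) / total reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqcore import (
    BARCODE_LEN,
    PROTOSPACER_LEN,
    READ_LEN,
    EditorSpec,
    LibraryMember,
    ProtospacerRecord,
    canonical_outcome_ok,
    edited_positions,
    substrate_positions,
    trinucleotide_context,
)
from .screen_sim import SyntheticScreen

POS_COLS = [f"pos{i}" for i in range(1, PROTOSPACER_LEN + 1)]


@dataclass
class TargetCounts:
    """Observed outcome sequences and read counts for one library member."""

    target_id: str
    record: ProtospacerRecord
    replicate_id: str
    outcome_counts: dict[str, int]

    @property
    def total_reads(self) -> int:
        return sum(self.outcome_counts.values())


@dataclass
class AssignmentResult:
    """Read-assignment output plus per-class drop tallies."""

    counts: list[TargetCounts]
    n_assigned: int = 0
    n_dropped_geometry: int = 0
    n_dropped_unassigned: int = 0
    n_dropped_noncanonical: int = 0


def counts_from_screen(screen: SyntheticScreen) -> list[TargetCounts]:
    """Adapt a simulated screen's count maps into TargetCounts records."""
    by_id = {m.record.id: m.record for m in screen.library}
    out: list[TargetCounts] = []
    for rep, rep_counts in enumerate(screen.counts):
        for tid, oc in rep_counts.items():
            out.append(TargetCounts(tid, by_id[tid], f"rep{rep + 1}", dict(oc)))
    return out


def assign_reads(
    reads: Iterable[str],
    library: list[LibraryMember],
    editor: EditorSpec,
    replicate_id: str = "rep1",
) -> AssignmentResult:
    """Assign reads to library members by exact barcode matching.

    Reads follow the designed amplicon geometry barcode5(6) + target(20) +
    pam(3) + barcode3(6) = 35 bp. A read is located by exact match of both
    barcodes at their designed offsets; its 20-nt target slice is then
    compared with the designed protospacer and kept only when every
    difference is the editor's canonical transition. Reads with wrong
    geometry, unknown barcode pairs, or non-canonical differences are
    dropped and tallied separately.
    """
    pair_index: dict[tuple[str, str], LibraryMember] = {}
    for m in library:
        key = (m.barcode5, m.barcode3)
        if key in pair_index:
            raise ValueError(f"duplicate barcode pair in library: {key}")
        pair_index[key] = m

    from collections import Counter

    read_tally = Counter(str(r) for r in reads)
    per_target: dict[str, dict[str, int]] = {}
    res = AssignmentResult(counts=[])
    b, t = BARCODE_LEN, PROTOSPACER_LEN
    for read, n in read_tally.items():
        if len(read) != READ_LEN:
            res.n_dropped_geometry += n
            continue
        member = pair_index.get((read[:b], read[b + t + 3 :]))
        if member is None:
            res.n_dropped_unassigned += n
            continue
        outcome = read[b : b + t]
        if not canonical_outcome_ok(member.record.sequence, outcome, editor):
            res.n_dropped_noncanonical += n
            continue
        tid = member.record.id
        per_target.setdefault(tid, {})
        per_target[tid][outcome] = per_target[tid].get(outcome, 0) + n
        res.n_assigned += n

    by_id = {m.record.id: m.record for m in library}
    res.counts = [
        TargetCounts(tid, by_id[tid], replicate_id, oc) for tid, oc in per_target.items()
    ]
    return res


def pool_replicates(counts: Iterable[TargetCounts]) -> list[TargetCounts]:
    """Sum outcome counts across replicates per target (merge rule: pooling)."""
    pooled: dict[str, TargetCounts] = {}
    for tc in counts:
        if tc.target_id not in pooled:
            pooled[tc.target_id] = TargetCounts(tc.target_id, tc.record, "pooled", {})
        agg = pooled[tc.target_id].outcome_counts
        for outcome, n in tc.outcome_counts.items():
            agg[outcome] = agg.get(outcome, 0) + n
    return list(pooled.values())


def per_base_efficiency(tc: TargetCounts, editor: EditorSpec) -> dict[int, float]:
    """Editing percentage per substrate position of one target.

    100 x (read count carrying the canonical transition at the position) /
    total read count of the target.
    """
    total = tc.total_reads
    if total == 0:
        raise ValueError(f"target {tc.target_id}: zero total reads")
    pct = {p: 0.0 for p in substrate_positions(tc.record, editor)}
    for outcome, n in tc.outcome_counts.items():
        for p in edited_positions(tc.record.sequence, outcome, editor):
            pct[p] += n
    return {p: 100.0 * c / total for p, c in pct.items()}


def overall_efficiency(tc: TargetCounts) -> float:
    """Overall editing percentage: 100 x edited (non-wild-type) reads / total."""
    total = tc.total_reads
    if total == 0:
        raise ValueError(f"target {tc.target_id}: zero total reads")
    wild_type = tc.outcome_counts.get(tc.record.sequence, 0)
    return 100.0 * (total - wild_type) / total


def efficiency_table(
    counts: Iterable[TargetCounts], editor: EditorSpec
) -> pd.DataFrame:
    """Per-target efficiency table: depth, overall %, and pos1..pos20 columns.

    Position columns are NaN where the target has no substrate base.
    Zero-depth targets are dropped (and counted in ``attrs['n_zero_depth']``).
    """
    rows = []
    records: dict[str, ProtospacerRecord] = {}
    n_zero = 0
    for tc in counts:
        if tc.total_reads == 0:
            n_zero += 1
            continue
        records[tc.target_id] = tc.record
        row = {"target_id": tc.target_id, "depth": tc.total_reads,
               "overall_pct": overall_efficiency(tc)}
        row.update({f"pos{p}": v for p, v in per_base_efficiency(tc, editor).items()})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["target_id", "depth", "overall_pct", *POS_COLS])
    df.attrs["editor"] = editor.name
    df.attrs["records"] = records
    df.attrs["n_zero_depth"] = n_zero
    df.attrs["provenance"] = ["efficiency_table(positions 1-20, PAM-distal first)"]
    return df


def filter_loci(
    table: pd.DataFrame, min_depth: int = 100, above_mean: bool = True
) -> pd.DataFrame:
    """Depth and above-mean-efficiency locus filters.

    Loci with depth < ``min_depth`` are removed first; when ``above_mean``,
    loci with overall efficiency <= the library mean (computed after the
    depth filter) are then removed. The mean is recorded in
    ``attrs['mean_overall_pct']`` either way.
    """
    if table.empty:
        raise ValueError("filter_loci: empty efficiency table")
    out = table[table["depth"] >= min_depth].copy()
    mean_pct = float(out["overall_pct"].mean()) if len(out) else float("nan")
    prov = list(table.attrs.get("provenance", []))
    prov.append(f"depth>={min_depth}: kept {len(out)}/{len(table)}")
    if above_mean:
        out = out[out["overall_pct"] > mean_pct].copy()
        prov.append(f"above_mean(>{mean_pct:.4f}%): kept {len(out)}")
    if out.empty:
        warnings.warn("filter_loci: no loci survive filtering", stacklevel=2)
    out.attrs = dict(table.attrs)
    out.attrs["mean_overall_pct"] = mean_pct
    out.attrs["provenance"] = prov
    return out


def library_mean_efficiency(table: pd.DataFrame, min_depth: int = 100) -> float:
    """Library mean overall editing % after the depth filter (the dichotomization threshold)."""
    kept = table[table["depth"] >= min_depth]
    if kept.empty:
        raise ValueError("no loci pass the depth filter")
    return float(kept["overall_pct"].mean())


def dichotomize(table: pd.DataFrame, mean_efficiency: float) -> pd.DataFrame:
    """Label every substrate base edited (1) / non-edited (0) against the mean.

    A base is labelled edited iff its per-position efficiency is >= the
    library mean editing percentage (ties go to edited). Returns a long frame
    (target_id, position, efficiency_pct, label).
    """
    rows = []
    for _, r in table.iterrows():
        for i, col in enumerate(POS_COLS, start=1):
            v = r[col]
            if pd.isna(v):
                continue
            rows.append(
                {"target_id": r["target_id"], "position": i,
                 "efficiency_pct": float(v), "label": int(v >= mean_efficiency)}
            )
    out = pd.DataFrame(rows, columns=["target_id", "position", "efficiency_pct", "label"])
    out.attrs = dict(table.attrs)
    out.attrs["mean_efficiency"] = float(mean_efficiency)
    return out


@dataclass
class PerBaseDataset:
    """Dichotomized per-base examples with per-run train/test/validation splits."""

    records: dict[str, ProtospacerRecord]
    # long-form: target_id, position, label (only substrate positions)
    examples: pd.DataFrame
    # index target_id, one column per run holding 'train' / 'test' / 'validation'
    splits: pd.DataFrame
    run_seeds: list[int]
    mean_efficiency: float

    @property
    def n_runs(self) -> int:
        return self.splits.shape[1]

    def split_ids(self, run: int, split: str) -> list[str]:
        col = self.splits.iloc[:, run]
        return list(col.index[col == split])


def assemble_dataset(
    labelled: pd.DataFrame,
    records: Mapping[str, ProtospacerRecord],
    unedited_ratio: float = 0.25,
    train_frac: float = 0.8,
    n_runs: int = 5,
    seed: int = 0,
) -> PerBaseDataset:
    """Build the per-base model dataset with unedited augmentation and splits.

    Takes the dichotomized long table over depth-filtered loci. Every target
    with >= 1 edited base is included; unedited targets are added at
    ``unedited_ratio`` x the edited-target count (default 1:4
    unedited:edited) to damp the bias toward edited sequences. Per run, a
    stratified (on per-target edit status) split assigns ~``train_frac`` of
    targets to train and halves the remainder 1:1 into test and validation.
    Reproducible: run r uses derived seed ``seed * 1000 + r``.
    """
    per_target = labelled.groupby("target_id")["label"].max()
    edited_ids = sorted(per_target.index[per_target == 1])
    unedited_pool = sorted(per_target.index[per_target == 0])
    if not edited_ids:
        raise ValueError("no edited targets in labelled table")
    n_unedited = int(round(unedited_ratio * len(edited_ids)))
    if n_unedited > len(unedited_pool):
        raise ValueError(
            f"unedited pool too small: need {n_unedited}, have {len(unedited_pool)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2**31), 97]))
    chosen_unedited = sorted(rng.choice(unedited_pool, size=n_unedited, replace=False))
    ids = edited_ids + list(chosen_unedited)
    examples = labelled[labelled["target_id"].isin(ids)][
        ["target_id", "position", "label"]
    ].reset_index(drop=True)

    run_seeds = [(int(seed) * 1000 + r) % (2**31) for r in range(n_runs)]
    strata = {tid: 1 for tid in edited_ids}
    strata.update({tid: 0 for tid in chosen_unedited})
    split_cols = {}
    for r, rs in enumerate(run_seeds):
        run_rng = np.random.default_rng(rs)
        assignment: dict[str, str] = {}
        for status in (1, 0):
            group = [tid for tid in ids if strata[tid] == status]
            run_rng.shuffle(group)
            n_train = int(round(train_frac * len(group)))
            rest = group[n_train:]
            n_test = len(rest) // 2
            for tid in group[:n_train]:
                assignment[tid] = "train"
            for tid in rest[:n_test]:
                assignment[tid] = "test"
            for tid in rest[n_test:]:
                assignment[tid] = "validation"
        split_cols[f"run{r}"] = pd.Series(assignment)
    splits = pd.DataFrame(split_cols).loc[ids]
    return PerBaseDataset(
        records={tid: records[tid] for tid in ids},
        examples=examples,
        splits=splits,
        run_seeds=run_seeds,
        mean_efficiency=float(labelled.attrs.get("mean_efficiency", float("nan"))),
    )


def position_profile(table: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Mean per-position efficiency curve over loci, and its argmax position.

    Positions lacking a substrate base at a locus contribute nothing to that
    position's mean. Returns (20-vector of means with NaN where no locus
    contributes, 1-based argmax position).
    """
    if table.empty:
        raise ValueError("position_profile: empty table")
    profile = table[POS_COLS].mean(skipna=True).to_numpy(dtype=float)
    argmax = int(np.nanargmax(profile)) + 1
    return profile, argmax


def trinuc_proportions(
    labelled: pd.DataFrame,
    records: Mapping[str, ProtospacerRecord],
    only_edited: bool = True,
) -> pd.Series:
    """Proportion of each trinucleotide motif among (edited) substrate bases.

    Bases whose context is undefined (missing flank) are excluded. The
    result sums to 1 over the motifs observed.
    """
    sub = labelled[labelled["label"] == 1] if only_edited else labelled
    tallies: dict[str, int] = {}
    for tid, pos in zip(sub["target_id"], sub["position"]):
        ctx = trinucleotide_context(records[tid], int(pos))
        if ctx is None:
            continue
        tallies[ctx] = tallies.get(ctx, 0) + 1
    if not tallies:
        return pd.Series(dtype=float)
    s = pd.Series(tallies, dtype=float).sort_index()
    return s / s.sum()


def replicate_concordance(
    counts: Iterable[TargetCounts], min_depth: int = 100
) -> float:
    """Pearson r^2 between replicate per-target overall editing percentages.

    Requires exactly two replicate ids among the counts; targets present at
    >= min_depth in both replicates enter the correlation.
    """
    by_rep: dict[str, dict[str, float]] = {}
    for tc in counts:
        if tc.total_reads >= min_depth:
            by_rep.setdefault(tc.replicate_id, {})[tc.target_id] = overall_efficiency(tc)
    if len(by_rep) != 2:
        raise ValueError(f"need exactly 2 replicates, got {sorted(by_rep)}")
    (ra, rb) = by_rep.values()
    shared = sorted(set(ra) & set(rb))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared targets between replicates")
    x = np.array([ra[t] for t in shared])
    y = np.array([rb[t] for t in shared])
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r
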