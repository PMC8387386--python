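"""File formats: library design tables, counts tables, FASTA/FASTQ, provenance.

All tabular artifacts are tab-separated with a header row, preceded by
comment lines (``# ...``) that state the coordinate convention (positions
1–20, PAM-distal first) and, where applicable, the provenance/config hash.
Malformed rows are rejected with their line numbers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import LibraryMember, ProtospacerRecord
from .screen_proc import TargetCounts
from .screen_sim import SyntheticScreen

COORD_NOTE = "# positions are 1-based, counted from the PAM-distal end of the 20-nt protospacer"

LIBRARY_COLS = ["id", "spacer", "barcode5", "target20", "pam", "barcode3", "flank5", "flank3"]
COUNTS_COLS = ["target_id", "replicate", "outcome_sequence", "count"]


def config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: str | Path, extra_comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_NOTE + "\n")
        for c in extra_comments or []:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def write_library(members: Iterable[LibraryMember], path: str | Path,
                  comments: list[str] | None = None) -> None:
    rows = [
        {"id": m.record.id, "spacer": m.spacer, "barcode5": m.barcode5,
         "target20": m.record.sequence, "pam": m.record.pam,
         "barcode3": m.barcode3, "flank5": m.record.flank5, "flank3": m.record.flank3}
        for m in members
    ]
    _write_tsv(pd.DataFrame(rows, columns=LIBRARY_COLS), path, comments)


def read_library(path: str | Path) -> list[LibraryMember]:
    df = _read_tsv(path).fillna("")
    missing = set(LIBRARY_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing library columns {sorted(missing)}")
    members, seen = [], set()
    for i, row in df.iterrows():
        line = i + 2  # header line is 1 (comments excluded by the reader)
        if row["id"] in seen:
            raise ValueError(f"{path} line {line}: duplicate id {row['id']!r}")
        seen.add(row["id"])
        try:
            rec = ProtospacerRecord(row["id"], row["target20"], row["pam"],
                                    row["flank5"], row["flank3"])
            members.append(LibraryMember(record=rec, spacer=row["spacer"],
                                         barcode5=row["barcode5"], barcode3=row["barcode3"]))
        except ValueError as e:
            raise ValueError(f"{path} line {line}: {e}") from e
    return members


def write_counts_table(counts: Iterable[TargetCounts], path: str | Path,
                       comments: list[str] | None = None) -> None:
    rows = [
        {"target_id": tc.target_id, "replicate": tc.replicate_id,
         "outcome_sequence": o, "count": n}
        for tc in counts
        for o, n in sorted(tc.outcome_counts.items())
    ]
    _write_tsv(pd.DataFrame(rows, columns=COUNTS_COLS), path, comments)


def read_counts_table(
    path: str | Path, records: Mapping[str, ProtospacerRecord]
) -> list[TargetCounts]:
    df = _read_tsv(path)
    missing = set(COUNTS_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing counts columns {sorted(missing)}")
    grouped: dict[tuple[str, str], TargetCounts] = {}
    for i, row in df.iterrows():
        line = i + 2
        tid = row["target_id"]
        if tid not in records:
            raise ValueError(f"{path} line {line}: unknown target_id {tid!r}")
        try:
            n = int(row["count"])
        except (TypeError, ValueError) as e:
            raise ValueError(f"{path} line {line}: non-integer count {row['count']!r}") from e
        if n < 0:
            raise ValueError(f"{path} line {line}: negative count {n}")
        key = (tid, row["replicate"])
        if key not in grouped:
            grouped[key] = TargetCounts(tid, records[tid], row["replicate"], {})
        oc = grouped[key].outcome_counts
        oc[row["outcome_sequence"]] = oc.get(row["outcome_sequence"], 0) + n
    return list(grouped.values())


def screen_counts_tables(screen: SyntheticScreen, out_dir: str | Path,
                         comments: list[str] | None = None) -> list[Path]:
    """Write one counts TSV per replicate of a simulated screen."""
    from .screen_proc import counts_from_screen

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_rep: dict[str, list[TargetCounts]] = {}
    for tc in counts_from_screen(screen):
        by_rep.setdefault(tc.replicate_id, []).append(tc)
    paths = []
    for rep, tcs in sorted(by_rep.items()):
        p = out_dir / f"counts_{rep}.tsv"
        write_counts_table(tcs, p, comments)
        paths.append(p)
    return paths


def read_fasta_protospacers(
    path: str | Path, pam: str = "AGG"
) -> list[ProtospacerRecord]:
    """Protospacer list from FASTA; PAM/flanks from the description or a default.

    Description tokens of the form ``pam=TGG flank5=A flank3=C`` override the
    default PAM and the (absent) flanks.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(
            t.split("=", 1) for t in rec.description.split() if "=" in t
        )
        out.append(
            ProtospacerRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                pam=tokens.get("pam", pam).upper(),
                flank5=tokens.get("flank5", "").upper(),
                flank3=tokens.get("flank3", "").upper(),
            )
        )
    return out


def write_fastq(reads: Iterable[str], path: str | Path, phred: int = 30) -> None:
    """Fixed-quality FASTQ for simulated 35-bp screen reads."""
    records = (
        SeqRecord(Seq(r), id=f"read{i}", description="",
                  letter_annotations={"phred_quality": [phred] * len(r)})
        for i, r in enumerate(reads)
    )
    SeqIO.write(records, str(path), "fastq")


def read_fastq_reads(path: str | Path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def write_dataset(dataset, prefix: str | Path) -> None:
    """Persist a PerBaseDataset as <prefix>.examples.tsv / .splits.tsv / .json."""
    prefix = str(prefix)
    _write_tsv(dataset.examples, prefix + ".examples.tsv")
    splits = dataset.splits.reset_index(names="target_id")
    _write_tsv(splits, prefix + ".splits.tsv")
    Path(prefix + ".json").write_text(json.dumps({
        "run_seeds": dataset.run_seeds,
        "mean_efficiency": dataset.mean_efficiency,
        "n_targets": int(dataset.splits.shape[0]),
    }, indent=2) + "\n")


def read_dataset(prefix: str | Path, records: Mapping[str, ProtospacerRecord]):
    """Load a PerBaseDataset written by :func:`write_dataset`."""
    from .screen_proc import PerBaseDataset

    prefix = str(prefix)
    examples = _read_tsv(prefix + ".examples.tsv")
    examples["position"] = examples["position"].astype(int)
    examples["label"] = examples["label"].astype(int)
    splits = _read_tsv(prefix + ".splits.tsv").set_index("target_id")
    meta = json.loads(Path(prefix + ".json").read_text())
    return PerBaseDataset(
        records={tid: records[tid] for tid in splits.index},
        examples=examples,
        splits=splits,
        run_seeds=list(meta["run_seeds"]),
        mean_efficiency=float(meta["mean_efficiency"]),
    )


def write_provenance(path: str | Path, config: dict, extra: dict | None = None) -> dict:
    """Provenance JSON: config, config hash, package version, tallies."""
    from . import __version__

    doc = {
        "config": config,
        "config_hash": config_hash(config),
        "package_version": __version__,
        "coordinate_convention": COORD_NOTE.lstrip("# "),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n")
    return doc
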