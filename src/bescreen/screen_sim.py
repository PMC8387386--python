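"""Synthetic self-targeting screen generator with known editing ground truth.

The generator emulates the structure of a pooled self-targeting library
screen: each library member carries a random 20-nt protospacer with an NGG
PAM between two 6-nt barcodes; sequencing a member yields reads whose
protospacer slice is either wild type or carries canonical transitions
(A->G for ABE-class editors, C->T for CBE-class). Editing truth is a
per-position window probability times a trinucleotide-context multiplier,
so every downstream stage (read assignment, quantification, per-base and
outcome-distribution models) has a recovery-testable input.

Randomness flows from one master seed expanded into named substreams
(library, depths, edits, noise) so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqcore import (
    ABE,
    CBE,
    ALPHABET,
    BARCODE_LEN,
    PROTOSPACER_LEN,
    EditorSpec,
    ProtospacerRecord,
    LibraryMember,
    substrate_positions,
    trinucleotide_context,
)

# substream tags (mixed into the master seed; keeps derived seeds < 2**31)
_STREAMS = {"library": 1, "depths": 2, "edits": 3, "noise": 4, "fastq": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed % (2**31), _STREAMS[stream]]))


@dataclass
class EditorTruthModel:
    """Simulator ground truth: window probabilities x motif multipliers.

    ``window`` maps 1-based PAM-distal positions to a base editing
    probability; positions absent from the map have probability 0.
    ``motif_multipliers`` maps trinucleotide motifs (preceding base,
    substrate, following base) to a nonnegative multiplier; motifs absent
    default to 1. The effective per-read, per-position editing probability is
    min(window[p] * multiplier(context), ceiling).
    """

    name: str
    editor: EditorSpec
    window: dict[int, float]
    motif_multipliers: dict[str, float] = field(default_factory=dict)
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        for p, w in self.window.items():
            if not (1 <= p <= PROTOSPACER_LEN and 0.0 <= w <= 1.0):
                raise ValueError(f"bad window entry {p}: {w}")
        if any(m < 0 for m in self.motif_multipliers.values()):
            raise ValueError("motif multipliers must be nonnegative")

    def effective_probability(self, record: ProtospacerRecord, position: int) -> float:
        """min(window[p] x multiplier(trinucleotide context), ceiling)."""
        w = self.window.get(position, 0.0)
        ctx = trinucleotide_context(record, position)
        mult = self.motif_multipliers.get(ctx, 1.0) if ctx is not None else 1.0
        return float(min(w * mult, self.ceiling))

    def truth_vector(self, record: ProtospacerRecord) -> tuple[list[int], np.ndarray]:
        """(substrate positions, effective probabilities) for one target."""
        pos = substrate_positions(record, self.editor)
        return pos, np.array([self.effective_probability(record, p) for p in pos])


@dataclass
class ScreenConfig:
    """Shape of a simulated screen (coverage, replication, noise)."""

    n_targets: int = 2000
    depth_mean: float = 1000.0
    depth_dispersion: float = 10.0  # negative-binomial size parameter
    n_replicates: int = 2
    replicate_noise_sd: float = 0.10  # logit-scale sd of per-(replicate,target) offset
    co_edit_dose_sd: float = 0.0  # per-read logit-scale latent dose; 0 = independent positions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")


@dataclass
class SyntheticScreen:
    """Library + truth + per-replicate outcome counts."""

    library: list[LibraryMember]
    truth: EditorTruthModel
    config: ScreenConfig
    # counts[replicate][target_id] -> {outcome_sequence: read count}
    counts: list[dict[str, dict[str, int]]]


def generate_library(
    n: int,
    seed: int,
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> list[LibraryMember]:
    """Random 20-mer protospacer library with barcodes, NGG PAMs and 1-nt flanks.

    ``composition`` gives the per-symbol proportions (A, C, G, T) used for the
    protospacer; barcodes, PAM N and flanks are sampled uniformly. Barcode
    pairs are guaranteed unique so exact-match read assignment is well posed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
        raise ValueError("composition must be 4 nonnegative proportions summing to 1")
    rng = _rng(seed, "library")
    bases = np.array(list(ALPHABET))
    members: list[LibraryMember] = []
    seen_pairs: set[tuple[str, str]] = set()
    while len(members) < n:
        spacer = "".join(bases[rng.choice(4, size=PROTOSPACER_LEN, p=comp)])
        pam = bases[rng.integers(4)] + "GG"
        flank5 = str(bases[rng.integers(4)])
        flank3 = str(bases[rng.integers(4)])
        bc5 = "".join(bases[rng.integers(4, size=BARCODE_LEN)])
        bc3 = "".join(bases[rng.integers(4, size=BARCODE_LEN)])
        if (bc5, bc3) in seen_pairs:
            continue
        seen_pairs.add((bc5, bc3))
        rec = ProtospacerRecord(
            id=f"T{len(members):05d}", sequence=spacer, pam=pam, flank5=flank5, flank3=flank3
        )
        members.append(LibraryMember(record=rec, barcode5=bc5, barcode3=bc3))
    return members


def _outcome_string(spacer: str, positions: list[int], code: int, product: str) -> str:
    out = list(spacer)
    for j, p in enumerate(positions):
        if code >> j & 1:
            out[p - 1] = product
    return "".join(out)


def simulate_reads(
    library: list[LibraryMember], truth: EditorTruthModel, config: ScreenConfig
) -> SyntheticScreen:
    """Sample outcome-sequence read counts for every library member.

    Each read edits every substrate position independently with probability
    min(window x multiplier, ceiling), perturbed per (replicate, target) on
    the logit scale by a N(0, replicate_noise_sd) offset. When
    ``co_edit_dose_sd`` > 0 an additional per-read latent dose offset couples
    positions within a read. Depth is negative-binomial per target and
    replicate. Deterministic under config.seed.
    """
    depth_rng = _rng(config.seed, "depths")
    edit_rng = _rng(config.seed, "edits")
    noise_rng = _rng(config.seed, "noise")
    product = truth.editor.product
    nb_n = config.depth_dispersion
    counts: list[dict[str, dict[str, int]]] = [dict() for _ in range(config.n_replicates)]

    for member in library:
        rec = member.record
        positions, probs = truth.truth_vector(rec)
        k = len(positions)
        with np.errstate(divide="ignore"):
            logits = np.log(probs) - np.log1p(-probs)  # -inf where p == 0
        for rep in range(config.n_replicates):
            depth = int(
                depth_rng.negative_binomial(nb_n, nb_n / (nb_n + config.depth_mean))
            )
            if config.replicate_noise_sd > 0:
                offset = noise_rng.normal(0.0, config.replicate_noise_sd)
            else:
                offset = 0.0
            target_counts: dict[str, int] = {}
            if depth == 0:
                counts[rep][rec.id] = target_counts
                continue
            if k == 0:
                target_counts[rec.sequence] = depth
                counts[rep][rec.id] = target_counts
                continue
            if config.co_edit_dose_sd > 0:
                dose = edit_rng.normal(0.0, config.co_edit_dose_sd, size=(depth, 1))
            else:
                dose = 0.0
            p_rep = 1.0 / (1.0 + np.exp(-(logits[None, :] + offset + dose)))
            edited = edit_rng.random((depth, k)) < p_rep
            codes = edited @ (1 << np.arange(k, dtype=np.int64))
            uniq, n = np.unique(codes, return_counts=True)
            for code, c in zip(uniq, n):
                target_counts[_outcome_string(rec.sequence, positions, int(code), product)] = int(c)
            counts[rep][rec.id] = target_counts
    return SyntheticScreen(library=library, truth=truth, config=config, counts=counts)


def _factor_multipliers(prev: dict[str, float], substrate: str, nxt: dict[str, float]) -> dict[str, float]:
    """16 motif multipliers from separable preceding/following factors, mean-normalized."""
    pf = {b: prev.get(b, 1.0) for b in ALPHABET}
    nf = {b: nxt.get(b, 1.0) for b in ALPHABET}
    pmean = sum(pf.values()) / 4.0
    nmean = sum(nf.values()) / 4.0
    return {
        a + substrate + b: (pf[a] / pmean) * (nf[b] / nmean)
        for a in ALPHABET
        for b in ALPHABET
    }


def packaged_profiles(scale: float = 1.0) -> dict[str, EditorTruthModel]:
    """Truth models for the four emulated editors.

    Windows peak at protospacer position 6 for the ABEmax-, CBE4max- and
    ABE8e-like editors and at position 3 for the Target-AID-like editor
    (1-based, PAM-distal first); the ABE8e-like window is broader at half
    maximum than the ABEmax-like one. Context multipliers encode the
    deaminase preferences: preceding-T preference (ABEmax-, CBE4max-like),
    preceding-A aversion plus following-C preference (ABEmax-like, weaker
    preceding-A aversion for ABE8e-like) and following-C aversion
    (Target-AID-like). Window values are fixture definitions calibrated so
    mean overall editing lands in the 3-4.5% range at default scale.
    """

    def scaled(window: dict[int, float]) -> dict[int, float]:
        return {p: min(w * scale, 1.0) for p, w in window.items()}

    return {
        "ABEmax-like": EditorTruthModel(
            name="ABEmax-like",
            editor=ABE,
            window=scaled({3: 0.007, 4: 0.019, 5: 0.033, 6: 0.044, 7: 0.031, 8: 0.016, 9: 0.007}),
            motif_multipliers=_factor_multipliers(
                {"T": 1.9, "A": 0.35, "C": 1.0, "G": 0.9}, "A", {"C": 1.4, "A": 0.9, "G": 0.9, "T": 0.9}
            ),
        ),
        "CBE4max-like": EditorTruthModel(
            name="CBE4max-like",
            editor=CBE,
            window=scaled({3: 0.009, 4: 0.021, 5: 0.033, 6: 0.042, 7: 0.030, 8: 0.014, 9: 0.005}),
            motif_multipliers=_factor_multipliers(
                {"T": 2.0, "C": 0.8, "A": 0.7, "G": 0.8}, "C", {}
            ),
        ),
        "ABE8e-like": EditorTruthModel(
            name="ABE8e-like",
            editor=ABE,
            window=scaled(
                {2: 0.007, 3: 0.012, 4: 0.018, 5: 0.023, 6: 0.027, 7: 0.023, 8: 0.018, 9: 0.012, 10: 0.007}
            ),
            motif_multipliers=_factor_multipliers({"A": 0.6, "T": 1.2}, "A", {}),
        ),
        "Target-AID-like": EditorTruthModel(
            name="Target-AID-like",
            editor=CBE,
            window=scaled({1: 0.014, 2: 0.030, 3: 0.044, 4: 0.032, 5: 0.018, 6: 0.007}),
            motif_multipliers=_factor_multipliers({}, "C", {"C": 0.4, "A": 1.1, "G": 1.1, "T": 1.1}),
        ),
    }


def screen_reads(
    screen: SyntheticScreen, replicate: int, shuffle_seed: int | None = None
) -> list[str]:
    """Flatten one replicate's counts into 35-bp read strings.

    Read geometry is barcode5(6) + outcome(20) + pam(3) + barcode3(6),
    mirroring the designed amplicon; optional shuffling decouples read order
    from library order for assignment tests.
    """
    by_id = {m.record.id: m for m in screen.library}
    reads: list[str] = []
    for tid, outcome_counts in screen.counts[replicate].items():
        m = by_id[tid]
        for outcome, c in outcome_counts.items():
            reads.extend([m.barcode5 + outcome + m.record.pam + m.barcode3] * c)
    if shuffle_seed is not None:
        _rng(shuffle_seed, "fastq").shuffle(reads)
    return reads
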