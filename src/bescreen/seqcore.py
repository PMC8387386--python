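"""Core sequence types and coordinate conventions for base-editor screens.

Positions along the 20-nt protospacer are 1-based and counted from the
PAM-distal end: position 1 is the 5'-most base of the protospacer (on the
non-target strand as printed), position 20 is adjacent to the NGG PAM.
All modules in this package share that convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

PROTOSPACER_LEN = 20
ALPHABET = "ACGT"
_ACGT = set(ALPHABET)
_PAM_RE = re.compile(r"^[ACGT]GG$")

#: index used for symbol <-> integer conversion everywhere (A=0, C=1, G=2, T=3)
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def _check_alphabet(seq: str, what: str) -> None:
    bad = set(seq) - _ACGT
    if bad:
        raise ValueError(f"{what} contains non-ACGT symbol(s): {sorted(bad)!r}")


@dataclass(frozen=True)
class EditorSpec:
    """A base-editor class: which base it deaminates and what it becomes.

    ABE-class editors convert A•T to G•C (substrate A, product G); CBE-class
    editors convert C•G to T•A (substrate C, product T).
    """

    name: str
    substrate: str
    product: str

    def __post_init__(self) -> None:
        if (self.substrate, self.product) not in {("A", "G"), ("C", "T")}:
            raise ValueError(
                f"(substrate, product) must be (A,G) or (C,T), got "
                f"({self.substrate},{self.product})"
            )


ABE = EditorSpec("ABE", "A", "G")
CBE = EditorSpec("CBE", "C", "T")


@dataclass(frozen=True)
class ProtospacerRecord:
    """A 20-nt protospacer with its NGG PAM and optional 1-nt flanks.

    ``flank5`` is the base immediately 5' of protospacer position 1;
    ``flank3`` the base immediately 3' of position 20 (i.e. the N of the
    PAM region side is *not* implied — flank3 is stored explicitly so the
    trinucleotide context at position 20 is well defined).
    """

    id: str
    sequence: str
    pam: str
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != PROTOSPACER_LEN:
            raise ValueError(
                f"protospacer must be {PROTOSPACER_LEN} nt, got {len(self.sequence)}"
            )
        _check_alphabet(self.sequence, f"protospacer {self.id!r}")
        if not _PAM_RE.match(self.pam):
            raise ValueError(f"PAM must match NGG over ACGT, got {self.pam!r}")
        for fl, name in ((self.flank5, "flank5"), (self.flank3, "flank3")):
            if len(fl) > 1:
                raise ValueError(f"{name} must be 0 or 1 nt, got {fl!r}")
            if fl:
                _check_alphabet(fl, name)

    def base_at(self, position: int) -> str:
        check_position(position)
        return self.sequence[position - 1]


def check_position(position: int) -> None:
    if not 1 <= position <= PROTOSPACER_LEN:
        raise ValueError(f"position must be in [1, {PROTOSPACER_LEN}], got {position}")


def substrate_positions(record: ProtospacerRecord, editor: EditorSpec) -> list[int]:
    """1-based PAM-distal positions holding the editor's substrate base, ascending."""
    return [i + 1 for i, b in enumerate(record.sequence) if b == editor.substrate]


def scan_pam_distance(
    context_sequence: str, target_index: int, min_gap: int = 8, max_gap: int = 18
) -> bool:
    """Test whether an NGG PAM sits 8–18 bases downstream of a target base.

    ``target_index`` is the 0-based index of the target base in
    ``context_sequence``. The gap d counts the bases strictly between the
    target base and the first (N) base of the PAM; a target with d in
    [min_gap, max_gap] corresponds to protospacer position 20 - d, which for
    the default bounds places the target inside positions 2–12 and hence
    covers the published editing windows.
    """
    if not 0 <= target_index < len(context_sequence):
        raise IndexError(f"target_index {target_index} out of bounds")
    for d in range(min_gap, max_gap + 1):
        pam_start = target_index + 1 + d
        pam = context_sequence[pam_start : pam_start + 3]
        if len(pam) == 3 and pam[1:] == "GG":
            return True
    return False


def gc_content(spacer: str) -> float:
    """Fraction of G or C symbols in a spacer sequence."""
    _check_alphabet(spacer, "spacer")
    if not spacer:
        raise ValueError("empty spacer")
    return (spacer.count("G") + spacer.count("C")) / len(spacer)


def trinucleotide_context(
    record: ProtospacerRecord, position: int
) -> Optional[str]:
    """3-mer (preceding, target, following) around a protospacer position.

    Uses flank5/flank3 at the protospacer boundaries; returns None when the
    needed flank is absent, so callers can exclude undefined contexts rather
    than guess.
    """
    check_position(position)
    seq = record.sequence
    prev = record.flank5 if position == 1 else seq[position - 2]
    nxt = record.flank3 if position == PROTOSPACER_LEN else seq[position]
    if not prev or not nxt:
        return None
    return prev + seq[position - 1] + nxt


def canonical_outcome_ok(
    protospacer: str, outcome: str, editor: EditorSpec
) -> bool:
    """True iff *outcome* differs from *protospacer* only by canonical transitions.

    A canonical transition replaces the editor's substrate base by its product
    (A->G for ABE, C->T for CBE); any other difference is non-canonical.
    """
    if len(outcome) != len(protospacer):
        return False
    for a, b in zip(protospacer, outcome):
        if a != b and not (a == editor.substrate and b == editor.product):
            return False
    return True


def edited_positions(protospacer: str, outcome: str, editor: EditorSpec) -> tuple[int, ...]:
    """1-based positions where *outcome* carries the canonical transition."""
    return tuple(
        i + 1
        for i, (a, b) in enumerate(zip(protospacer, outcome))
        if a == editor.substrate and b == editor.product
    )


@dataclass
class LibraryMember:
    """One row of a self-targeting library design: spacer + barcoded target."""

    record: ProtospacerRecord
    spacer: str = ""
    barcode5: str = ""
    barcode3: str = ""

    def __post_init__(self) -> None:
        if not self.spacer:
            self.spacer = self.record.sequence
        for bc, name in ((self.barcode5, "barcode5"), (self.barcode3, "barcode3")):
            if bc:
                _check_alphabet(bc, name)


# re-exported field used by read assignment: designed read geometry is
# barcode5(6) + target(20) + pam(3) + barcode3(6) = 35 bp
BARCODE_LEN = 6
READ_LEN = BARCODE_LEN + PROTOSPACER_LEN + 3 + BARCODE_LEN
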