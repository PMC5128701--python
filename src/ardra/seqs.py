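"""Sequence records, IUPAC degeneracy logic, FASTA I/O and global alignment.

All downstream stages (primer matching, digestion, classification,
phylogeny) consume :class:`SequenceRecord` objects produced here.  Identity
between partial 16S sequences of unequal length is computed from an optimal
global alignment with the terminal-overhang columns excluded from the
denominator, which is how "percent identity to the closest relative" behaves
for partial reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO

__all__ = [
    "IUPAC_SETS",
    "SequenceRecord",
    "PairwiseAlignment",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "iupac_match",
    "reverse_complement",
    "global_align",
    "identity_pct",
]

#: Degeneracy sets of the IUPAC nucleotide alphabet.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input or invalid residues."""


def _normalize(residues: str, context: str) -> str:
    seq = residues.upper().replace("U", "T")
    bad = set(seq) - set(IUPAC_SETS)
    if bad:
        raise FastaFormatError(
            f"{context}: non-IUPAC characters {sorted(bad)!r}"
        )
    if not seq:
        raise FastaFormatError(f"{context}: empty sequence")
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """An identified DNA sequence over the IUPAC alphabet.

    Residues are uppercased and RNA-style U is mapped to T on construction;
    the id must be a single whitespace-free token (the first token of a
    FASTA header).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}")
        object.__setattr__(
            self, "residues", _normalize(self.residues, f"record {self.id!r}")
        )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences with end-gap-free identity.

    ``identity_pct`` is 100 x matches / aligned columns, where columns inside
    a terminal-gap overhang of either sequence are excluded from the
    denominator and internal gap columns count as mismatches.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into normalized records.

    Record order is preserved.  Empty files, duplicate ids and non-IUPAC
    residues raise :class:`FastaFormatError` naming the offender.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def iupac_match(pattern_base: str, target_base: str) -> bool:
    """True iff ``target_base`` lies in the degeneracy set of ``pattern_base``."""
    try:
        return target_base in IUPAC_SETS[pattern_base]
    except KeyError:
        raise ValueError(f"non-IUPAC character {pattern_base!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement with degenerate codes complemented (Y<->R etc.)."""
    bad = set(seq.upper()) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"non-IUPAC characters {sorted(bad)!r}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


# Among co-optimal global alignments we want the one pushing gaps into the
# terminal overhangs (that is what the end-gap-free identity denominator
# assumes).  A tiny bonus on end gaps steers the traceback there without
# ever flipping a strictly suboptimal alignment into the winner: with the
# default integer-valued scoring the total bonus stays far below the score
# granularity of 1.
_END_GAP_EPS = 1e-6


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap  # linear gap cost
    aligner.open_end_insertion_score = gap + _END_GAP_EPS
    aligner.extend_end_insertion_score = gap + _END_GAP_EPS
    aligner.open_end_deletion_score = gap + _END_GAP_EPS
    aligner.extend_end_deletion_score = gap + _END_GAP_EPS
    return aligner


def _terminal_spans(a: str, b: str) -> tuple[int, int]:
    """(leading, trailing) column counts occupied by terminal-gap overhangs."""

    def lead(s: str) -> int:
        n = 0
        while n < len(s) and s[n] == "-":
            n += 1
        return n

    leading = max(lead(a), lead(b))
    trailing = max(lead(a[::-1]), lead(b[::-1]))
    return leading, trailing


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch global alignment of two sequences.

    Scoring is linear-gap (defaults +1 match, -1 mismatch, -2 per gapped
    column, terminal gaps penalized like any other).  Among co-optimal
    alignments a single deterministic traceback is reported.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else _normalize(a, "sequence a")
    sb = b.residues if isinstance(b, SequenceRecord) else _normalize(b, "sequence b")
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(sa, sb)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    # re-score the chosen alignment under the stated scheme exactly,
    # without the end-gap traceback bias
    score = 0.0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            score += gap
        elif x == y:
            score += match
        else:
            score += mismatch
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        identity_pct=_identity_from_alignment(aligned_a, aligned_b),
    )


def _identity_from_alignment(aligned_a: str, aligned_b: str) -> float:
    leading, trailing = _terminal_spans(aligned_a, aligned_b)
    core_a = aligned_a[leading : len(aligned_a) - trailing]
    core_b = aligned_b[leading : len(aligned_b) - trailing]
    columns = len(core_a)
    if columns <= 0:
        return 0.0
    matches = sum(x == y and x != "-" for x, y in zip(core_a, core_b))
    return 100.0 * matches / columns


def identity_pct(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """End-gap-free percent identity under the default alignment scoring.

    Identity is a property of the unordered pair: operands are canonicalized
    (lexicographically smaller sequence first) before aligning, so the value
    is exactly symmetric even when several co-optimal alignments with
    different column structures exist.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else _normalize(a, "sequence a")
    sb = b.residues if isinstance(b, SequenceRecord) else _normalize(b, "sequence b")
    if sb < sa:
        sa, sb = sb, sa
    return global_align(sa, sb).identity_pct


def as_records(seqs: Sequence[str], prefix: str = "s") -> list[SequenceRecord]:
    """Convenience: wrap plain strings in records with generated ids."""
    return [SequenceRecord(f"{prefix}{i}", s) for i, s in enumerate(seqs)]
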