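"""Nearest-reference assignment, novelty calling and chimera screening.

A clone is assigned to its best-matching labelled reference by end-gap-free
global-alignment identity.  Clones under 97% identity to their closest
relative are called novel (the conventional species-level 16S cutoff);
genus labels are transferred only above a (configurable) 90% floor.

The chimera screen is a deliberately simple split-half test, not a full
fragment-recombination search: a clone is flagged when its two halves match
*different* references and each half matches its parent clearly better than
the whole clone matches any single reference.  It is a screen, not a proof.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .otu import AbundanceTable
from .seqs import SequenceRecord, identity_pct

__all__ = [
    "UNCLASSIFIED",
    "ReferenceDB",
    "NoveltyCall",
    "ChimeraCall",
    "nearest_reference",
    "screen_chimeras",
    "dominance_report",
    "genus_richness",
    "GenusShare",
]

UNCLASSIFIED = "Unclassified"

#: identity below which a clone is a putative new (novel) sequence
NOVELTY_THRESHOLD_PCT = 97.0
#: identity floor for transferring the best reference's genus label
GENUS_THRESHOLD_PCT = 90.0
MIN_SCREEN_LENGTH = 40


class ReferenceDB:
    """Labelled reference sequences standing in for a BLAST database."""

    def __init__(
        self,
        records: Sequence[SequenceRecord],
        labels: Mapping[str, tuple[str, str]],
    ) -> None:
        if not records:
            raise ValueError("reference database is empty")
        for rec in records:
            if rec.id not in labels:
                raise ValueError(f"reference {rec.id!r} has no genus label")
            if not labels[rec.id][0]:
                raise ValueError(f"reference {rec.id!r} has an empty genus")
        self.records = list(records)
        self.labels = dict(labels)
        self._identity_cache: dict[tuple[str, str], float] = {}

    def genus(self, ref_id: str) -> str:
        return self.labels[ref_id][0]

    @classmethod
    def from_files(cls, fasta: str | Path, labels_tsv: str | Path) -> "ReferenceDB":
        from .seqs import read_fasta

        records = read_fasta(fasta)
        labels: dict[str, tuple[str, str]] = {}
        with open(labels_tsv) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                labels[row["ref_id"]] = (row["genus"], row.get("family", ""))
        return cls(records, labels)

    def identity(self, query: str, ref: SequenceRecord) -> float:
        # clone libraries contain many identical sequences; cache by residues
        key = (query, ref.id)
        if key not in self._identity_cache:
            self._identity_cache[key] = identity_pct(query, ref)
        return self._identity_cache[key]

    def best_match(self, query: str) -> tuple[str, float]:
        """(ref_id, identity) of the best reference; ties to smallest ref id."""
        best_id, best_identity = "", -1.0
        for ref in sorted(self.records, key=lambda r: r.id):
            ident = self.identity(query, ref)
            if ident > best_identity:
                best_id, best_identity = ref.id, ident
        return best_id, best_identity


@dataclass(frozen=True)
class NoveltyCall:
    clone_id: str
    best_ref_id: str
    identity_pct: float
    is_novel: bool
    assigned_genus: str


@dataclass(frozen=True)
class ChimeraCall:
    clone_id: str
    parent_5prime: str
    parent_3prime: str
    gain_pct: float
    is_chimeric: bool


def nearest_reference(
    clone: SequenceRecord,
    db: ReferenceDB,
    novelty_threshold: float = NOVELTY_THRESHOLD_PCT,
    genus_threshold: float = GENUS_THRESHOLD_PCT,
) -> NoveltyCall:
    """Best-reference call with novelty verdict (novel iff identity < 97%)."""
    best_id, identity = db.best_match(clone.residues)
    return NoveltyCall(
        clone_id=clone.id,
        best_ref_id=best_id,
        identity_pct=identity,
        is_novel=identity < novelty_threshold,
        assigned_genus=db.genus(best_id) if identity >= genus_threshold else UNCLASSIFIED,
    )


def screen_chimeras(
    clones: Sequence[SequenceRecord],
    db: ReferenceDB,
    margin: float = 3.0,
) -> list[ChimeraCall]:
    """Split-half chimera screen against the reference database.

    Each clone is split at its midpoint; it is flagged chimeric iff the two
    halves' best references differ and the weaker half still matches its
    parent at least ``margin`` percentage points better than the full-length
    sequence matches any single reference.
    """
    if not clones:
        raise ValueError("no clones to screen")
    calls: list[ChimeraCall] = []
    for clone in clones:
        if len(clone) < MIN_SCREEN_LENGTH:
            warnings.warn(
                f"clone {clone.id!r} shorter than {MIN_SCREEN_LENGTH} nt; "
                "skipped by the chimera screen",
                stacklevel=2,
            )
            continue
        mid = len(clone) // 2
        ref5, ident5 = db.best_match(clone.residues[:mid])
        ref3, ident3 = db.best_match(clone.residues[mid:])
        _, full_ident = db.best_match(clone.residues)
        gain = min(ident5, ident3) - full_ident
        calls.append(
            ChimeraCall(
                clone_id=clone.id,
                parent_5prime=ref5,
                parent_3prime=ref3,
                gain_pct=gain,
                is_chimeric=(ref5 != ref3 and gain >= margin),
            )
        )
    return calls


@dataclass(frozen=True)
class GenusShare:
    genus: str
    clone_pct: float
    display_pct: int
    dominant: bool


def dominance_report(
    table: AbundanceTable,
    genera: Mapping[str, str],
    total_clones_override: int | None = None,
    dominance_threshold_pct: float = 10.0,
) -> list[GenusShare]:
    """Per-genus clone percentages, sorted by decreasing share.

    ``genera`` maps every OTU id to its genus (possibly "Unclassified").
    The denominator defaults to the table total but may be overridden when
    an externally stated library size should be honoured.  Display values
    are rounded half-up to whole percent; genera holding at least 10% of
    clones are marked dominant.
    """
    missing = set(table.counts) - set(genera)
    if missing:
        raise ValueError(f"OTUs without a genus label: {sorted(missing)}")
    n = table.total if total_clones_override is None else total_clones_override
    if n < table.total:
        raise ValueError(f"override {n} is less than the table total {table.total}")
    by_genus: dict[str, int] = {}
    for otu_id, count in table.counts.items():
        by_genus[genera[otu_id]] = by_genus.get(genera[otu_id], 0) + count
    shares = []
    for genus, count in sorted(by_genus.items(), key=lambda kv: (-kv[1], kv[0])):
        pct = 100.0 * count / n
        shares.append(
            GenusShare(
                genus=genus,
                clone_pct=pct,
                display_pct=int(math_floor_half_up(pct)),
                dominant=pct >= dominance_threshold_pct,
            )
        )
    return shares


def math_floor_half_up(x: float) -> int:
    """Round half up to the nearest integer (22.5 -> 23)."""
    import math

    return int(math.floor(x + 0.5))


def genus_richness(calls: Sequence[NoveltyCall] | Mapping[str, str]) -> int:
    """Distinct genera among per-OTU calls, excluding "Unclassified"."""
    if isinstance(calls, Mapping):
        genera = set(calls.values())
    else:
        genera = {c.assigned_genus for c in calls}
    return len(genera - {UNCLASSIFIED})
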