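"""OTU calling from joint band patterns and the abundance table.

Two clones belong to the same OTU iff their gel band patterns are equal for
every enzyme used (both MspI and HaeIII in the default screen).  All
fuzziness lives upstream in the gel binning step, so pattern equality is
exact here and clustering is a deterministic partition of the clone set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .gel import BandPattern

__all__ = ["OTU", "AbundanceTable", "cluster_by_pattern", "singleton_count"]


@dataclass(frozen=True)
class OTU:
    """A cluster of clones sharing one joint restriction pattern."""

    otu_id: str
    members: tuple[str, ...]
    representative: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("OTU must have at least one member")
        if self.representative != min(self.members):
            raise ValueError("representative must be the lexicographically smallest member")


@dataclass
class AbundanceTable:
    """Ordered OTU -> clone-count map; the substrate for diversity statistics."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("all OTU counts must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def richness(self) -> int:
        return len(self.counts)

    def abundances(self) -> list[int]:
        return list(self.counts.values())

    @classmethod
    def from_counts(cls, counts: Sequence[int], prefix: str = "OTU") -> "AbundanceTable":
        return cls({f"{prefix}_{i + 1:03d}": int(c) for i, c in enumerate(counts)})

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AbundanceTable":
        counts: dict[str, int] = {}
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                counts[row["otu_id"]] = int(row["count"])
        return cls(counts)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["otu_id", "count"])
            for otu_id, count in self.counts.items():
                writer.writerow([otu_id, count])


def cluster_by_pattern(
    patterns: Mapping[str, Sequence[BandPattern]]
) -> tuple[list[OTU], AbundanceTable]:
    """Partition clones into OTUs by exact joint-pattern equality.

    ``patterns`` maps each clone id to its per-enzyme band patterns (one per
    enzyme, same enzyme set for every clone).  OTUs are ordered by
    descending clone count, ties broken by representative id, and named
    OTU_001, OTU_002, ...
    """
    if not patterns:
        raise ValueError("no clones to cluster")
    enzyme_sets = {tuple(p.enzyme_name for p in pats) for pats in patterns.values()}
    if len(enzyme_sets) != 1:
        raise ValueError(f"clones digested with differing enzyme sets: {enzyme_sets}")
    n_enzymes = len(next(iter(enzyme_sets)))
    groups: dict[tuple, list[str]] = {}
    for clone_id, pats in patterns.items():
        if len(pats) != n_enzymes:
            raise ValueError(f"clone {clone_id!r} missing a band pattern")
        key = tuple((p.enzyme_name, p.bands) for p in pats)
        groups.setdefault(key, []).append(clone_id)

    members_sorted = sorted(
        (sorted(m) for m in groups.values()), key=lambda m: (-len(m), m[0])
    )
    otus = [
        OTU(otu_id=f"OTU_{i + 1:03d}", members=tuple(m), representative=m[0])
        for i, m in enumerate(members_sorted)
    ]
    table = AbundanceTable({o.otu_id: len(o.members) for o in otus})
    return otus, table


def singleton_count(table: AbundanceTable) -> int:
    """Number of OTUs represented by exactly one clone."""
    if not table.counts:
        raise ValueError("empty abundance table")
    return sum(1 for c in table.counts.values() if c == 1)


def write_membership(otus: Sequence[OTU], path: str | Path) -> None:
    """Export OTU membership as TSV (otu_id, representative, comma-joined members)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["otu_id", "representative", "members"])
        for otu in otus:
            writer.writerow([otu.otu_id, otu.representative, ",".join(otu.members)])
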