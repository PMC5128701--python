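"""Restriction digestion and the agarose-gel observability model (ARDRA).

A clone's ARDRA fingerprint is the band pattern its digested amplicon shows
on a 2% agarose gel.  Two rules turn exact fragment lengths into
gel-observable bands: fragments shorter than ``min_observable_bp`` (default
100 bp) are invisible, and sizes are binned on a fixed grid
(``size_bin_bp``, default 20 bp) so that co-migrating fragments collapse to
one band.  Fixed-grid binning (rather than a pairwise +/- tolerance) makes
band-pattern equality a true equivalence relation, so OTU clustering on
patterns is transitive and order-independent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seqs import SequenceRecord, reverse_complement

__all__ = [
    "Enzyme",
    "MSP_I",
    "HAE_III",
    "GelModel",
    "BandPattern",
    "digest",
    "to_band_pattern",
    "band_pattern",
    "load_enzymes",
    "write_patterns",
]


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease cutting before ``cut_offset`` in its site."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if not rec or set(rec) - set("ACGT"):
            raise ValueError(f"{self.name}: recognition must be non-degenerate DNA")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(f"{self.name}: cut_offset outside recognition site")
        object.__setattr__(self, "recognition", rec)

    @property
    def palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)


# The two four-cutters used to screen the clone library.
MSP_I = Enzyme("MspI", "CCGG", 1)    # C^CGG
HAE_III = Enzyme("HaeIII", "GGCC", 2)  # GG^CC


@dataclass(frozen=True)
class GelModel:
    """Observability rules of the gel: detection floor and size resolution."""

    min_observable_bp: int = 100
    size_bin_bp: int = 20

    def __post_init__(self) -> None:
        if self.min_observable_bp < 0:
            raise ValueError("min_observable_bp must be >= 0")
        if self.size_bin_bp < 1:
            raise ValueError("size_bin_bp must be >= 1")

    def bin(self, size_bp: int) -> int:
        """Nearest multiple of ``size_bin_bp``, half rounded up."""
        return ((size_bp * 2 + self.size_bin_bp) // (2 * self.size_bin_bp)) * self.size_bin_bp


@dataclass(frozen=True)
class BandPattern:
    """Gel-observable fingerprint: strictly increasing binned band sizes."""

    enzyme_name: str
    bands: tuple[int, ...]

    def __post_init__(self) -> None:
        if list(self.bands) != sorted(set(self.bands)):
            raise ValueError("bands must be strictly increasing and unique")


def _cut_positions(seq: str, enzyme: Enzyme) -> list[int]:
    positions: set[int] = set()
    site = enzyme.recognition
    start = seq.find(site)
    while start != -1:
        positions.add(start + enzyme.cut_offset)
        start = seq.find(site, start + 1)
    if not enzyme.palindromic:
        # non-palindromic sites also occur on the bottom strand
        rc_site = reverse_complement(site)
        start = seq.find(rc_site)
        while start != -1:
            positions.add(start + len(site) - enzyme.cut_offset)
            start = seq.find(rc_site, start + 1)
    return sorted(p for p in positions if 0 < p < len(seq))


def digest(seq: SequenceRecord | str, enzyme: Enzyme) -> list[int]:
    """Fragment lengths (positional order) from a complete digestion.

    Fragment lengths always sum to the input length; a site-free sequence
    yields a single fragment.  Degenerate bases are rejected because the
    presence of a site would be ambiguous.
    """
    s = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"cannot digest degenerate bases {sorted(bad)!r}")
    cuts = _cut_positions(s, enzyme)
    bounds = [0, *cuts, len(s)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def to_band_pattern(
    fragments: Sequence[int], enzyme_name: str, gel: GelModel = GelModel()
) -> BandPattern:
    """Apply the gel model: drop sub-detection fragments, bin, deduplicate."""
    if any(f <= 0 for f in fragments):
        raise ValueError("fragment lengths must be positive")
    observable = sorted({gel.bin(f) for f in fragments if f >= gel.min_observable_bp})
    return BandPattern(enzyme_name=enzyme_name, bands=tuple(observable))


def band_pattern(
    seq: SequenceRecord | str, enzyme: Enzyme, gel: GelModel = GelModel()
) -> BandPattern:
    """Digest then apply the gel model in one step."""
    return to_band_pattern(digest(seq, enzyme), enzyme.name, gel)


def load_enzymes(path: str | Path) -> list[Enzyme]:
    """Read extra enzymes from a TSV with columns name, recognition, cut_offset."""
    enzymes = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            enzymes.append(
                Enzyme(row["name"], row["recognition"], int(row["cut_offset"]))
            )
    return enzymes


def write_patterns(
    patterns: dict[str, Iterable[BandPattern]], path: str | Path
) -> None:
    """Export per-clone patterns as TSV (clone_id, enzyme, comma-joined bands)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["clone_id", "enzyme", "bands_bp"])
        for clone_id, pats in patterns.items():
            for pat in pats:
                writer.writerow(
                    [clone_id, pat.enzyme_name, ",".join(map(str, pat.bands))]
                )
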