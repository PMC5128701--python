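"""In-silico PCR: degenerate-primer site search and amplicon extraction.

The default primer pair targets the archaeal 16S rRNA gene: forward 21F
(TTCCGGTTGATCCYGCCGGA) and reverse 958R (YCCGGCGTTGCCAATT), giving the
~950 bp partial gene the clone libraries are built from.  Degeneracy is
resolved with IUPAC sets, not counted as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqs import IUPAC_SETS, SequenceRecord, reverse_complement

__all__ = [
    "FORWARD_21F",
    "REVERSE_958R",
    "PrimerPair",
    "Amplicon",
    "AmplificationError",
    "find_sites",
    "amplify",
]

FORWARD_21F = "TTCCGGTTGATCCYGCCGGA"
REVERSE_958R = "YCCGGCGTTGCCAATT"


class AmplificationError(RuntimeError):
    """No in-silico product could be formed on a template."""


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3' on their strands."""

    forward: str = FORWARD_21F
    reverse: str = REVERSE_958R
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise ValueError(f"{name} primer shorter than 10 nt")
            bad = set(p.upper()) - set(IUPAC_SETS)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC chars {sorted(bad)!r}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class Amplicon:
    """A PCR product in forward-primer orientation.

    ``start``/``end`` are 0-based half-open coordinates on the template as
    given.  For a plus-strand product ``residues == template[start:end]``;
    when the template was supplied in the opposite orientation (``strand ==
    "-"``) the product is the reverse complement of that slice, so that
    ``residues`` always begins with the forward primer.
    """

    template_id: str
    start: int
    end: int
    residues: str
    strand: str = "+"

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def header(self) -> str:
        """FASTA header with 1-based inclusive coordinates."""
        suffix = "" if self.strand == "+" else "_rc"
        return f"{self.template_id}_{self.start + 1}-{self.end}{suffix}"


def find_sites(
    template: SequenceRecord | str, primer: str, max_mismatches: int = 0
) -> list[tuple[int, int]]:
    """All primer binding positions on the given strand.

    Returns ``(start, mismatch_count)`` pairs in ascending order; a template
    base matches when it lies in the primer base's IUPAC degeneracy set.
    """
    seq = template.residues if isinstance(template, SequenceRecord) else template.upper()
    primer = primer.upper()
    sites: list[tuple[int, int]] = []
    for start in range(len(seq) - len(primer) + 1):
        mismatches = 0
        for p, t in zip(primer, seq[start : start + len(primer)]):
            if t not in IUPAC_SETS[p]:
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            sites.append((start, mismatches))
    return sites


def _product_span(seq: str, primers: PrimerPair) -> tuple[int, int] | None:
    """(start, end) of the product on this strand, or None.

    The product runs from the 5'-most forward-primer site to the end of the
    nearest downstream reverse-primer site (the reverse primer matched as
    its reverse complement); with several candidates the shortest product
    from the 5'-most forward site is taken, keeping the result
    deterministic.
    """
    fwd_sites = find_sites(seq, primers.forward, primers.max_mismatches)
    if not fwd_sites:
        return None
    fwd_start = fwd_sites[0][0]
    rev_on_template = reverse_complement(primers.reverse)
    min_len = len(primers.forward) + len(primers.reverse)
    for rev_start, _ in find_sites(seq, rev_on_template, primers.max_mismatches):
        end = rev_start + len(rev_on_template)
        if end - fwd_start >= min_len:
            return fwd_start, end
    return None


def amplify(template: SequenceRecord, primers: PrimerPair = PrimerPair()) -> Amplicon:
    """Extract the product the primer pair would amplify from a template.

    Both orientations of the template are considered (PCR does not care
    which strand a clone insert was reported on); the product is always
    returned 5'->3' from the forward primer.  Primers are included in the
    product.
    """
    span = _product_span(template.residues, primers)
    if span is not None:
        start, end = span
        return Amplicon(
            template_id=template.id,
            start=start,
            end=end,
            residues=template.residues[start:end],
        )
    rc = reverse_complement(template.residues)
    span = _product_span(rc, primers)
    if span is not None:
        s, e = span
        length = len(template.residues)
        return Amplicon(
            template_id=template.id,
            start=length - e,
            end=length - s,
            residues=rc[s:e],
            strand="-",
        )
    raise AmplificationError(
        f"{template.id}: no forward/reverse primer site pair on either strand"
    )
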