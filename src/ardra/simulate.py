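"""Seeded generator of mock archaeal clone libraries with known ground truth.

The generator emulates the statistical shape of a hypersaline crystallizer
clone library: ~26 lineages spread over ~15 genera, per-lineage clone
counts following the bundled frequency table, reference identities spanning
90-100%, and a few injected midpoint-fusion chimeras.  Reference
"backbones" are random sequences at haloarchaeal-like ~60% GC with real
primer-binding sites embedded, so the in-silico PCR, digestion, clustering,
classification and phylogeny stages all run end to end without any external
data.  Lineages are guaranteed pattern-distinct under the default gel
model, which makes OTU recovery an exact, checkable ground truth.

Sequences are indel-free by default so they are trivially aligned for the
phylogeny stage; an indel mode exists for alignment-robustness tests of the
identity computation only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import UNCLASSIFIED, ReferenceDB
from .fixtures import load_table1
from .gel import GelModel, HAE_III, MSP_I, band_pattern
from .otu import OTU
from .pcr import FORWARD_21F, REVERSE_958R, PrimerPair, amplify
from .seqs import IUPAC_SETS, SequenceRecord, identity_pct, reverse_complement, write_fasta

__all__ = ["CommunitySpec", "SyntheticLibrary", "generate", "truth_compare"]

_BASES = np.array(list("ACGT"))
#: haloarchaeal 16S genes are GC rich; backbones are drawn at ~60% GC
_BASE_PROBS = np.array([0.2, 0.3, 0.3, 0.2])
_FLANK_BP = 25
CHIMERA_LINEAGE = "chimera"


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of the mock community; defaults mirror the bundled table."""

    n_lineages: int = 26
    abundances: tuple[int, ...] | None = None  # default: bundled table counts
    theta: float | None = None  # geometric-series alternative to explicit counts
    n_genera: int = 15
    seq_length: int = 937
    divergence_from_ref: tuple[float, ...] | None = None  # identity targets in [0.9, 1]
    n_chimeras: int = 3
    within_lineage_mutations: int = 0
    indels: bool = False
    seed: int = 0

    def resolved_abundances(self) -> list[int]:
        if self.abundances is not None:
            if len(self.abundances) != self.n_lineages:
                raise ValueError("abundances length must equal n_lineages")
            if any(a < 1 for a in self.abundances):
                raise ValueError("abundances must be >= 1")
            return list(self.abundances)
        if self.theta is not None:
            # geometric rank-abundance series, truncated at 1 clone
            return [max(1, round(100 * self.theta * (1 - self.theta) ** i))
                    for i in range(self.n_lineages)]
        table = load_table1()
        if self.n_lineages != len(table):
            raise ValueError(
                "explicit abundances (or theta) required when n_lineages "
                f"differs from the bundled table ({len(table)} lineages)"
            )
        return table["count"].tolist()

    def resolved_identity_targets(self) -> list[float]:
        if self.divergence_from_ref is not None:
            targets = list(self.divergence_from_ref)
            if len(targets) != self.n_lineages:
                raise ValueError("divergence_from_ref length must equal n_lineages")
        elif self.n_lineages == 26:
            targets = [x / 100.0 for x in load_table1()["best_match_identity_pct"]]
        else:
            targets = list(np.linspace(0.90, 1.0, self.n_lineages))
        if any(not 0.0 <= t <= 1.0 for t in targets):
            raise ValueError("identity targets must lie in [0, 1]")
        return targets


@dataclass
class SyntheticLibrary:
    """Clones plus labelled references plus a per-clone ground-truth table."""

    clones: list[SequenceRecord]
    references: ReferenceDB
    truth: pd.DataFrame  # clone_id, true_lineage, true_genus, is_chimera
    spec: CommunitySpec

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.clones, outdir / "clones.fasta")
        write_fasta(self.references.records, outdir / "references.fasta")
        with open(outdir / "reference_labels.tsv", "w") as fh:
            fh.write("ref_id\tgenus\tfamily\n")
            for rec in self.references.records:
                genus, family = self.references.labels[rec.id]
                fh.write(f"{rec.id}\t{genus}\t{family}\n")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length, p=_BASE_PROBS))


def _resolve_degenerate(rng: np.random.Generator, primer: str) -> str:
    return "".join(
        b if b in "ACGT" else rng.choice(sorted(IUPAC_SETS[b])) for b in primer
    )


def _lineage_plan(spec: CommunitySpec) -> tuple[list[str], list[str], list[str]]:
    """(lineage names, lineage genus, genus list) for the requested sizes."""
    if spec.n_lineages == 26 and spec.n_genera == 15:
        table = load_table1()
        return (
            table["otu"].tolist(),
            table["genus"].tolist(),
            sorted(set(table["genus"]) - {UNCLASSIFIED}),
        )
    genera = [f"Genus{i + 1:02d}" for i in range(spec.n_genera)]
    names = [f"L{i + 1:02d}" for i in range(spec.n_lineages)]
    lineage_genus = [genera[i % spec.n_genera] for i in range(spec.n_lineages)]
    return names, lineage_genus, genera


def _amplifies_exactly(template: SequenceRecord, primers: PrimerPair,
                       expected: str, offset: int) -> bool:
    try:
        amp = amplify(template, primers)
    except Exception:
        return False
    return amp.start == offset and amp.residues == expected


def generate(spec: CommunitySpec, gel: GelModel = GelModel()) -> SyntheticLibrary:
    """Build a fully reproducible mock library from a community spec.

    Each lineage is derived from its genus backbone by point mutations
    hitting its identity target within +/-0.3 points, re-sampled (up to 100
    attempts) until its joint MspI+HaeIII band pattern differs from every
    other lineage's under the gel model.  Chimeras are midpoint fusions of
    two distinct reference amplicons with mutual identity <= 90%.
    """
    rng = np.random.default_rng(spec.seed)
    primers = PrimerPair()
    abundances = spec.resolved_abundances()
    identity_targets = spec.resolved_identity_targets()
    names, lineage_genus, genera = _lineage_plan(spec)
    interior_len = spec.seq_length - len(FORWARD_21F) - len(REVERSE_958R)
    if interior_len < 100:
        raise ValueError("seq_length too short to host both primers")

    def gel_plausible(seq: str, lo: int = 3, hi: int = 10) -> bool:
        # digests of real ~950 bp 16S amplicons show 3-10 observable bands;
        # mock backbones are resampled until they look the same on the gel
        return all(
            lo <= len(band_pattern(seq, enz, gel).bands) <= hi
            for enz in (MSP_I, HAE_III)
        )

    # genus backbones with embedded primer-binding sites
    backbones: dict[str, str] = {}
    templates_flanks: dict[str, tuple[str, str]] = {}
    for genus in genera:
        for _ in range(300):
            fwd = _resolve_degenerate(rng, FORWARD_21F)
            rev = _resolve_degenerate(rng, REVERSE_958R)
            amplicon = fwd + _random_seq(rng, interior_len) + reverse_complement(rev)
            flank5, flank3 = _random_seq(rng, _FLANK_BP), _random_seq(rng, _FLANK_BP)
            template = SequenceRecord(f"tmp_{genus}", flank5 + amplicon + flank3)
            if _amplifies_exactly(template, primers, amplicon, _FLANK_BP) and gel_plausible(
                amplicon, 3, 8
            ):
                backbones[genus] = amplicon
                templates_flanks[genus] = (flank5, flank3)
                break
        else:
            raise RuntimeError(f"could not build an amplifiable backbone for {genus}")

    # assign a backbone to every lineage; unclassified lineages borrow one
    backbone_of: list[str] = []
    cycle = itertools.cycle(genera)
    for genus in lineage_genus:
        backbone_of.append(genus if genus in backbones else next(cycle))

    def joint_pattern(seq: str):
        return (band_pattern(seq, MSP_I, gel).bands, band_pattern(seq, HAE_III, gel).bands)

    lineage_seqs: dict[str, str] = {}
    seen_patterns: set[tuple] = set()
    mutable = np.arange(len(FORWARD_21F), len(FORWARD_21F) + interior_len)
    for name, genus_bb, target in zip(names, backbone_of, identity_targets):
        base = backbones[genus_bb]
        n_mut = round((1.0 - target) * spec.seq_length)
        for attempt in range(100):
            seq = _mutate(rng, base, mutable, n_mut)
            if spec.indels:
                seq = _apply_indels(rng, seq, len(FORWARD_21F), interior_len)
            flank5, flank3 = templates_flanks[genus_bb]
            template = SequenceRecord(f"tmp_{name}", flank5 + seq + flank3)
            if not _amplifies_exactly(template, primers, seq, _FLANK_BP):
                continue
            pat = joint_pattern(seq)
            if pat in seen_patterns or not gel_plausible(seq):
                continue
            lineage_seqs[name] = seq
            seen_patterns.add(pat)
            break
        else:
            raise RuntimeError(
                f"no pattern-distinct variant found for lineage {name} after 100 "
                "attempts; try a larger seq_length or finer gel bins"
            )

    # reference database (amplicon-region sequences, one per genus)
    ref_records = [SequenceRecord(f"REF_{g}", backbones[g]) for g in genera]
    family = _family_lookup(spec)
    refdb = ReferenceDB(
        ref_records, {f"REF_{g}": (g, family.get(g, "")) for g in genera}
    )

    clones: list[SequenceRecord] = []
    truth_rows: list[dict] = []
    for name, genus, count in zip(names, lineage_genus, abundances):
        genus_bb = backbone_of[names.index(name)]
        flank5, flank3 = templates_flanks[genus_bb]
        for c in range(count):
            seq = lineage_seqs[name]
            if spec.within_lineage_mutations > 0:
                seq = _mutate(rng, seq, mutable, spec.within_lineage_mutations)
            clone_id = f"{name}_c{c + 1:02d}"
            clones.append(SequenceRecord(clone_id, flank5 + seq + flank3))
            truth_rows.append(
                {"clone_id": clone_id, "true_lineage": name,
                 "true_genus": genus, "is_chimera": False}
            )

    # midpoint-fusion chimeras between well-separated references
    pairs = [(a, b) for a, b in itertools.combinations(genera, 2)]
    rng.shuffle(pairs)
    made = 0
    for g1, g2 in pairs:
        if made >= spec.n_chimeras:
            break
        if identity_pct(backbones[g1], backbones[g2]) > 90.0:
            continue
        mid = spec.seq_length // 2
        seq = backbones[g1][:mid] + backbones[g2][mid:]
        flank5, flank3 = templates_flanks[g1]
        template = SequenceRecord(f"CHIM_{made + 1:02d}", flank5 + seq + flank3)
        if not _amplifies_exactly(template, primers, seq, _FLANK_BP):
            continue
        clones.append(template)
        truth_rows.append(
            {"clone_id": template.id, "true_lineage": CHIMERA_LINEAGE,
             "true_genus": CHIMERA_LINEAGE, "is_chimera": True}
        )
        made += 1
    if made < spec.n_chimeras:
        raise RuntimeError("could not place the requested number of chimeras")

    return SyntheticLibrary(
        clones=clones,
        references=refdb,
        truth=pd.DataFrame(truth_rows),
        spec=spec,
    )


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray, n_mut: int) -> str:
    if n_mut == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(positions, size=n_mut, replace=False):
        current = chars[pos]
        chars[pos] = rng.choice([b for b in "ACGT" if b != current])
    return "".join(chars)


def _apply_indels(rng: np.random.Generator, seq: str, start: int, span: int,
                  n_indels: int = 2) -> str:
    chars = list(seq)
    for _ in range(n_indels):
        pos = int(rng.integers(start + 10, start + span - 10))
        if rng.random() < 0.5:
            chars.insert(pos, str(rng.choice(_BASES)))
        else:
            del chars[pos]
    return "".join(chars)


def _family_lookup(spec: CommunitySpec) -> dict[str, str]:
    if spec.n_lineages == 26 and spec.n_genera == 15:
        table = load_table1()
        return dict(zip(table["genus"], table["family"]))
    return {}


def truth_compare(
    truth: pd.DataFrame, otus: Sequence[OTU]
) -> tuple[tuple[int, float], tuple[int, float]]:
    """Score OTU recovery against ground truth.

    Returns ``((lumping_count, lumping_rate), (splitting_count,
    splitting_rate))``: lumping counts unordered pairs of distinct true
    lineages co-occurring in one OTU (rate over all lineage pairs);
    splitting counts true lineages spread over more than one OTU (rate over
    lineages).
    """
    lineage_of = dict(zip(truth["clone_id"], truth["true_lineage"]))
    lineages = sorted(set(truth.loc[~truth["is_chimera"], "true_lineage"]))
    lumped_pairs: set[tuple[str, str]] = set()
    otus_of_lineage: dict[str, set[str]] = {}
    for otu in otus:
        members_lineages = set()
        for clone_id in otu.members:
            if clone_id not in lineage_of:
                raise ValueError(f"clone {clone_id!r} absent from the truth table")
            lin = lineage_of[clone_id]
            members_lineages.add(lin)
            otus_of_lineage.setdefault(lin, set()).add(otu.otu_id)
        for a, b in itertools.combinations(sorted(members_lineages), 2):
            lumped_pairs.add((a, b))
    n_pairs = len(lineages) * (len(lineages) - 1) // 2
    lumping = len(lumped_pairs)
    splitting = sum(1 for lin in lineages if len(otus_of_lineage.get(lin, set())) > 1)
    return (
        (lumping, lumping / n_pairs if n_pairs else 0.0),
        (splitting, splitting / len(lineages) if lineages else 0.0),
    )
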