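# Methods

This package reimplements, as tested code, the classic clone-library
workflow used to census archaeal diversity in a hypersaline crystallizer
pond: amplify a partial 16S rRNA gene from community DNA with
archaea-specific primers, fingerprint each cloned amplicon by restriction
digestion (ARDRA/RFLP), group clones with identical gel patterns into
OTUs, and summarize the community with coverage, entropy, rarefaction,
novelty and dominance statistics plus a neighbor-joining phylogeny. Every
stage is deterministic given its inputs and a seed.

## In-silico PCR

Primers are IUPAC strings; a template base binds a primer base when it
lies in the primer base's degeneracy set (degeneracy is never counted as a
mismatch; a separate `max_mismatches` budget, default 0, covers true
mismatches). Defaults are the archaeal pair 21F
(`TTCCGGTTGATCCYGCCGGA`) and 958R (`YCCGGCGTTGCCAATT`), which excise the
~950 bp partial gene the clone libraries carry. The product runs from the
5′-most forward site to the end of the nearest downstream reverse site
(primers included); among multiple candidates the shortest product from
the 5′-most forward site is taken so output is deterministic. Both
template orientations are searched and the product is always reported
5′→3′ from the forward primer, so a clone submitted on either strand gives
the same product. Whether real cloned inserts include primer sequence is
unknowable from length alone; primers-inclusive extraction is assumed.

## Digestion and the gel model

The two built-in four-cutters are MspI (`C^CGG`) and HaeIII (`GG^CC`).
Digestion cuts before `site_start + cut_offset` at every occurrence of the
recognition sequence; fragment lengths always sum to the input length.
Palindromic sites are scanned on one strand; user-supplied non-palindromic
enzymes are scanned on both.

What a 2% agarose gel can actually distinguish is modelled by two rules:

* fragments shorter than `min_observable_bp` (default 100 bp) are
  invisible and dropped **before** binning;
* observable sizes are binned to the nearest multiple of `size_bin_bp`
  (default 20 bp, round half up), and equal binned sizes collapse to one
  band (co-migration).

Fixed-grid binning was chosen over a pairwise ±tolerance deliberately:
grid equality is transitive, so "same pattern" is an equivalence relation
and OTU clustering is order-independent and unambiguous. The 20 bp grid
approximates agarose resolution in the 100–700 bp range where the real
fingerprints were read; the true visual-comparison tolerance of the
original gels is unknowable, so the grid width is this package's decree
and is configurable. No upper observable bound is imposed.

## OTU calling and diversity statistics

Two clones share an OTU iff their binned band lists are equal for MspI
**and** HaeIII. OTUs are ordered by descending abundance then
representative id. All fuzziness lives in the binning step; clustering
itself is exact.

From the abundance table (counts `N_i`, total `N`, richness `S`,
singletons `n`):

* Good's coverage `C = (1 − n/N) × 100`, with "unique clones" read as
  singleton OTUs (the standard Good estimator);
* Shannon `H = −Σ p_i ln p_i`, `p_i = N_i/N`, natural log, so `H ≤ ln S`;
* rarefaction `E[S_m] = Σ_i [1 − C(N−N_i, m)/C(N, m)]` — the exact
  hypergeometric (Hurlbert) expectation, evaluated with exact integer
  binomials (`math.comb`), so there is no overflow or cancellation at any
  library size of interest. A seeded Monte-Carlo subsampler exists for
  cross-checking only.

## Classification and the chimera screen

Nearest-reference assignment replaces the original remote BLAST step with
end-gap-free global-alignment identity against a local labelled FASTA.
Alignment is Needleman–Wunsch (match +1, mismatch −1, linear gap −2,
configurable); identity is 100 × matches / columns, excluding columns in a
terminal-gap overhang of either sequence — the natural behaviour when
comparing partial reads of unequal length. Among co-optimal alignments the
traceback is steered toward terminal (rather than internal) gap placement
by an infinitesimal end-gap bonus far below the scoring granularity, then
the reported score is recomputed exactly under the stated scheme; this
keeps both the score exact and the identity well-defined. Pairwise
identity is treated as a property of the unordered sequence pair: operands
are canonicalized (lexicographically smaller first) before aligning, so
identity is exactly symmetric even where co-optimal alignments with
different column structures exist. A clone is
**novel** below 97% identity (strictly less; the conventional
species-level 16S cutoff) and inherits its best reference's genus at ≥90%
identity (a configurable floor — the original study assigned genera by
BLAST affiliation plus tree placement, which has no single threshold).

The chimera screen is a deliberate simplification of database
chimera-checking tools: split each clone at its midpoint, find the best
reference for each half and for the full sequence, and flag iff the halves'
best references differ **and** the weaker half beats the full-length best
identity by at least `margin` (default 3 percentage points). It is labelled
a screen, not a proof: it sees only two-parent midpoint-style fusions,
which is also exactly what the synthetic generator injects. Alignments are
cached by residue string, which matters because clone libraries contain
many identical sequences.

Dominance reports per-genus clone percentages (round half up for display;
≥10% marked dominant). The denominator can be overridden with an
externally stated library size so that published percentages computed on a
slightly different total can be replicated as printed.

## Phylogeny

Distances between pre-aligned sequences use pairwise deletion (columns
with a gap or ambiguity in either sequence are skipped) under p-distance
or Jukes–Cantor `d = −(3/4) ln(1 − 4p/3)`; JC raises beyond its p < 3/4
domain, naming the offending pair. Neighbor joining is the standard
Saitou–Nei agglomeration on the Q-criterion, ties broken toward the
smallest index pair, negative branch lengths clamped to zero with a
warning, final three lineages resolved directly (trees are unrooted;
rooting on a named outgroup leaf is a separate post-hoc operation).
Bootstrap resamples alignment columns with replacement (seeded NumPy
generator), rebuilds the NJ tree per replicate, and scores each internal
bipartition of the full-data tree by the percentage of replicates
containing it; the default display masks supports below 70% but all values
are stored. Trees are held as dendropy objects, so Newick serialization,
rerooting and bipartition encoding come from a standard toolkit while the
NJ algorithm itself is implemented here (and cross-checked against an
independent implementation in the tests). Multiple alignment is out of
scope: callers supply pre-aligned input, and the synthetic generator emits
indel-free sequences that are trivially aligned.

## The synthetic community generator

The generator is the package's test bed: it emulates the statistical
structure the analysis assumes so every stage can be validated against a
known truth, without downloading any sequence data.

* **Backbones.** One random reference sequence per genus (15 by default)
  at ~60% GC — haloarchaeal-like composition — with concrete
  primer-binding sites embedded and 25 bp random flanks so in-silico PCR
  has real work to do. Backbones are rejection-sampled until (a) the
  primers excise exactly the designed 937 bp amplicon and (b) both
  digests show 3–8 observable bands, matching what real ~950 bp
  haloarchaeal amplicons showed on the gel (purely random sequence at
  this GC is more site-dense than real 16S and would otherwise produce
  many sub-100 bp fragments).
* **Lineages.** 26 by default, each derived from its genus backbone by
  point mutations targeting the bundled table's identity spectrum
  (90–99%, hit within ±0.3 points by construction), re-sampled until its
  joint band pattern is distinct from every other lineage's and itself
  gel-plausible (3–10 bands). Distinctness makes "26 OTUs" a
  constructible ground truth; `truth_compare` exists precisely to measure
  what happens when that assumption is relaxed (e.g. coarser gel bins).
* **Abundances.** The bundled table's printed clone counts
  (20, 5, 4, 1, 17, … — 109 clones total) by default; an explicit vector
  or a geometric rank-abundance series are alternatives. Within-lineage
  noise defaults to 0 mutations so all copies of a lineage share one
  pattern, mirroring the determinism of a single cloned insert.
* **Chimeras.** 3 midpoint fusions of two distinct reference amplicons
  with mutual identity ≤90%, appended as clones — 112 records in all,
  reproducing the original library's shape (112 sequenced, 3 chimeric,
  109 analyzed).
* Everything derives from one NumPy seed; the same spec and seed produce
  byte-identical FASTA/TSV outputs.

What the generator does **not** emulate: tree-structured sequence
evolution (lineages are star-like around their backbone), rate
heterogeneity, indels (off by default; an indel mode exists only for
alignment-robustness tests of the identity computation), chimera formation
at arbitrary breakpoints, and partial digestion or gel artifacts. Passing
recovery tests therefore show the pipeline's bookkeeping and numerics are
correct under the stated assumptions — not that ARDRA itself resolves
arbitrary natural communities, where distinct lineages genuinely can share
band patterns (that failure mode is what `truth_compare` quantifies).

Because unrelated random backbones sit near p ≈ 0.75, Jukes–Cantor
distances are undefined between mock genera; trees over synthetic data use
p-distance, while JC remains the default for real, related sequences.

## Replication of the published statistics

`replicate_printed_table()` reruns the sequence-free statistics directly
on the bundled 26-OTU frequency table with the stated 109-clone
denominator: 26 OTUs, 10 singletons, 15 named genera, Halanaeroarchaeum
28% and Halorubrum 23% of clones, and 14/26 ≈ 53.8% novel OTUs — all as
published. Two published values are deliberately reported as
**not reproducible** rather than matched: the stated coverage of 86%
conflicts with the stated formula (with n = 10 and N = 109 it gives
90.8%), and the stated Shannon index of 5.24 exceeds ln 26 ≈ 3.26, the
mathematical maximum for 26 OTUs (the computed value is 2.70 nats). The
formulas, not the printed numbers, are treated as normative, and the
report flags the discrepancies explicitly.

## Problem sizes and numerical choices

The default analyses run a 112-clone, 15-reference library: the chimera
screen is the heavy step (three cached global alignments per unique
sequence against 15 references, a few seconds), and the full pipeline
completes in well under a minute; the bootstrap tree over 41 leaves at
1000 replicates takes about half a minute. Exact rarefaction is used
everywhere (Monte-Carlo only as a cross-check); alignment scoring is
integer-valued so score comparisons in tests are exact; NJ tie-breaks and
OTU ordering are lexicographic so every artifact is byte-reproducible
under a fixed seed and config (the run log records a config hash).
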