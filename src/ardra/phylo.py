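"""Distance matrices, neighbor joining and bootstrap support.

Distances between aligned 16S sequences are computed with pairwise deletion
(columns where either sequence has a gap or ambiguous base are skipped) as
either raw p-distance or the Jukes-Cantor correction
d = -(3/4) ln(1 - 4p/3).  Trees are built with the Saitou-Nei
neighbor-joining algorithm and held as unrooted dendropy trees, so Newick
I/O, rerooting on an outgroup and topology comparison use a standard
toolkit.  Bootstrap supports are percentages of column-resampled replicates
containing each internal bipartition of the full-data tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from Bio import SeqIO

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "read_alignment",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if np.any(d < 0) or np.any(np.diag(d) != 0) or not np.allclose(d, d.T):
            raise ValueError("matrix must be symmetric, nonnegative, zero-diagonal")
        object.__setattr__(self, "d", d)


@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths and optional bootstrap supports.

    Internal node labels carry integer bootstrap percentages once
    :func:`bootstrap_support` has run.
    """

    tree: dendropy.Tree

    @property
    def leaf_names(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def as_newick(self, mask_support_below: float | None = None) -> str:
        tree = self.tree
        if mask_support_below is not None:
            tree = self.tree.clone(depth=1)
            for nd in tree.preorder_internal_node_iter():
                if nd.label is not None and float(nd.label) < mask_support_below:
                    nd.label = None
        return tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path: str | Path, mask_support_below: float | None = None) -> None:
        Path(path).write_text(self.as_newick(mask_support_below) + "\n")

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.is_rooted = False
        return cls(tree)

    def root_on_outgroup(self, leaf_name: str) -> "PhyloTree":
        """Return a copy rerooted on the edge leading to the named leaf."""
        tree = self.tree.clone(depth=1)
        node = tree.find_node_with_taxon_label(leaf_name)
        if node is None:
            raise ValueError(f"no leaf named {leaf_name!r}")
        length = node.edge.length or 0.0
        tree.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2)
        tree.is_rooted = True
        return PhyloTree(tree)


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA (gaps allowed) as (id, sequence) pairs."""
    pairs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not pairs:
        raise ValueError(f"no records in {path}")
    return pairs


def _seq_array(seqs: Sequence[tuple[str, str]]) -> tuple[tuple[str, ...], np.ndarray]:
    ids = tuple(i for i, _ in seqs)
    lengths = {len(s) for _, s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths {sorted(lengths)}")
    arr = np.array([list(s) for _, s in seqs])
    return ids, arr


def distance_matrix(
    seqs: Sequence[tuple[str, str]], model: str = "jc"
) -> DistanceMatrix:
    """Pairwise distances over equal-length sequences with pairwise deletion.

    ``model`` is "p" (proportion of differing sites) or "jc" (Jukes-Cantor);
    JC is undefined when p >= 3/4 and raises, naming the offending pair.
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    if model not in {"p", "jc"}:
        raise ValueError(f"unknown model {model!r}")
    ids, arr = _seq_array(seqs)
    valid = np.isin(arr, list("ACGT"))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            p = float((arr[i][both] != arr[j][both]).sum()) / compared
            if model == "p":
                dist = p
            else:
                if p >= 0.75:
                    raise ValueError(
                        f"Jukes-Cantor undefined for {ids[i]} vs {ids[j]} (p={p:.3f})"
                    )
                dist = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=ids, d=d)


def _clamped(length: float, context: str) -> float:
    if length < 0:
        warnings.warn(f"negative branch length {length:.4g} at {context} clamped to 0")
        return 0.0
    return length


def neighbor_joining(
    dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q_ij = (n-2) d_ij - r_i - r_j is
    joined; ties go to the smallest (i, j) index pair in the current working
    matrix.  Negative branch lengths are clamped to zero with a warning.
    The final three lineages are resolved directly, leaving the conventional
    trifurcating unrooted tree.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    namespace = taxon_namespace or dendropy.TaxonNamespace(list(dm.taxa))
    nodes = [
        dendropy.Node(taxon=namespace.require_taxon(label)) for label in dm.taxa
    ]
    d = dm.d.copy()
    active = list(range(n))  # indices into rows of d / entries of nodes

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) among minima for determinism
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        qmin = q[i_loc, j_loc]
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        i_loc, j_loc = min((min(a, b), max(a, b)) for a, b in ties)
        i, j = active[i_loc], active[j_loc]

        dij = d[i, j]
        vi = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        vj = dij - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = _clamped(vi, dm.taxa[i] if i < n else "internal")
        nodes[j].edge.length = _clamped(vj, dm.taxa[j] if j < n else "internal")

        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row)] = new_row
        d[: len(new_row), -1] = new_row
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    root = dendropy.Node()
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for k, v in ((a, va), (b, vb), (c, vc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = _clamped(v, "final join")
    tree = dendropy.Tree(taxon_namespace=namespace, seed_node=root)
    tree.is_rooted = False
    return PhyloTree(tree)


def _internal_bitmasks(tree: dendropy.Tree) -> dict[int, dendropy.Node]:
    """Normalized split bitmasks of internal (non-trivial) edges."""
    tree.encode_bipartitions()
    out: dict[int, dendropy.Node] = {}
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        out[nd.edge.bipartition.split_bitmask] = nd
    return out


def bootstrap_support(
    seqs: Sequence[tuple[str, str]],
    model: str = "jc",
    replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree of the full alignment with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement ``replicates`` times
    (seeded); each internal bipartition's support is the percentage of
    replicate NJ trees containing it, stored as the node label.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ids, arr = _seq_array(seqs)
    full = neighbor_joining(distance_matrix(seqs, model=model))
    targets = _internal_bitmasks(full.tree)
    counts = {mask: 0 for mask in targets}
    rng = np.random.default_rng(seed)
    n_cols = arr.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = ["".join(row) for row in arr[:, cols]]
        rep = neighbor_joining(
            distance_matrix(list(zip(ids, resampled)), model=model),
            taxon_namespace=full.tree.taxon_namespace,
        )
        rep_masks = set(_internal_bitmasks(rep.tree))
        for mask in counts:
            if mask in rep_masks:
                counts[mask] += 1
    for mask, node in targets.items():
        node.label = str(round(100.0 * counts[mask] / replicates))
    return full
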