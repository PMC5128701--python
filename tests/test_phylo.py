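"""Distance models, neighbor joining, bootstrap and Newick round-trips."""

import itertools
import math
import warnings

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from ardra.phylo import (
    DistanceMatrix,
    PhyloTree,
    bootstrap_support,
    distance_matrix,
    neighbor_joining,
)


def _random_tree_matrix(rng, n):
    """A random additive matrix: path lengths of a random unrooted binary tree."""
    taxa = [f"t{i}" for i in range(n)]
    # random topology by repeated joining; leaf sets tracked per subtree
    subtrees = [(t, {t}) for t in taxa]
    newick_parts = dict((t, t) for t in taxa)
    lengths = {t: float(rng.uniform(0.05, 1.0)) for t in taxa}
    counter = 0
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        (na, sa), (nb, sb) = subtrees[i], subtrees[j]
        name = f"__in{counter}"
        counter += 1
        newick_parts[name] = (
            f"({newick_parts[na]}:{lengths[na]},{newick_parts[nb]}:{lengths[nb]})"
        )
        lengths[name] = float(rng.uniform(0.05, 1.0))
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append((name, sa | sb))
    (a, _), (b, _), (c, _) = subtrees
    newick = (
        f"({newick_parts[a]}:{lengths[a]},{newick_parts[b]}:{lengths[b]},"
        f"{newick_parts[c]}:{lengths[c]});"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n, n))
    taxon = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                d[i, j] = pdm.patristic_distance(taxon[a], taxon[b])
    return tree, DistanceMatrix(tuple(taxa), d)


def _rf(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=tree_a.as_string(schema="newick"), schema="newick",
                          taxon_namespace=ns)
    b = dendropy.Tree.get(data=tree_b.as_string(schema="newick"), schema="newick",
                          taxon_namespace=ns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b)


class TestDistanceMatrix:
    def test_identical_pair_zero_under_both_models(self):
        seqs = [("a", "ACGTACGT"), ("b", "ACGTACGT"), ("c", "ACGAACGA")]
        for model in ("p", "jc"):
            dm = distance_matrix(seqs, model)
            assert dm.d[0, 1] == 0.0

    def test_p_and_jc_closed_forms(self):
        seqs = [("a", "ACGT"), ("b", "ACGA"), ("c", "ACTT")]
        dm_p = distance_matrix(seqs, "p")
        assert dm_p.d[0, 1] == pytest.approx(0.25)
        dm_jc = distance_matrix(seqs, "jc")
        assert dm_jc.d[0, 1] == pytest.approx(-0.75 * math.log(1 - 1 / 3))

    def test_gap_columns_excluded_pairwise(self):
        seqs = [("a", "AC-T"), ("b", "ACGT"), ("c", "ACGA")]
        dm = distance_matrix(seqs, "p")
        assert dm.d[0, 1] == 0.0  # 3 comparable columns, all equal
        assert dm.d[1, 2] == pytest.approx(0.25)  # full 4 columns

    def test_jc_saturated_pair_raises_naming_pair(self):
        seqs = [("a", "AAAA"), ("b", "CCCC"), ("c", "AAAA")]
        with pytest.raises(ValueError, match="a vs b"):
            distance_matrix(seqs, "jc")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            distance_matrix([("a", "ACG"), ("b", "ACGT"), ("c", "ACGT")])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ("A", "B", "C"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        )
        tree = neighbor_joining(dm).tree
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_quartet_recovered_against_brute_force(self):
        # additive matrix of ((A:1,B:2):1,(C:3,D:4))
        dm = DistanceMatrix(
            ("A", "B", "C", "D"),
            np.array(
                [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
            ),
        )
        # brute force: least-squares fit of each of the 3 quartet topologies
        def quartet_ls(split):
            (a, b), (c, d) = split
            idx = {t: i for i, t in enumerate(dm.taxa)}
            # five branch lengths: la, lb, lc, ld, internal m
            import numpy.linalg as la

            rows, rhs = [], []
            pairs = {
                (a, b): [1, 1, 0, 0, 0],
                (c, d): [0, 0, 1, 1, 0],
                (a, c): [1, 0, 1, 0, 1],
                (a, d): [1, 0, 0, 1, 1],
                (b, c): [0, 1, 1, 0, 1],
                (b, d): [0, 1, 0, 1, 1],
            }
            for (x, y), row in pairs.items():
                rows.append(row)
                rhs.append(dm.d[idx[x], idx[y]])
            sol, res, *_ = la.lstsq(np.array(rows, float), np.array(rhs), rcond=None)
            fit = np.array(rows) @ sol
            return float(((fit - rhs) ** 2).sum())

        splits = [
            (("A", "B"), ("C", "D")),
            (("A", "C"), ("B", "D")),
            (("A", "D"), ("B", "C")),
        ]
        errors = {s: quartet_ls(s) for s in splits}
        best = min(errors, key=errors.get)
        assert best == (("A", "B"), ("C", "D"))
        assert errors[best] == pytest.approx(0.0, abs=1e-18)

        tree = neighbor_joining(dm)
        expected = PhyloTree.from_newick("((A:1,B:2):1,C:3,D:4);")
        assert _rf(tree.tree, expected.tree) == 0
        # exact branch lengths on the additive input
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_equidistant_matrix_joins_first_pair(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(("A", "B", "C", "D"), d)
        tree = neighbor_joining(dm).tree
        cherries = {
            tuple(sorted(lf.taxon.label for lf in nd.leaf_iter()))
            for nd in tree.preorder_internal_node_iter()
            if nd.parent_node is not None
        }
        assert ("A", "B") in cherries

    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(13)
        for n in (4, 5, 6, 7, 8):
            true_tree, dm = _random_tree_matrix(rng, n)
            nj = neighbor_joining(dm)
            assert _rf(nj.tree, true_tree) == 0
            # path-length matrix reproduces the input
            pdm = nj.tree.phylogenetic_distance_matrix()
            taxon = {t.label: t for t in nj.tree.taxon_namespace}
            for i, j in itertools.combinations(range(n), 2):
                got = pdm.patristic_distance(taxon[dm.taxa[i]], taxon[dm.taxa[j]])
                assert got == pytest.approx(dm.d[i, j], abs=1e-9)

    def test_agrees_with_independent_nj_implementation(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(29)
        _, dm = _random_tree_matrix(rng, 7)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(SkbioDM(dm.d, ids=list(dm.taxa)))
        theirs_dendropy = dendropy.Tree.get(data=str(theirs), schema="newick")
        assert _rf(ours.tree, theirs_dendropy) == 0

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            neighbor_joining(dm)


class TestNewick:
    def test_round_trip_preserves_topology_lengths_supports(self):
        newick = "((A:1.5,B:2.25)93:0.5,C:3.125,D:4.0);"
        tree = PhyloTree.from_newick(newick)
        again = PhyloTree.from_newick(tree.as_newick())
        assert _rf(tree.tree, again.tree) == 0
        for t in (tree, again):
            node = t.tree.find_node_with_taxon_label("A").parent_node
            assert node.label == "93"
            assert node.edge.length == pytest.approx(0.5)

    def test_support_masking_hides_weak_edges_only(self):
        tree = PhyloTree.from_newick("((A:1,B:1)45:1,(C:1,D:1)92:1,E:1);")
        masked = tree.as_newick(mask_support_below=70)
        assert "92" in masked and "45" not in masked
        # original keeps everything
        assert "45" in tree.as_newick()

    def test_rooting_on_outgroup(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,OUT:4);")
        rooted = tree.root_on_outgroup("OUT")
        children = rooted.tree.seed_node.child_nodes()
        assert len(children) == 2
        sides = [
            {lf.taxon.label for lf in c.leaf_iter()} for c in children
        ]
        assert {"OUT"} in sides


def _clade_alignment(rng, n_per_clade=3, length=240, sep_mut=80, within_mut=4):
    base = rng.choice(list("ACGT"), size=length)
    other = base.copy()
    idx = rng.choice(length, sep_mut, replace=False)
    for i in idx:
        other[i] = rng.choice([b for b in "ACGT" if b != other[i]])

    def variants(stem, root, k):
        out = []
        for v in range(k):
            s = root.copy()
            for i in rng.choice(length, within_mut, replace=False):
                s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
            out.append((f"{stem}{v}", "".join(s)))
        return out

    return variants("x", base, n_per_clade) + variants("y", other, n_per_clade)


class TestBootstrap:
    def test_fixed_seed_reproduces_supports(self):
        rng = np.random.default_rng(31)
        aln = _clade_alignment(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t1 = bootstrap_support(aln, replicates=100, seed=5)
            t2 = bootstrap_support(aln, replicates=100, seed=5)
        assert t1.as_newick() == t2.as_newick()

    def test_congruent_signal_gives_full_support(self):
        rng = np.random.default_rng(37)
        # two clearly separated clades, no homoplasy within
        aln = _clade_alignment(rng, n_per_clade=2, sep_mut=120, within_mut=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = bootstrap_support(aln, replicates=200, seed=2)
        supports = [
            int(nd.label)
            for nd in tree.tree.preorder_internal_node_iter()
            if nd.parent_node is not None and nd.label is not None
        ]
        assert supports and all(s == 100 for s in supports)

    def test_weak_edge_support_close_to_high_replicate_oracle(self):
        rng = np.random.default_rng(0)
        base = rng.choice(list("ACGT"), size=300)

        def mut(s, k):
            s = s.copy()
            for i in rng.choice(len(s), k, replace=False):
                s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
            return s

        aln = [
            ("t1", "".join(base)),
            ("t2", "".join(mut(base, 10))),
            ("t3", "".join(mut(base, 60))),
            ("t4", "".join(mut(base, 65))),
            ("t5", "".join(mut(base, 70))),
        ]

        def supports(tree):
            return {
                frozenset(lf.taxon.label for lf in nd.leaf_iter()): int(nd.label)
                for nd in tree.tree.preorder_internal_node_iter()
                if nd.parent_node is not None and nd.label is not None
            }

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            small = supports(bootstrap_support(aln, replicates=1000, seed=1))
            oracle = supports(bootstrap_support(aln, replicates=10000, seed=99))
        for clade, support in small.items():
            assert abs(support - oracle[clade]) <= 5

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support([("a", "ACGT"), ("b", "ACGT"), ("c", "ACGT")],
                              replicates=0)
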