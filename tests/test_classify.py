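"""Nearest-reference novelty calls, chimera screen, dominance and genus tallies."""

import numpy as np
import pytest

from ardra.classify import (
    ReferenceDB,
    dominance_report,
    genus_richness,
    nearest_reference,
    screen_chimeras,
)
from ardra.otu import AbundanceTable
from ardra.seqs import SequenceRecord


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(rng, seq, n_mut):
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_mut, replace=False):
        chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
    return "".join(chars)


@pytest.fixture(scope="module")
def refdb():
    rng = np.random.default_rng(17)
    records = [SequenceRecord(f"REF_{g}", _random_seq(rng, 900)) for g in "ABC"]
    labels = {r.id: (f"Genus{r.id[-1]}", "Fam") for r in records}
    return ReferenceDB(records, labels)


class TestNearestReference:
    def test_exact_copy_is_not_novel(self, refdb):
        clone = SequenceRecord("q", refdb.records[0].residues)
        call = nearest_reference(clone, refdb)
        assert call.best_ref_id == "REF_A"
        assert call.identity_pct == 100.0
        assert not call.is_novel
        assert call.assigned_genus == "GenusA"

    def test_exactly_97_percent_is_not_novel(self, refdb):
        # rule is strictly "less than 97%": mutate exactly 3% of columns
        rng = np.random.default_rng(1)
        ref = refdb.records[0].residues
        clone = SequenceRecord("q", _mutate(rng, ref, 27))  # 27/900 = 3%
        call = nearest_reference(clone, refdb)
        assert call.identity_pct == pytest.approx(97.0)
        assert not call.is_novel

    def test_ten_percent_mutated_is_novel_with_hamming_identity(self, refdb):
        rng = np.random.default_rng(2)
        ref = refdb.records[1].residues
        clone = SequenceRecord("q", _mutate(rng, ref, 90))
        # column-wise comparison oracle (no indels involved)
        hamming_identity = 100.0 * sum(
            a == b for a, b in zip(clone.residues, ref)
        ) / len(ref)
        call = nearest_reference(clone, refdb)
        assert call.best_ref_id == "REF_B"
        assert call.identity_pct == pytest.approx(hamming_identity) == 90.0
        assert call.is_novel
        assert call.assigned_genus == "GenusB"  # 90% is still >= genus floor

    def test_below_genus_floor_unclassified(self, refdb):
        rng = np.random.default_rng(3)
        clone = SequenceRecord("q", _mutate(rng, refdb.records[2].residues, 150))
        call = nearest_reference(clone, refdb, genus_threshold=90.0)
        assert call.is_novel
        assert call.assigned_genus == "Unclassified"


class TestChimeraScreen:
    def test_two_parent_fusion_flagged_with_parents(self, refdb):
        x, y = refdb.records[0].residues, refdb.records[1].residues
        clone = SequenceRecord("chim", x[:450] + y[450:])
        (call,) = screen_chimeras([clone], refdb)
        assert call.is_chimeric
        assert (call.parent_5prime, call.parent_3prime) == ("REF_A", "REF_B")
        # verify the halves really are their parents, by direct column count
        assert sum(a == b for a, b in zip(clone.residues[:450], x[:450])) == 450
        assert sum(a == b for a, b in zip(clone.residues[450:], y[450:])) == 450
        assert call.gain_pct >= 3.0

    def test_pure_clone_not_flagged(self, refdb):
        clone = SequenceRecord("pure", refdb.records[0].residues)
        (call,) = screen_chimeras([clone], refdb)
        assert not call.is_chimeric

    def test_lightly_mutated_clone_not_flagged(self, refdb):
        rng = np.random.default_rng(4)
        clone = SequenceRecord("m2", _mutate(rng, refdb.records[0].residues, 18))
        (call,) = screen_chimeras([clone], refdb)
        assert not call.is_chimeric  # halves cannot beat full match by >= 3 points

    def test_short_clone_skipped_with_warning(self, refdb):
        clone = SequenceRecord("tiny", "ACGTACGT")
        with pytest.warns(UserWarning, match="tiny"):
            calls = screen_chimeras([clone], refdb)
        assert calls == []

    def test_all_injected_chimeras_and_only_those_flagged(self, default_library):
        from ardra.pcr import amplify

        amps = [
            SequenceRecord(c.id, amplify(c).residues) for c in default_library.clones
        ]
        calls = screen_chimeras(amps, default_library.references)
        flagged = {c.clone_id for c in calls if c.is_chimeric}
        truly = set(
            default_library.truth.loc[default_library.truth.is_chimera, "clone_id"]
        )
        assert flagged == truly


class TestDominance:
    def test_two_genus_split(self):
        table = AbundanceTable({"A": 30, "B": 70})
        shares = dominance_report(table, {"A": "g1", "B": "g2"})
        assert [(s.genus, s.display_pct, s.dominant) for s in shares] == [
            ("g2", 70, True),
            ("g1", 30, True),
        ]

    def test_single_genus_is_everything(self):
        table = AbundanceTable({"A": 9})
        (share,) = dominance_report(table, {"A": "g"})
        assert share.clone_pct == 100.0

    def test_override_denominator_below_total_rejected(self):
        table = AbundanceTable({"A": 30, "B": 70})
        with pytest.raises(ValueError):
            dominance_report(table, {"A": "g1", "B": "g2"}, total_clones_override=50)

    def test_table1_halorubrum_23_pct_of_109(self, table1):
        table = AbundanceTable(dict(zip(table1["otu"], table1["count"])))
        genera = dict(zip(table1["otu"], table1["genus"]))
        shares = {s.genus: s for s in dominance_report(table, genera, 109)}
        assert shares["Halorubrum"].display_pct == 23
        assert shares["Halanaeroarchaeum"].display_pct == 28
        assert shares["Halanaeroarchaeum"].dominant

    def test_percentages_sum_to_100_without_override(self, table1):
        table = AbundanceTable(dict(zip(table1["otu"], table1["count"])))
        genera = dict(zip(table1["otu"], table1["genus"]))
        shares = dominance_report(table, genera)
        assert sum(s.clone_pct for s in shares) == pytest.approx(100.0)
        assert abs(sum(s.display_pct for s in shares) - 100) <= 2  # integer rounding

    def test_missing_genus_label_rejected(self):
        with pytest.raises(ValueError, match="OTUs without"):
            dominance_report(AbundanceTable({"A": 1, "B": 1}), {"A": "g"})


class TestGenusRichness:
    def test_counts_distinct_named_genera(self):
        assert genus_richness({"o1": "g1", "o2": "g1", "o3": "g2"}) == 2

    def test_unclassified_excluded(self):
        assert genus_richness({"o1": "Unclassified", "o2": "Unclassified"}) == 0

    def test_table1_yields_fifteen_genera(self, table1):
        assert genus_richness(dict(zip(table1["otu"], table1["genus"]))) == 15


def test_novel_fraction_of_table1_matches_abstract(table1):
    """14 of 26 OTUs sit below the 97% species cutoff: 53.8%, the reported
    53.9% within rounding."""
    novel_pct = 100.0 * (table1["best_match_identity_pct"] < 97).mean()
    assert novel_pct == pytest.approx(53.85, abs=0.2)
    assert abs(novel_pct - 53.9) <= 0.2
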