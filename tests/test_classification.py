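import numpy as np
import pytest

from clonalholes.classification import (
    classify_cd5,
    classify_dependence,
    cross_assign,
    public_paired,
    recurrent_clonotypes,
    subrepertoire_diversity,
    top_expanded,
)
from clonalholes.diversity import hill_diversity
from clonalholes.io import PairedCell, aggregate_paired
from clonalholes.model import Clonotype, PairedClonotype

from .conftest import make_table

CTRL = ["ctrl_1", "ctrl_2", "ctrl_3"]
MUT = ["mut_1", "mut_2", "mut_3"]


def clone(i):
    return Clonotype(f"TRAV{i + 1}", f"TRAJ{i + 1}", f"CAA{i:03d}F")


class TestRecurrence:
    def test_three_of_six_is_recurrent(self, two_group_table):
        rec = recurrent_clonotypes(two_group_table, min_samples=3)
        assert clone(1) in rec  # present in exactly 3 samples

    def test_two_of_six_is_not_recurrent(self, two_group_table):
        rec = recurrent_clonotypes(two_group_table, min_samples=3)
        assert clone(4) not in rec  # single-sample clone

    def test_min_samples_validation(self, two_group_table):
        with pytest.raises(ValueError):
            recurrent_clonotypes(two_group_table, min_samples=0)

    def test_presence_respects_min_umi(self, two_group_table):
        rec1 = recurrent_clonotypes(two_group_table, min_samples=3, min_umi=1)
        rec2 = recurrent_clonotypes(two_group_table, min_samples=3, min_umi=2)
        assert rec2 <= rec1


class TestDependence:
    def test_exclusive_presence_patterns(self, two_group_table):
        rec = recurrent_clonotypes(two_group_table)
        labels = classify_dependence(two_group_table, rec, CTRL, MUT)
        assert labels.label_of(clone(1)) == "dependent"   # 3 ctrl, 0 mut
        assert labels.label_of(clone(2)) == "newcomer"    # 0 ctrl, 3 mut
        assert labels.label_of(clone(3)) == "shared"      # 2 ctrl, 1 mut

    def test_partition_and_inclusion_exclusion_identity(self, two_group_table):
        rec = recurrent_clonotypes(two_group_table)
        labels = classify_dependence(two_group_table, rec, CTRL, MUT)
        assert labels.dependent | labels.shared | labels.newcomer == rec
        assert not (labels.dependent & labels.newcomer)
        assert (
            len(labels.present_in_a) + len(labels.present_in_b) - len(labels.shared)
            == len(rec)
        )

    def test_invariant_to_sample_order_and_count_magnitude(self, two_group_table):
        rec = recurrent_clonotypes(two_group_table)
        base = classify_dependence(two_group_table, rec, CTRL, MUT)
        # scaling counts does not change presence-based labels
        scaled = make_table(
            two_group_table.counts.to_numpy() * 17,
            [(s.sample_id, s.group, s.subset) for s in two_group_table.samples],
            clone_keys=list(two_group_table.counts.index),
        )
        again = classify_dependence(scaled, rec, list(reversed(CTRL)), MUT)
        assert again.dependent == base.dependent
        assert again.newcomer == base.newcomer

    def test_group_validation(self, two_group_table):
        rec = recurrent_clonotypes(two_group_table)
        with pytest.raises(ValueError):
            classify_dependence(two_group_table, rec, [], MUT)
        with pytest.raises(ValueError):
            classify_dependence(two_group_table, rec, CTRL, CTRL)
        with pytest.raises(ValueError):
            classify_dependence(two_group_table, rec, CTRL[:2], MUT)


class TestCD5:
    def _cd5_table(self, lo_pattern, hi_pattern):
        counts = [list(lo_pattern) + list(hi_pattern), [1] * 8]
        specs = [(f"lo_{i}", "control", "CD5lo") for i in range(4)] + [
            (f"hi_{i}", "control", "CD5hi") for i in range(4)
        ]
        return make_table(counts, specs)

    def test_three_of_four_lo_and_zero_hi_is_natural_lo(self):
        t = self._cd5_table([2, 1, 3, 0], [0, 0, 0, 0])
        labels = classify_cd5(t, t.subset_ids("CD5lo"), t.subset_ids("CD5hi"))
        assert labels.label_of(clone(0)) == "natural_lo"

    def test_any_presence_in_the_other_extreme_unassigns(self):
        t = self._cd5_table([2, 1, 3, 4], [1, 0, 0, 0])
        labels = classify_cd5(t, t.subset_ids("CD5lo"), t.subset_ids("CD5hi"))
        assert labels.label_of(clone(0)) == "unassigned"

    def test_reciprocal_pattern_is_natural_hi(self):
        t = self._cd5_table([0, 0, 0, 0], [5, 1, 2, 1])
        labels = classify_cd5(t, t.subset_ids("CD5lo"), t.subset_ids("CD5hi"))
        assert labels.label_of(clone(0)) == "natural_hi"
        assert not labels.natural_lo & labels.natural_hi

    def test_overlapping_subsets_rejected(self):
        t = self._cd5_table([1, 1, 1, 1], [0, 0, 0, 0])
        ids = t.subset_ids("CD5lo")
        with pytest.raises(ValueError):
            classify_cd5(t, ids, ids)


class TestCrossAssign:
    def _labels(self, two_group_table):
        rec = recurrent_clonotypes(two_group_table)
        return classify_dependence(two_group_table, rec, CTRL, MUT)

    def test_single_dependent_query_is_fully_dependent(self, two_group_table):
        xa = cross_assign({clone(1)}, self._labels(two_group_table))
        assert xa.fractions_matched["dependent"] == 1.0
        assert xa.n_unmatched == 0

    def test_unmatched_queries_warn_and_are_counted(self, two_group_table):
        stranger = Clonotype("TRAV99", "TRAJ99", "CXXXF")
        with pytest.warns(UserWarning):
            xa = cross_assign({stranger}, self._labels(two_group_table))
        assert xa.n_matched == 0 and xa.n_unmatched == 1

    def test_both_denominators_reported(self, two_group_table):
        stranger = Clonotype("TRAV99", "TRAJ99", "CXXXF")
        xa = cross_assign({clone(1), stranger}, self._labels(two_group_table))
        assert xa.fractions_matched["dependent"] == 1.0
        assert xa.fractions_all["dependent"] == 0.5

    def test_empty_query_rejected(self, two_group_table):
        with pytest.raises(ValueError):
            cross_assign(set(), self._labels(two_group_table))


class TestTopExpanded:
    def test_ranks_by_mean_relative_frequency(self):
        counts = [[50, 50], [30, 30], [20, 20]]
        t = make_table(counts, ["s1", "s2"])
        top = top_expanded(t, k=2)
        assert list(top["rank_freq"]) == pytest.approx([0.5, 0.3])

    def test_exact_tie_breaks_lexicographically(self):
        keys = [("TRAV2", "TRAJ1", "CAF"), ("TRAV1", "TRAJ1", "CAF")]
        t = make_table([[5], [5]], ["s1"], clone_keys=keys)
        top = top_expanded(t, k=1)
        assert top.index[0] == ("TRAV1", "TRAJ1", "CAF")

    def test_k_beyond_clonotypes_warns_and_returns_all(self):
        t = make_table([[3], [1]], ["s1"])
        with pytest.warns(UserWarning):
            top = top_expanded(t, k=10)
        assert len(top) == 2

    def test_pooled_ranking_weights_deep_samples(self):
        # clone 0 dominates the deep sample; pooled ranking must pick it up
        counts = [[90, 1], [10, 9]]
        t = make_table(counts, ["deep", "shallow"])
        pooled = top_expanded(t, k=1, pooled=True)
        assert pooled.index[0][0] == "TRAV1"


def _paired(n, v="TRAV14-1"):
    return PairedClonotype(
        alpha=Clonotype(v, "TRAJ2", f"CAL{n}F"),
        beta=Clonotype("TRBV5", "TRBJ1", f"CAS{n}F"),
    )


class TestPublicPaired:
    def test_clone_in_one_mouse_per_genotype_is_public(self):
        cells = [
            PairedCell("a1", "control", _paired(1)),
            PairedCell("b3", "mutant", _paired(1)),
            PairedCell("a1", "control", _paired(2)),
        ]
        shared = public_paired(aggregate_paired(cells), "control", "mutant")
        assert len(shared) == 1
        assert shared.loc[0, "n_mice_control"] == 1
        assert shared.loc[0, "n_mice_mutant"] == 1

    def test_no_overlap_gives_empty_result(self):
        cells = [
            PairedCell("a1", "control", _paired(1)),
            PairedCell("b1", "mutant", _paired(2)),
        ]
        shared = public_paired(aggregate_paired(cells), "control", "mutant")
        assert len(shared) == 0


class TestSubrepertoireDiversity:
    def test_full_subset_reproduces_unrestricted_diversity(self, two_group_table):
        allc = two_group_table.clonotypes
        sub = subrepertoire_diversity(two_group_table, allc)
        for sid in two_group_table.sample_ids:
            assert sub[sid] == pytest.approx(
                hill_diversity(two_group_table.vector(sid), 1)
            )

    def test_single_present_clone_gives_diversity_one(self, two_group_table):
        sub = subrepertoire_diversity(two_group_table, [clone(0)])
        assert sub["ctrl_1"] == pytest.approx(1.0)

    def test_equal_abundance_restriction(self):
        t = make_table([[4], [2], [2]], ["s1"])
        sub = subrepertoire_diversity(t, [clone(1), clone(2)])
        assert sub["s1"] == pytest.approx(2.0)

    def test_empty_restriction_is_undefined_not_an_error(self, two_group_table):
        sub = subrepertoire_diversity(two_group_table, [clone(1)])
        assert sub["mut_1"] is None  # dependent clone absent from mutants

    def test_empty_subset_rejected(self, two_group_table):
        with pytest.raises(ValueError):
            subrepertoire_diversity(two_group_table, [])
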