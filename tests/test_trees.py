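"""Schedule arithmetic, split frequencies, consensus, ASDSF, NJ, origin calls."""
from __future__ import annotations

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from algc4.records import TaxonGroup
from algc4.trees import (
    BipartitionTable,
    RunSchedule,
    TreeSampleSet,
    apply_burnin,
    asdsf,
    assign_origin,
    assign_origin_over_samples,
    bipartition_frequencies,
    expected_sample_count,
    majority_rule_consensus,
    neighbor_joining,
    nontrivial_splits,
)
from oracles import random_binary_topology, to_newick, tree_distances, tree_splits


def samples_from(newicks: list[str]) -> TreeSampleSet:
    tns = dendropy.TaxonNamespace()
    trees = [
        dendropy.Tree.get(data=n, schema="newick", taxon_namespace=tns, preserve_underscores=True)
        for n in newicks
    ]
    return TreeSampleSet(trees, tns)


class TestSchedule:
    @pytest.mark.parametrize(
        "generations,every,initial,expected",
        [
            (5_000_000, 100, True, 50_001),
            (100, 100, True, 2),
            (999, 100, False, 9),
            (1000, 100, False, 10),
        ],
    )
    def test_sample_count(self, generations, every, initial, expected):
        sched = RunSchedule(generations, every, initial)
        assert expected_sample_count(sched) == expected

    def test_zero_interval_rejected(self):
        with pytest.raises(ValueError):
            RunSchedule(sample_every=0)

    def test_linear_in_generations(self):
        counts = [expected_sample_count(RunSchedule(g, 100, False)) for g in (10_000, 20_000, 30_000)]
        assert counts[2] - counts[1] == counts[1] - counts[0]


class TestBurnin:
    def test_quarter_of_50001(self):
        samples = samples_from(["((A,B),(C,D));"] * 101)
        kept = apply_burnin(samples, 0.25)
        assert len(kept) == 101 - math.floor(0.25 * 101)

    def test_full_run_scale_arithmetic(self):
        # floor(0.25 * 50001) = 12500 discarded, 37501 retained
        assert 50_001 - math.floor(0.25 * 50_001) == 37_501

    def test_zero_fraction_unchanged(self):
        samples = samples_from(["((A,B),(C,D));"] * 4)
        assert len(apply_burnin(samples, 0.0)) == 4

    def test_four_trees_quarter(self):
        samples = samples_from(["((A,B),(C,D));"] * 4)
        assert len(apply_burnin(samples, 0.25)) == 3

    def test_empty_set_ok(self):
        assert len(apply_burnin(TreeSampleSet([]), 0.5)) == 0


AB_CD = frozenset({"C", "D"})  # canonical side (without leaf A) of AB|CD
AC_BD = frozenset({"B", "D"})


class TestBipartitions:
    def test_unanimous_split(self):
        table = bipartition_frequencies(samples_from(["((A,B),(C,D));"] * 3))
        assert table.frequencies == {AB_CD: 1.0}

    def test_two_thirds_one_third(self):
        table = bipartition_frequencies(
            samples_from(["((A,B),(C,D));", "((A,B),(C,D));", "((A,C),(B,D));"])
        )
        assert table.frequencies[AB_CD] == pytest.approx(2 / 3)
        assert table.frequencies[AC_BD] == pytest.approx(1 / 3)

    def test_four_leaf_tree_has_one_nontrivial_split(self):
        table = bipartition_frequencies(samples_from(["((A,B),(C,D));"]))
        assert len(table.frequencies) == 1

    def test_each_tree_contributes_n_minus_3_splits(self):
        rng = np.random.default_rng(3)
        for n in (5, 6, 8):
            labels = [f"L{i}" for i in range(n)]
            top = random_binary_topology(labels, rng)
            tree = dendropy.Tree.get(
                data=to_newick(top), schema="newick", preserve_underscores=True
            )
            assert len(nontrivial_splits(tree)) == n - 3

    def test_matches_brute_force_counts_on_random_five_leaf_sets(self):
        rng = np.random.default_rng(17)
        labels = list("ABCDE")
        for _ in range(5):
            tops = [random_binary_topology(labels, rng) for _ in range(rng.integers(2, 11))]
            table = bipartition_frequencies(samples_from([to_newick(t) for t in tops]))
            expected: dict[frozenset, float] = {}
            for t in tops:
                for s in tree_splits(t):
                    expected[s] = expected.get(s, 0) + 1 / len(tops)
            assert set(table.frequencies) == set(expected)
            for s, f in expected.items():
                assert table.frequencies[s] == pytest.approx(f)


class TestConsensus:
    def test_identical_samples_give_sample_topology_full_support(self):
        samples = samples_from(["((A,B),(C,D));"] * 5)
        cons = majority_rule_consensus(bipartition_frequencies(samples))
        assert cons.supports == {AB_CD: 1.0}
        assert nontrivial_splits(cons.tree()) == {AB_CD}

    def test_majority_split_retained_with_support(self):
        samples = samples_from(["((A,B),(C,D));", "((A,B),(C,D));", "((A,C),(B,D));"])
        cons = majority_rule_consensus(bipartition_frequencies(samples))
        assert set(cons.supports) == {AB_CD}
        assert cons.supports[AB_CD] == pytest.approx(2 / 3)

    def test_even_split_collapses_to_star(self):
        samples = samples_from(["((A,B),(C,D));", "((A,C),(B,D));"])
        cons = majority_rule_consensus(bipartition_frequencies(samples))
        assert cons.supports == {}
        assert nontrivial_splits(cons.tree()) == frozenset()

    def test_threshold_below_half_rejected(self):
        table = bipartition_frequencies(samples_from(["((A,B),(C,D));"]))
        with pytest.raises(ValueError, match="0.5"):
            majority_rule_consensus(table, threshold=0.4)

    def test_consensus_idempotent(self):
        samples = samples_from(["(((A,B),C),(D,E));"] * 4)
        cons = majority_rule_consensus(bipartition_frequencies(samples))
        again = majority_rule_consensus(bipartition_frequencies(samples_from([cons.newick] * 3)))
        assert set(again.supports) == set(cons.supports)
        assert all(v == 1.0 for v in again.supports.values())


class TestAsdsf:
    def test_identical_runs_zero(self):
        run = samples_from(["((A,B),(C,D));"] * 10)
        assert asdsf(run, run) == 0.0

    def test_hand_computed_two_split_case(self):
        run_a = samples_from(["((A,B),(C,D));"] * 5)
        run_b = samples_from(["((A,B),(C,D));"] * 4 + ["((A,C),(B,D));"])
        # sd(1.0, 0.8) = sd(0.0, 0.2) = 0.2/sqrt(2); mean is the same
        expected = (abs(1.0 - 0.8) / math.sqrt(2) + abs(0.0 - 0.2) / math.sqrt(2)) / 2
        assert asdsf(run_a, run_b) == pytest.approx(expected)

    def test_symmetric(self):
        run_a = samples_from(["((A,B),(C,D));"] * 3)
        run_b = samples_from(["((A,C),(B,D));"] * 3)
        assert asdsf(run_a, run_b) == pytest.approx(asdsf(run_b, run_a))

    def test_min_freq_excludes_rare_splits(self):
        run_a = samples_from(["((A,B),(C,D));"] * 20)
        run_b = samples_from(["((A,B),(C,D));"] * 19 + ["((A,C),(B,D));"])
        # the 5% split is below min_freq=0.10 in both runs
        value = asdsf(run_a, run_b, min_freq=0.10)
        assert value == pytest.approx(abs(1.0 - 0.95) / math.sqrt(2))

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="leaf"):
            asdsf(samples_from(["((A,B),(C,D));"]), samples_from(["((A,B),(C,E));"]))


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:4))
        dm = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = neighbor_joining(dm)
        assert nontrivial_splits(tree) == {frozenset({"C", "D"})}
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(dm.loc[a, b])

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(99)
        for n in (5, 6, 7, 8):
            labels = [f"L{i}" for i in range(n)]
            top = random_binary_topology(labels, rng)
            dists = tree_distances(top)
            d = pd.DataFrame(0.0, index=labels, columns=labels)
            for pair, value in dists.items():
                a, b = sorted(pair)
                d.loc[a, b] = d.loc[b, a] = value
            tree = neighbor_joining(d)
            assert nontrivial_splits(tree) == tree_splits(top)

    def test_label_order_invariant(self):
        rng = np.random.default_rng(4)
        labels = [f"L{i}" for i in range(6)]
        top = random_binary_topology(labels, rng)
        dists = tree_distances(top)
        perm = labels[::-1]
        d = pd.DataFrame(0.0, index=perm, columns=perm)
        for pair, value in dists.items():
            a, b = sorted(pair)
            d.loc[a, b] = d.loc[b, a] = value
        assert nontrivial_splits(neighbor_joining(d)) == tree_splits(top)

    def test_matches_independent_nj_implementation(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj

        rng = np.random.default_rng(12)
        labels = [f"L{i}" for i in range(7)]
        m = rng.uniform(0.2, 1.0, size=(7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        ours = neighbor_joining(pd.DataFrame(m, index=labels, columns=labels))
        theirs = nj(DistanceMatrix(m, labels))
        their_tree = dendropy.Tree.get(
            data=str(theirs).strip(), schema="newick", preserve_underscores=True
        )
        assert nontrivial_splits(ours) == nontrivial_splits(their_tree)

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame(np.arange(16.0).reshape(4, 4), index=list("ABCD"), columns=list("ABCD"))
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d)


LABELS = {
    "euk1": TaxonGroup.rhodophyta,
    "euk2": TaxonGroup.rhodophyta,
    "prot1": TaxonGroup.proteobacteria,
    "prot2": TaxonGroup.proteobacteria,
    "cyano1": TaxonGroup.cyanobacteria,
    "cyano2": TaxonGroup.cyanobacteria,
}


def tree_of(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


class TestOriginAssignment:
    def test_sister_to_proteobacteria(self):
        t = tree_of(
            "(((euk1:0.1,euk2:0.1):0.2,(prot1:0.1,prot2:0.1):0.2):0.6,"
            "(cyano1:0.1,cyano2:0.1):0.6);"
        )
        call = assign_origin(t, LABELS, TaxonGroup.rhodophyta)
        assert call.inferred_donor is TaxonGroup.proteobacteria
        assert call.support == 1.0

    def test_nested_inside_cyanobacteria(self):
        t = tree_of(
            "((cyano1:0.3,(euk1:0.1,(euk2:0.1,cyano2:0.1):0.1):0.1):0.8,"
            "(prot1:0.2,prot2:0.2):0.8);"
        )
        call = assign_origin(t, LABELS, TaxonGroup.rhodophyta)
        assert call.inferred_donor is TaxonGroup.cyanobacteria

    def test_mixed_donor_when_clade_spans_groups(self):
        t = tree_of(
            "(((euk1:0.1,prot1:0.1):0.1,(euk2:0.1,cyano1:0.1):0.1):0.5,"
            "(prot2:0.2,cyano2:0.2):0.5);"
        )
        call = assign_origin(t, LABELS, TaxonGroup.rhodophyta)
        assert call.inferred_donor == "mixed"

    def test_no_prokaryotes_rejected(self):
        labels = {"a": TaxonGroup.rhodophyta, "b": TaxonGroup.rhodophyta,
                  "c": TaxonGroup.chlorophyta_plants, "d": TaxonGroup.chlorophyta_plants}
        with pytest.raises(ValueError, match="prokaryote"):
            assign_origin(tree_of("((a:1,b:1):1,(c:1,d:1):1);"), labels, TaxonGroup.rhodophyta)

    def test_support_over_samples(self):
        agree = (
            "(((euk1:0.1,euk2:0.1):0.2,(prot1:0.1,prot2:0.1):0.2):0.6,"
            "(cyano1:0.1,cyano2:0.1):0.6);"
        )
        disagree = (
            "(((euk1:0.1,euk2:0.1):0.2,(cyano1:0.1,cyano2:0.1):0.2):0.6,"
            "(prot1:0.1,prot2:0.1):0.6);"
        )
        samples = samples_from([agree, agree, agree, disagree])
        call = assign_origin_over_samples(samples, LABELS, TaxonGroup.rhodophyta)
        assert call.inferred_donor is TaxonGroup.proteobacteria
        assert call.support == pytest.approx(0.75)
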