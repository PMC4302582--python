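import itertools

import dendropy
import pytest
from dendropy.calculate import treecompare
from hypothesis import given, settings, strategies as st

import congruity as cg
from congruity.io import ValidationError
from congruity.splits import Split, TaxonSet

from conftest import random_resolved_tree
from oracles import informative_masks, realizable_pairs


def split_from_taxa(ts, taxa):
    return Split.from_taxa(ts, taxa)


class TestExtractInformativeSplits:
    def test_single_internal_edge(self):
        tree = cg.parse_newick("((A,B),(C,D));")
        ts = TaxonSet("ABCD")
        assert cg.extract_informative_splits(tree, ts) == frozenset(
            {split_from_taxa(ts, "AB")}
        )

    @pytest.mark.parametrize("n,expected", [(100, 97), (50, 47)])
    def test_resolved_tree_split_count(self, n, expected):
        tree = random_resolved_tree(n, seed=n)
        assert len(cg.extract_informative_splits(tree)) == expected

    def test_fewer_than_four_leaves_gives_empty_set(self):
        assert cg.extract_informative_splits(cg.parse_newick("((A,B),C);")) == frozenset()

    def test_polytomies_yield_fewer_splits(self):
        star = cg.parse_newick("(A,B,C,D,E);")
        assert cg.extract_informative_splits(star) == frozenset()
        partial = cg.parse_newick("((A,B),C,D,E);")
        assert len(cg.extract_informative_splits(partial)) == 1

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(4, 32), st.integers(0, 10**6))
    def test_one_tree_splits_pairwise_compatible(self, n, seed):
        tree = random_resolved_tree(n, seed)
        splits = list(cg.extract_informative_splits(tree))
        assert len(splits) == n - 3
        for a, b in itertools.combinations(splits, 2):
            assert cg.are_compatible(a, b)


class TestAreCompatible:
    def test_nested_clades_compatible(self):
        ts = TaxonSet("ABCDE")
        assert cg.are_compatible(
            split_from_taxa(ts, "AB"), split_from_taxa(ts, "ABC")
        )

    def test_crossing_splits_incompatible(self):
        # AB|CDE vs AC|BDE: all four side intersections nonempty
        ts = TaxonSet("ABCDE")
        assert not cg.are_compatible(
            split_from_taxa(ts, "AB"), split_from_taxa(ts, "AC")
        )

    def test_self_compatible(self):
        ts = TaxonSet("ABCDE")
        s = split_from_taxa(ts, "AB")
        assert cg.are_compatible(s, s)

    def test_mismatched_taxon_sets_error(self):
        s1 = split_from_taxa(TaxonSet("ABCDE"), "AB")
        s2 = split_from_taxa(TaxonSet("ABCDF"), "AB")
        with pytest.raises(ValidationError):
            cg.are_compatible(s1, s2)

    @pytest.mark.parametrize("n", [5, 6])
    def test_matches_exhaustive_realizability_small(self, n):
        """Compatibility must equal joint realizability in some resolved
        tree (checked exhaustively; larger n in the acceptance suite)."""
        ts = TaxonSet(chr(65 + i) for i in range(n))
        realizable = realizable_pairs(n)
        for a, b in itertools.combinations_with_replacement(
            informative_masks(n), 2
        ):
            expected = (min(a, b), max(a, b)) in realizable
            assert cg.are_compatible(Split(ts, a), Split(ts, b)) == expected


class TestSplitPool:
    def test_identical_trees_total_congruence(self):
        tree = random_resolved_tree(100, seed=3)
        trees = [tree.clone(depth=1) for _ in range(48)]
        pool = cg.build_split_pool(trees)
        assert pool.size == 97
        assert pool.min_possible == 97
        assert pool.max_possible == 4656
        assert set(pool.counts.values()) == {48}

    def test_bounds_for_five_trees_on_fifty_taxa(self):
        tree = random_resolved_tree(50, seed=4)
        pool = cg.build_split_pool([tree.clone(depth=1) for _ in range(5)])
        assert pool.size == pool.min_possible == 47
        assert pool.max_possible == 235

    def test_counts_reflect_occurrence(self):
        t1 = cg.parse_newick("((A,B),(C,D),E);")
        t2 = cg.parse_newick("((A,B),(C,E),D);")
        pool = cg.build_split_pool([t1, t2])
        ts = pool.taxon_set
        assert pool.count(split_from_taxa(ts, "AB")) == 2
        assert pool.count(split_from_taxa(ts, "CD")) == 1
        assert pool.size == 3

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cg.build_split_pool(
                [cg.parse_newick("((A,B),(C,D));"), cg.parse_newick("((A,B),(C,E));")]
            )

    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(st.integers(8, 24), st.integers(2, 8), st.integers(0, 10**6))
    def test_pool_size_bounds_hold(self, n, t, seed):
        trees = [random_resolved_tree(n, seed + i) for i in range(t)]
        pool = cg.build_split_pool(trees)
        assert pool.min_possible <= pool.size <= pool.max_possible

    def test_export_frame_columns(self):
        pool = cg.build_split_pool([cg.parse_newick("((A,B),(C,D),E);")])
        df = pool.to_frame()
        assert list(df.columns) == [
            "split",
            "side_size",
            "other_side_size",
            "n_trees",
            "fraction",
        ]
        assert set(df["split"]) == {"A,B", "C,D"}


class TestRfSplitDistance:
    def test_identity(self, quartet):
        assert cg.rf_split_distance(quartet, quartet) == 0

    def test_disjoint_split_sets(self):
        # two resolved 50-taxon trees sharing no split: 47 + 47
        t1 = random_resolved_tree(50, seed=10)
        t2 = random_resolved_tree(50, seed=20)
        s1 = cg.extract_informative_splits(t1)
        s2 = cg.extract_informative_splits(t2)
        shared = len(s1 & s2)
        assert cg.rf_split_distance(t1, t2) == 94 - 2 * shared

    def test_five_taxon_disjoint_example(self):
        t1 = cg.parse_newick("((A,B),(C,D),E);")
        t2 = cg.parse_newick("((A,C),(B,D),E);")
        assert cg.rf_split_distance(t1, t2) == 4

    def test_agrees_with_dendropy(self):
        """Independent cross-check against dendropy's RF implementation."""
        tns = dendropy.TaxonNamespace()
        for seed in range(5):
            a = random_resolved_tree(20, seed=seed)
            b = random_resolved_tree(20, seed=seed + 100)
            da = dendropy.Tree.get(
                data=cg.write_newick(a), schema="newick", taxon_namespace=tns
            )
            db = dendropy.Tree.get(
                data=cg.write_newick(b), schema="newick", taxon_namespace=tns
            )
            expected = treecompare.symmetric_difference(da, db)
            assert cg.rf_split_distance(a, b) == expected

    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(st.integers(6, 16), st.integers(0, 10**5))
    def test_metric_properties(self, n, seed):
        a = random_resolved_tree(n, seed)
        b = random_resolved_tree(n, seed + 1)
        c = random_resolved_tree(n, seed + 2)
        dab = cg.rf_split_distance(a, b)
        assert dab == cg.rf_split_distance(b, a) >= 0
        assert cg.rf_split_distance(a, a) == 0
        assert dab <= cg.rf_split_distance(a, c) + cg.rf_split_distance(c, b)
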