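import numpy as np
import pytest

import congruity as cg
from congruity.io import ValidationError, write_newick
from congruity.simulate import (
    WagModel,
    discrete_gamma_rates,
    zipf_truncated_mean,
    zipf_truncated_pmf,
    _wag,
)

from conftest import random_resolved_tree


class TestWagModel:
    def test_transition_rows_are_distributions(self):
        model = _wag()
        for t in (0.01, 0.5, 5.0):
            P = model.transition(t)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert np.all(P >= 0)

    def test_zero_time_is_identity(self):
        assert np.allclose(_wag().transition(0.0), np.eye(20), atol=1e-10)

    def test_mean_rate_is_one(self):
        # short-time off-diagonal mass ~ t for a mean-one-rate chain
        model = _wag()
        t = 1e-4
        P = model.transition(t)
        off = 1.0 - float(np.sum(model.freqs * np.diag(P)))
        assert off == pytest.approx(t, rel=1e-2)

    def test_stationarity(self):
        model = _wag()
        assert np.allclose(model.freqs @ model.transition(2.0), model.freqs)


class TestDiscreteGamma:
    def test_category_means_average_to_one(self):
        for shape in (0.3, 1.0, 2.5):
            rates = discrete_gamma_rates(shape, 4)
            assert np.mean(rates) == pytest.approx(1.0)
            assert np.all(np.diff(rates) > 0)

    def test_large_shape_approaches_uniform_rates(self):
        rates = discrete_gamma_rates(200.0, 4)
        assert np.allclose(rates, 1.0, atol=0.2)


class TestZipf:
    def test_pmf_normalised_and_decreasing(self):
        pmf = zipf_truncated_pmf(1.6, 100)
        assert pmf.sum() == pytest.approx(1.0)
        assert np.all(np.diff(pmf) < 0)

    def test_sampled_mean_matches_closed_form(self):
        rng = np.random.default_rng(0)
        pmf_cum = np.cumsum(zipf_truncated_pmf(1.6, 100))
        draws = np.searchsorted(pmf_cum, rng.random(20000)) + 1
        expected = zipf_truncated_mean(1.6, 100)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se


class TestSpeciesTree:
    def test_split_count_and_determinism(self):
        t1 = cg.simulate_species_tree(100, seed=7)
        t2 = cg.simulate_species_tree(100, seed=7)
        assert len(cg.extract_informative_splits(t1)) == 97
        assert write_newick(t1) == write_newick(t2)

    def test_minimal_tree(self):
        t = cg.simulate_species_tree(4, seed=1)
        assert len(cg.extract_informative_splits(t)) == 1

    def test_height_matches_tree_scale(self):
        t = cg.simulate_species_tree(30, seed=2, tree_scale=3.0)
        height = max(l.distance_from_root() for l in t.leaf_node_iter())
        assert height == pytest.approx(3.0)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValidationError):
            cg.simulate_species_tree(3, seed=0)


class TestApplyLgtEvents:
    def test_zero_events_identity(self):
        species = random_resolved_tree(20, seed=1)
        gene, events = cg.apply_lgt_events(species, 0, rng=2)
        assert events == []
        assert cg.rf_split_distance(species, gene) == 0

    def test_single_move_on_quartet_is_spr_neighbour(self, quartet):
        """On 4 taxa the SPR neighbourhood (excluding the identity) is the
        two other quartet topologies, both at RF distance 2."""
        for seed in range(30):
            gene, events = cg.apply_lgt_events(quartet, 1, rng=seed)
            assert cg.rf_split_distance(quartet, gene) == 2
            assert len(events) == 1

    def test_leaf_set_conserved_under_many_moves(self):
        species = random_resolved_tree(16, seed=3)
        before = {l.taxon.label for l in species.leaf_node_iter()}
        gene, events = cg.apply_lgt_events(species, 25, rng=4)
        assert {l.taxon.label for l in gene.leaf_node_iter()} == before
        assert len(events) == 25

    def test_rf_bounded_by_move_count(self):
        """Each SPR changes at most 2(n-3) splits, so k moves cannot push
        the RF distance past 2k(n-3) (and stay within the metric's cap)."""
        for n, k, seed in [(8, 1, 0), (12, 2, 1), (16, 5, 2)]:
            species = random_resolved_tree(n, seed=seed)
            gene, _ = cg.apply_lgt_events(species, k, rng=seed)
            d = cg.rf_split_distance(species, gene)
            assert 0 < d <= min(2 * k * (n - 3), 2 * (n - 3))

    def test_species_tree_untouched(self):
        species = random_resolved_tree(12, seed=5)
        before = write_newick(species)
        cg.apply_lgt_events(species, 10, rng=6)
        assert write_newick(species) == before


class TestEvolveAlignment:
    def test_zero_branch_lengths_keep_root_sequence(self):
        tree = cg.parse_newick("((A:0,B:0):0,(C:0,D:0):0);")
        config = cg.SimConfig(n_taxa=4, n_families=1, root_length=120, seed=0)
        aln = cg.evolve_alignment(tree, config, rng=1)
        assert aln.length == 120
        assert len(set(aln.seqs)) == 1

    def test_zero_indel_rate_gapless_length_L(self):
        tree = random_resolved_tree(10, seed=1)
        config = cg.SimConfig(
            n_taxa=10, n_families=1, root_length=250, indel_rate=0.0, seed=0
        )
        aln = cg.evolve_alignment(tree, config, rng=2)
        assert aln.length == 250
        assert all("-" not in s for s in aln.seqs)

    def test_missing_branch_length_rejected(self):
        tree = cg.parse_newick("((A,B),(C,D));")
        config = cg.SimConfig(n_taxa=4, n_families=1, root_length=50, seed=0)
        with pytest.raises(ValidationError, match="branch lengths"):
            cg.evolve_alignment(tree, config, rng=0)

    def test_saturation_approaches_identity_floor(self):
        """On very long branches pairwise identity decays to the random
        collision baseline sum(pi_i^2) of the equilibrium frequencies."""
        tree = cg.parse_newick("((A:10,B:10):1,(C:10,D:10):1);")
        # near-uniform site rates so every site is actually saturated
        config = cg.SimConfig(
            n_taxa=4, n_families=1, root_length=3000, gamma_shape=50.0, seed=0
        )
        aln = cg.evolve_alignment(tree, config, rng=3)
        floor = 100 * _wag().identity_floor
        observed = cg.avg_pairwise_identity(aln)
        assert observed == pytest.approx(floor, abs=2.0)

    def test_insertion_growth_matches_indel_model(self):
        """Inserted columns accumulate at indel_rate x (L+1) x total branch
        length x mean zipf length; observed growth should sit within 3
        standard errors of that expectation."""
        tree = random_resolved_tree(8, seed=4, scale=1.0)
        total_len = sum(
            e.length for e in tree.preorder_edge_iter() if e.length
        )
        L = 400
        rate = 0.004
        config = cg.SimConfig(
            n_taxa=8,
            n_families=1,
            root_length=L,
            indel_rate=rate,
            seed=0,
        )
        growths = []
        for rep in range(25):
            aln = cg.evolve_alignment(tree, config, rng=100 + rep)
            growths.append(aln.length - L)
        expected = rate * (L + 1) * total_len * zipf_truncated_mean(1.6, 100)
        growths = np.array(growths, dtype=float)
        se = growths.std(ddof=1) / np.sqrt(len(growths))
        assert abs(growths.mean() - expected) < 3 * se + 1.0


class TestGenerateDataset:
    def test_seed_determinism_bytewise(self, tmp_path):
        config = cg.SimConfig(
            n_taxa=10, n_families=4, root_length=150, lgt_events=2, seed=9
        )
        d1 = cg.generate_dataset(config)
        d2 = cg.generate_dataset(config)
        (tmp_path / "a").mkdir()
        (tmp_path / "b").mkdir()
        d1.save(tmp_path / "a")
        d2.save(tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_ground_truth_bundled(self):
        config = cg.SimConfig(
            n_taxa=12,
            n_families=6,
            root_length=100,
            lgt_events=3,
            seed=10,
        )
        ds = cg.generate_dataset(config)
        assert len(ds.families) == 6
        assert len(ds.events) == 18
        for fam in ds.families:
            assert fam.alignment is not None
            assert fam.pairwise_identity is not None

    def test_variable_lengths_sampled_per_family(self):
        config = cg.SimConfig(
            n_taxa=8, n_families=8, root_length=(100, 800), seed=11
        )
        ds = cg.generate_dataset(config)
        lengths = [f.mean_sequence_length for f in ds.families]
        assert max(lengths) - min(lengths) > 100

    def test_pool_grows_with_tree_height_at_short_lengths(self):
        """Tripling sequence divergence inflates the split pool of trees
        inferred from short alignments."""
        pools = {}
        for scale in (1.0, 3.0):
            config = cg.SimConfig(
                n_taxa=40,
                n_families=15,
                root_length=200,
                tree_scale=scale,
                seed=12,
            )
            ds = cg.generate_dataset(config)
            trees = [cg.nj_tree(f.alignment) for f in ds.families]
            pools[scale] = cg.build_split_pool(trees).size
        assert pools[3.0] > pools[1.0]

    def test_pool_shrinks_with_alignment_length(self, sim_length_pair):
        short_pool = cg.build_split_pool(sim_length_pair[150][1]).size
        long_pool = cg.build_split_pool(sim_length_pair[1000][1]).size
        assert long_pool < short_pool
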