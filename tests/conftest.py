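import numpy as np
import pytest

import congruity as cg


def random_resolved_tree(n: int, seed: int, scale: float = 1.0):
    """A random resolved species tree, used wherever a generic topology on
    n taxa is needed."""
    return cg.simulate_species_tree(n, seed=seed, tree_scale=scale)


@pytest.fixture(scope="session")
def quartet():
    return cg.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def five_taxon_ref():
    return cg.parse_newick("((A,B),(C,D),E);")


@pytest.fixture(scope="session")
def sim_length_pair():
    """Two small simulated datasets differing only in alignment length,
    with NJ-inferred gene trees — the closed-loop length experiment at
    desk scale (shared across tests to keep the suite fast)."""
    out = {}
    for L in (150, 1000):
        config = cg.SimConfig(
            n_taxa=24, n_families=12, root_length=L, lgt_events=0, seed=11
        )
        dataset = cg.generate_dataset(config)
        trees = [cg.nj_tree(f.alignment) for f in dataset.families]
        out[L] = (dataset, trees)
    return out
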