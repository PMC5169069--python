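import numpy as np
import pytest

from abaccus import figure1_fixture, root_at_farthest_leaf
from abaccus.simulate import SimConfig, simulate_taxonomy


@pytest.fixture
def fig1():
    """Worked-example inputs: (gene tree, 13-species taxonomy, seed leaf)."""
    return figure1_fixture()


@pytest.fixture
def fig1_rooted(fig1):
    gtree, table, seed = fig1
    root_at_farthest_leaf(gtree, seed)
    return gtree, table, seed


# breadth presets keeping the loss-oracle tables small (<= 32 species
# per domain) so literal enumeration stays instant
_SMALL_BREADTHS = [
    (1, 1, 2, 2, 2, 1, 1, 2),
    (1, 2, 1, 3, 1, 2, 1, 2),
    (1, 1, 1, 2, 2, 2, 1, 1),
    (1, 1, 3, 1, 3, 1, 3, 1),
    (2, 1, 2, 1, 2, 1, 2, 1),
]


def random_loss_case(rng: np.random.Generator):
    """One randomized loss-counting instance on a small taxonomy.

    Returns (table, seed_lineage, clade, sister, node_rank, shared_rank)
    with the seed species always inside the clade.
    """
    breadth = _SMALL_BREADTHS[int(rng.integers(len(_SMALL_BREADTHS)))]
    config = SimConfig(
        breadth=breadth, n_domains=int(rng.integers(1, 3)), rng_seed=0
    )
    table = simulate_taxonomy(config)
    species = sorted(table.species)
    seed_sp = species[int(rng.integers(len(species)))]
    lineage = table.lineage_of(seed_sp)
    node_rank = int(rng.integers(0, 8))
    shared_rank = int(rng.integers(node_rank, 10))

    def subset():
        k = int(rng.integers(0, max(2, len(species) // 3)))
        idx = rng.choice(len(species), size=k, replace=False)
        return {species[i] for i in idx}

    clade = subset() | {seed_sp}
    sister = subset() - clade
    return table, lineage, clade, sister, node_rank, shared_rank


@pytest.fixture
def loss_case_factory():
    return random_loss_case
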