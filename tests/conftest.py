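import random

import pytest

from quartetpp import (
    SimConfig,
    TaxonIndex,
    parse_newick,
    simulate_msc_gene_trees,
    simulate_yule_tree,
    unroot,
)


def trees_from(newicks, taxa=None):
    """Parse and unroot a list of newick strings over one shared index."""
    if taxa is None:
        taxa = TaxonIndex()
    return [unroot(parse_newick(s, taxa)) for s in newicks], taxa


@pytest.fixture
def quartet_taxa():
    return TaxonIndex()


@pytest.fixture
def balanced_quartet(quartet_taxa):
    """Unrooted 4-taxon species tree 12|34 with its single internal edge."""
    return unroot(parse_newick("((1,2),(3,4));", quartet_taxa))


def random_instances(seed, n_reps, leaves=(6, 10), genes_per_rep=8):
    """Randomized (species tree, gene trees) scenarios for oracle tests.

    Yields binary, randomly-multifurcated, and taxon-deleted gene trees so
    the efficient counter is exercised on every structural case.
    """
    from quartetpp import delete_taxa, perturb_gene_trees

    rng = random.Random(seed)
    for _ in range(n_reps):
        l = rng.randint(*leaves)
        sp = simulate_yule_tree(
            SimConfig(n_leaves=l, seed=rng.randrange(2**30), n_genes=1)
        )
        gts = simulate_msc_gene_trees(sp, genes_per_rep, rng.randrange(2**30))
        gts = perturb_gene_trees(gts, 0.3, rng.randrange(2**30))
        for g in gts[::2]:  # contract ~30% of edges in half the trees
            for nd in list(g.dtree.preorder_internal_node_iter()):
                if nd.parent_node is not None and rng.random() < 0.3:
                    nd.edge.collapse()
        gts += delete_taxa(gts[:genes_per_rep // 2], 0.25, rng.randrange(2**30))
        yield sp, gts
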