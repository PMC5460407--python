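import random

import pytest

from plct import (
    GeneTree,
    LeafMap,
    SpeciesLocus,
    make_crossed_cherries,
    parse_leafmap_from_names,
    read_gene_tree,
)


@pytest.fixture
def crossed_instance():
    """The canonical infeasible quartet: loci crossed across two individuals."""
    return make_crossed_cherries()


@pytest.fixture
def uncrossed_instance():
    """Feasible control: each locus's two samples form a cherry."""
    tree = read_gene_tree("((A|1|i,A|1|ii),(A|2|i,A|2|ii));")
    return tree, parse_leafmap_from_names(tree)


@pytest.fixture
def chain_instance():
    """Six-leaf caterpillar whose LEG is the path A:1 -- B:1 -- A:2.

    The A:1 and A:2 label subtrees are edge-disjoint (no strong conflict)
    but both overlap the B:1 subtree, so transitivity alone makes the
    component conflicting.
    """
    tree = read_gene_tree("(a1x,(b1x,(a1y,(a2x,(b1y,a2y)))));")
    lmap = LeafMap(
        {
            "a1x": SpeciesLocus("A", "1"),
            "a1y": SpeciesLocus("A", "1"),
            "b1x": SpeciesLocus("B", "1"),
            "b1y": SpeciesLocus("B", "1"),
            "a2x": SpeciesLocus("A", "2"),
            "a2y": SpeciesLocus("A", "2"),
        }
    )
    return tree, lmap


def random_binary_tree(leaf_names, rng: random.Random) -> GeneTree:
    """Random unrooted binary topology (delegates to the library helper)."""
    from plct import random_topology

    return random_topology(list(leaf_names), seed=rng.randrange(2**31 - 1))


def random_leaf_map(
    leaf_names, rng: random.Random, n_species=3, max_loci=2
) -> LeafMap:
    """Random assignment of leaves to species-specific loci."""
    species = [chr(ord("A") + i) for i in range(n_species)]
    assignments = {}
    counters: dict[SpeciesLocus, int] = {}
    for name in leaf_names:
        sl = SpeciesLocus(rng.choice(species), str(rng.randrange(1, max_loci + 1)))
        assignments[name] = sl
        counters[sl] = counters.get(sl, 0) + 1
    samples = {}
    seen: dict[SpeciesLocus, int] = {}
    for name in leaf_names:
        sl = assignments[name]
        seen[sl] = seen.get(sl, 0) + 1
        samples[name] = f"s{seen[sl]}"
    return LeafMap(assignments, samples)


def random_instance(n_leaves: int, seed: int, n_species=3, max_loci=2):
    rng = random.Random(seed)
    names = [f"g{i}" for i in range(n_leaves)]
    tree = random_binary_tree(names, rng)
    return tree, random_leaf_map(names, rng, n_species=n_species, max_loci=max_loci)
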