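"""Brute-force ground truth for feasibility on small trees.

Feasibility only asks, per branch, whether it carries at least one
duplication — multiple duplications on one branch change nothing — so every
duplication placement is a subset of the unrooted branch set. On small
trees we can enumerate all 2^B subsets and count those satisfying every
allele and paralog constraint, giving an oracle wholly independent of the
PLCT/LEG machinery. The subset sweep is vectorized with numpy bitmasks.

The module also provides exhaustive enumeration of unrooted binary
topologies and of leaf-to-locus assignments, used to cross the main
algorithm against the oracle over a whole instance family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterator, Optional, Sequence

import numpy as np

from .tree import GeneTree, LeafMap, SpeciesLocus, read_gene_tree

__all__ = [
    "OracleResult",
    "brute_force_feasibility",
    "enumerate_topologies",
    "enumerate_leaf_maps",
]


@dataclass
class OracleResult:
    n_branches: int
    n_valid_placements: int
    feasible: bool
    exemplar: Optional[frozenset[str]]  # one valid placement, if any


def brute_force_feasibility(
    tree: GeneTree, leaf_map: LeafMap, max_branches: int = 16
) -> OracleResult:
    """Exhaustively test every duplication placement on the unrooted branches.

    Refuses trees with more than ``max_branches`` unrooted branches to keep
    the 2^B enumeration bounded.
    """
    leaf_map.validate_against(tree)
    branches = tree.unrooted_branches()
    B = len(branches)
    if B > max_branches:
        raise ValueError(f"{B} branches exceeds max_branches={max_branches}")
    index = {b: i for i, b in enumerate(branches)}

    allele_masks: list[int] = []
    paralog_masks: list[int] = []
    by_locus = leaf_map.genes_by_locus()
    for genes in by_locus.values():
        for a, b in combinations(genes, 2):
            m = 0
            for bid in tree.path_branches(a, b):
                m |= 1 << index[bid]
            allele_masks.append(m)
    by_species: dict[str, list] = {}
    for sl, genes in by_locus.items():
        by_species.setdefault(sl.species, []).append(genes)
    for groups in by_species.values():
        for gx, gy in combinations(groups, 2):
            for a in gx:
                for b in gy:
                    m = 0
                    for bid in tree.path_branches(a, b):
                        m |= 1 << index[bid]
                    paralog_masks.append(m)

    subsets = np.arange(1 << B, dtype=np.uint64)
    valid = np.ones(subsets.shape, dtype=bool)
    for m in allele_masks:
        valid &= (subsets & np.uint64(m)) == 0
    for m in paralog_masks:
        valid &= (subsets & np.uint64(m)) != 0
    n_valid = int(valid.sum())
    exemplar = None
    if n_valid:
        first = int(subsets[valid][0])
        exemplar = frozenset(b for b, i in index.items() if first >> i & 1)
    return OracleResult(
        n_branches=B,
        n_valid_placements=n_valid,
        feasible=n_valid > 0,
        exemplar=exemplar,
    )


# ---------------------------------------------------------------------------
# Exhaustive instance families for cross-checking


def enumerate_topologies(leaf_names: Sequence[str]) -> Iterator[GeneTree]:
    """Yield every unrooted binary topology on the given leaves.

    Generated by leaf insertion: the unique topology on 3 leaves, then each
    further leaf attached to every branch; yields (2n-5)!! trees for n
    leaves. Trees are returned in a rooted representation (root of
    out-degree 3 at an internal node); the algorithms only read the
    unrooted view.
    """
    n = len(leaf_names)
    if n < 3:
        raise ValueError("need at least 3 leaves")
    # nodes: 0..n-1 leaves, n.. internal
    first = [(0, n), (1, n), (2, n)]

    def expand(edges: list[tuple[int, int]], next_leaf: int, next_internal: int):
        if next_leaf == n:
            yield edges
            return
        for i in range(len(edges)):
            u, v = edges[i]
            w = next_internal
            new_edges = edges[:i] + edges[i + 1 :] + [(u, w), (v, w), (next_leaf, w)]
            yield from expand(new_edges, next_leaf + 1, next_internal + 1)

    for edges in expand(first, 3, n + 1):
        adj: dict[int, list[int]] = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)

        def newick(node: int, parent: int) -> str:
            nbs = [x for x in adj[node] if x != parent]
            if not nbs:
                return leaf_names[node]
            return "(" + ",".join(newick(x, node) for x in nbs) + ")"

        yield read_gene_tree(newick(n, -1) + ";")


def enumerate_leaf_maps(
    leaf_names: Sequence[str],
    n_species: int = 2,
    n_loci: int = 2,
    max_samples: int = 2,
) -> Iterator[LeafMap]:
    """Yield every assignment of leaves to species-specific loci.

    Classes are the cross of ``n_species`` species and ``n_loci`` loci per
    species; assignments placing more than ``max_samples`` genes in one
    class are skipped (each gene in a class is one sampled individual).
    """
    species = [chr(ord("A") + i) for i in range(n_species)]
    classes = [SpeciesLocus(s, str(l + 1)) for s in species for l in range(n_loci)]
    n = len(leaf_names)
    for assign in product(range(len(classes)), repeat=n):
        counts = [0] * len(classes)
        ok = True
        for c in assign:
            counts[c] += 1
            if counts[c] > max_samples:
                ok = False
                break
        if not ok:
            continue
        assignments = {leaf_names[i]: classes[assign[i]] for i in range(n)}
        seen: dict[int, int] = {}
        samples = {}
        for i in range(n):
            seen[assign[i]] = seen.get(assign[i], 0) + 1
            samples[leaf_names[i]] = f"s{seen[assign[i]]}"
        yield LeafMap(assignments, samples)
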