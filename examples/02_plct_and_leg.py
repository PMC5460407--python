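"""Inspect the two structures behind the verdict: PLCT and LEG.

A six-leaf caterpillar where the allele paths of A:1 and A:2 never touch,
but both overlap the path of B:1. Transitivity of locus equivalence chains
A:1 -- B:1 -- A:2 into one connected component, which contains two loci of
species A: infeasible without any directly conflicting branch.
"""

from plct import (
    LeafMap,
    SpeciesLocus,
    build_leg,
    build_plct,
    conflicts,
    decide,
    labeled_branch_fractions,
    read_gene_tree,
)

tree = read_gene_tree("(a1x,(b1x,(a1y,(a2x,(b1y,a2y)))));")
lmap = LeafMap(
    {
        "a1x": SpeciesLocus("A", "1"), "a1y": SpeciesLocus("A", "1"),
        "b1x": SpeciesLocus("B", "1"), "b1y": SpeciesLocus("B", "1"),
        "a2x": SpeciesLocus("A", "2"), "a2y": SpeciesLocus("A", "2"),
    }
)

plct = build_plct(tree, lmap)
print("branch labels (allele-path constraints):")
for bid in tree.unrooted_branches():
    labels = ",".join(str(s) for s in sorted(plct.labels[bid])) or "-"
    print(f"  {bid:8s} {labels}")
frac, multi = labeled_branch_fractions(plct)
print(f"labeled: {frac:.0%} of branches, multi-labeled: {multi:.0%}")

leg = build_leg(plct)
print("LEG edges:", sorted(tuple(map(str, sorted(e))) for e in leg.edges()))
print("LEG components:", [[str(x) for x in c] for c in leg.components])

rep = conflicts(leg, plct)
print("strong-conflict branches:", rep.strong_conflict_branches or "none")
print("weak-conflict branches:", sorted(rep.weak_conflict_branches))
print("verdict:", decide(tree, lmap).status.value)
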