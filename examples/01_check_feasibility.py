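"""Decide whether a gene tree admits any DLC reconciliation.

Two quartets from one species A, sampled at two loci in two individuals
(i, ii). In the "uncrossed" tree each locus's two alleles pair up; in the
"crossed" tree each individual's two loci pair up, which no placement of
duplications can explain.
"""

from plct import decide, make_crossed_cherries, parse_leafmap_from_names, read_gene_tree

crossed_tree, crossed_map = make_crossed_cherries(species="A")
uncrossed_tree = read_gene_tree("((A|1|i,A|1|ii),(A|2|i,A|2|ii));")
uncrossed_map = parse_leafmap_from_names(uncrossed_tree)

for name, tree, lmap in [
    ("uncrossed", uncrossed_tree, uncrossed_map),
    ("crossed", crossed_tree, crossed_map),
]:
    v = decide(tree, lmap)
    print(f"{name}: {tree.to_newick()}")
    print(f"  verdict: {v.status.value}")
    if v.witness is not None:
        print(f"  witness duplication branches: {sorted(v.witness)}")
    for comp, bad in v.conflict.conflicting_components:
        print(f"  conflicting loci: {[str(x) for x in comp]} (paralogs forced orthologous: {bad})")

# The witness branch is the single internal branch: placing one duplication
# there separates locus 1 from locus 2 while leaving both allele pairs
# untouched. The crossed tree has no such branch left, hence INFEASIBLE.
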