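# plct — gene tree feasibility with multiple samples per species

`plct` decides whether a gene-tree topology can be reconciled with *any*
species tree under a duplication–loss–coalescence (DLC) model when several
haploid individuals are sampled per species. It is aimed at phylogenomic
pipelines that build gene-family trees from population-resequencing data
(multiple genomes per species mapped to a reference) and need to flag
trees that no evolutionary history under the model can produce — a symptom
of reconstruction error or of model violations such as gene conversion.

## The problem and the algorithm

With one haploid sample per species, every gene tree can be reconciled
under duplication and loss alone, so reconciliation methods may focus on
finding an optimal history. With multiple samples this guarantee breaks.
Writing g ∈ L(s, ℓ) for a gene sampled at species-specific locus ℓ of
species s:

- **allele constraint** — two genes at the *same* locus of a species are
  alleles: no duplication may lie on the gene-tree path between them;
- **paralog constraint** — two genes at *different* loci of a species are
  paralogs: at least one duplication must lie on the path between them,
  whichever individuals they came from.

These constraints depend only on the (unrooted) gene-tree topology and the
leaf map, not on the species tree or the rooting. The decision procedure:

1. **PLCT** (partially labeled coalescent tree): for every locus ℓ with ≥ 2
   genes, label each branch on the minimal subtree spanning ℓ's leaves with
   ℓ. Labeled branches can carry no duplication.
2. **LEG** (locus equivalence graph): one vertex per species-specific
   locus; for every branch carrying labels {ℓ₁, …, ℓₘ}, m ≥ 2, add all
   pairwise edges. A shared branch is a single gene lineage existing at one
   locus, so co-labeling loci must be *equivalent* — descended from one
   ancestral locus through speciations alone. Equivalence is transitive and
   implies orthology.
3. **Verdict**: the gene tree is reconcilable iff no connected component of
   the LEG contains two loci of one species (which would force a gene pair
   to be orthologs and paralogs at once). For binary trees this is exact
   and a witness placement — a duplication on every unlabeled branch — is
   returned and verified. For multifurcating trees an irreconcilable LEG
   still proves infeasibility, while a reconcilable LEG leaves the verdict
   `UNKNOWN`.

The package also ships the supporting instruments: a brute-force oracle
that enumerates all 2^B duplication placements on small trees, diagnostic
statistics (locus monophyly, bootstrap support of conflicting branches,
feasibility sweeps under support-threshold collapsing), and a desk-scale
DLC simulator with k samples per species whose true histories are feasible
by construction.

## Worked example

```python
from plct import decide, make_crossed_cherries, parse_leafmap_from_names, read_gene_tree

uncrossed = read_gene_tree("((A|1|i,A|1|ii),(A|2|i,A|2|ii));")
v = decide(uncrossed, parse_leafmap_from_names(uncrossed))
print(v.status.value, sorted(v.witness))

crossed, cmap = make_crossed_cherries(species="A")
v = decide(crossed, cmap)
print(v.status.value, v.conflict.conflicting_components)
```

prints

```
FEASIBLE ['n1+n2']
INFEASIBLE [((SpeciesLocus(species='A', locus='1'), SpeciesLocus(species='A', locus='2')), {'A': ['1', '2']})]
```

In the uncrossed quartet the two alleles of each locus pair up, and a
single duplication on the internal branch (`n1+n2`, the unrooted branch
between the two cherries) separates the loci: feasible. In the crossed
quartet each *individual*'s two loci pair up instead, so the allele paths
of loci A:1 and A:2 jointly cover every branch; the internal branch carries
both labels, the LEG joins A:1–A:2 into one component containing two loci
of species A, and no valid reconciliation exists. The brute-force oracle
confirms 0 of the 32 placements are valid.

Longer narrative walkthroughs live in `examples/` (feasibility checks,
PLCT/LEG inspection, simulation, collapse sweeps, oracle cross-checks);
each is a runnable script.

## Command line

```sh
plct check tree.nwk --map leafmap.tsv          # exit 0 FEASIBLE / 3 INFEASIBLE / 4 UNKNOWN
plct check tree.nwk --delimiter "|" --collapse-support 50
plct oracle tree.nwk --map leafmap.tsv         # exhaustive placement counts
plct simulate -n 100 --out families/ --samples 2 --seed 1
plct stats families/ --sweep 25,50,75,100
```

Leaf maps are TSV with header `gene  species  locus  [sample]`, or derived
from leaf names like `A|1|i` via `--delimiter`.

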