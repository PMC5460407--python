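# Methods

## Model and decision procedure

A gene family evolves in three nested layers: a locus tree evolves inside
the species tree by a duplication–loss birth–death process, and the gene
(coalescent) tree evolves inside the locus tree by a multispecies
coalescent within each locus. Two model assumptions matter for the
algorithm. First, every duplication creates a new, unlinked locus, so
coalescence in the parent and daughter loci is independent and there is no
gene conversion between them. Second, duplications and losses fix
instantly in all descendant lineages (no hemiplasy), which cleanly
separates the duplication–loss layer from the coalescent layer.

Sampling k ≥ 2 haploid individuals per species at known species-specific
loci induces the allele and paralog constraints described in the README.
Feasibility is decided from the partially labeled coalescent tree (PLCT)
and the locus equivalence graph (LEG):

- The PLCT label set of a branch is the set of loci whose allele paths
  cross it. Per locus this equals the union of all pairwise leaf-to-leaf
  paths, i.e. the minimal (Steiner) subtree of the locus's leaves. We
  compute it in one counting pass per locus — a branch belongs to the
  Steiner subtree iff the subtree below it contains strictly between 0 and
  k of the locus's leaves — and keep the all-pairs path-union definition
  as the tested contract.
- The LEG joins loci that co-label a branch; components are computed with
  networkx and ordered canonically by their lexicographically smallest
  member, so all reports are byte-stable under input reordering.
- Verdicts: INFEASIBLE iff some component holds ≥ 2 loci of one species;
  otherwise FEASIBLE for binary trees, with the maximal witness (a
  duplication on every unlabeled branch); otherwise UNKNOWN, a first-class
  verdict for multifurcating trees with a reconcilable LEG, whose
  feasibility the theory leaves open. The maximal witness is canonical and
  deterministic; a minimal witness is a non-goal, and no claim of
  parsimony or probability attaches to it.

Everything operates on the unrooted view of the tree: a branch is
identified by its child node, and a root of out-degree 2 contributes a
single merged branch named `<childA>+<childB>` (sorted). A root of
out-degree 1 is suppressed at parse time. This makes rooting invariance
hold by construction; tests verify the verdict and the labels across every
rerooting.

## Conventions and numerical choices

- **Supports.** Numeric internal-node labels in Newick are bootstrap-like
  supports on the child branch; non-numeric labels are ignored. The two
  sides of a merged root branch annotate the same unrooted bipartition;
  when both carry a (different) value we use the minimum. Unknown support
  never collapses.
- **Collapse.** `collapse_low_support` contracts internal unrooted
  branches with known support strictly below the threshold; pendant
  branches never contract. Contraction removes a branch and its label set
  and changes no other branch's labels, hence LEG(collapsed) edges ⊆
  LEG(original) edges — the monotonicity that the sweep tests assert.
- **Monophyly.** Default mode is rooted-clade equality (matching how such
  tables are usually computed on rooted reconstructed trees); an unrooted
  mode accepting either side of any bipartition is provided because the
  feasibility machinery itself is unrooted. Reports state the mode.
  Singleton loci are trivially monophyletic.
- **Conflict classes.** A branch is in *strong* conflict if its own label
  set contains two loci of one species, and in *weak* conflict if any of
  its labels lies in a conflicting LEG component; strong ⊆ weak. The
  support comparison reports the two-sided Wilcoxon rank-sum statistic
  (scipy, normal approximation) per definition and flags it undefined when
  either group is empty — the statistic is standard plumbing, not a
  contribution of the package.
- **Oracle.** Whether a placement satisfies the constraints depends only
  on which branches carry ≥ 1 duplication, so placements are subsets of
  the unrooted branch set. The oracle enumerates all 2^B subsets
  (default cap B ≤ 16) with vectorized bitmask tests and is kept fully
  independent of the PLCT/LEG code path.

## Synthetic data

`simulate_family` draws the locus layer top-down (Poisson duplications and
losses per coalescent unit of species-tree branch length; a loss prunes
the locus's whole descendant clade, a duplication starts a new locus that
exists in all descendants) and then runs one multispecies coalescent per
locus bottom-up through the locus tree. k lineages enter at each extant
species carrying the locus; within a species branch with m lineages,
coalescence happens at rate m(m−1)/2 per coalescent unit; at a daughter
locus's origin the remaining lineages are forced to coalesce (the new
locus descends from a single gene copy), realized as sequential pairwise
joins at the origin time so the gene tree stays binary; the stem lineage
then joins the parent locus. The root locus coalesces freely above the
species root. Families with fewer than two surviving genes are flagged
empty and regenerated under caller control.

Defaults define the study conditions: a 12-taxon ultrametric species tree
of height 3 coalescent units (terminal branches 0.4–2.0 units, enough for
substantial incomplete lineage sorting at k ≥ 2), baseline ("1×")
duplication and loss rates of 0.1 events per coalescent unit (≈ 2 expected
duplications per family before loss, a realistic gene-family scale), and
k = 2 samples per species. Population size is folded into the coalescent
branch-length scale: `scale_species_tree(newick, f)` shrinks branches to
emulate larger populations, since only the ratio enters the coalescent.
One master seed drives everything; batch members use sub-streams derived
deterministically from it.

What the generator emulates — and does not. It produces true-model gene
trees (always feasible), copy-number variation across species via losses,
and ILS that grows with k and with shrinking branch lengths. It does not
model sequence evolution or tree reconstruction, per-sample (polymorphic)
locus loss — which would conflict with the no-hemiplasy assumption — gene
conversion, or hemiplasy. Infeasible instances therefore come from explicit
perturbations: `perturb_nni` (random nearest-neighbor interchanges standing
in for reconstruction error; supports and lengths are dropped and can be
reattached with `assign_supports`) and `make_crossed_cherries` (the
canonical infeasible quartet, optionally embedded in a feasible
background). `assign_supports`' conflict-aware rule draws conflicting
branches from 5–45 and others from 55–100, emulating the empirical
association between conflict and poor support without bootstrapping.
Passing tests on these inputs show the algorithm's correctness and the
qualitative trends; they do not certify behavior on reconstructed trees
from real sequence data.

## Verification strategy and problem sizes

The oracle cross-check enumerates every unrooted binary topology on 3–7
leaves ((2n−5)!! each, 945 at n = 7) against a family of leaf maps over 2
species × 2 loci × ≤ 2 samples: all assignments for n ≤ 5 (600 maps at
n = 5), and a fixed seeded sample of 8 (n = 6) or 6 (n = 7) maps per
topology — about 16,000 instances in total, each also checked against the
maximal-placement criterion. The theorem-guarantee batches use 1,000
instances each; rerooting invariance 200 instances × every branch; the
simulator soundness grid covers rates {0, 0.5×, 1×, 2×} × k ∈ {2, 5, 10}
with 42 families per cell (504 total); perturbation and collapse
experiments use 200 families; the ILS trend uses 200 families per sample
count on the half-scale (deep-coalescence) species tree. These sizes keep
the whole verification cycle fast while leaving the Monte-Carlo margins
(binomial-noise allowance for the NNI trend, ≥ 5 percentage points for the
monophyly drop) comfortably clear of their observed values.

## Known limitations

- Multifurcating trees with a reconcilable LEG are reported UNKNOWN; no
  search over binary refinements is attempted.
- The witness is maximal, not minimal or probable; downstream event
  inference should use a dedicated reconciliation method.
- The simulator's forced coalescence at locus origins creates zero-length
  internal branches; topology-level analyses are unaffected.
- Orthology beyond forced equivalence is not inferred: equivalent loci are
  orthologous, but orthologous loci need not be equivalent.
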