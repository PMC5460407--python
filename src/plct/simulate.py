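"""Desk-scale duplication-loss-coalescence simulator with multiple
individuals per species, plus controlled perturbations.

A gene family is generated in two layers, mirroring the standard unified
model. First, loci evolve down the species tree by a birth--death process:
a duplication creates a new, unlinked locus that fixes instantly in all
descendant lineages, and a loss removes the locus from the whole descendant
clade (no hemiplasy). Second, within each locus an independent multispecies
coalescent runs backward in time through the locus's species-tree
embedding, with k sampled lineages per extant species carrying the locus;
at a daughter locus's origin the surviving lineages are forced to coalesce
(the new locus descends from a single gene copy) and the resulting stem
lineage joins the parent locus. Branch lengths are in coalescent units, so
population size enters purely as a scaling of the species tree.

True-model gene trees are feasible by construction; the perturbation
helpers (random NNI moves, crossed-allele cherries) manufacture the
infeasible instances that arise in practice from reconstruction error or
model violations such as gene conversion.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .tree import GeneTree, LeafMap, Node, SpeciesLocus, read_gene_tree
from .labeling import build_plct
from .leg import build_leg, conflicts

__all__ = [
    "SimParams",
    "SimFamily",
    "DEFAULT_SPECIES_TREE",
    "simulate_family",
    "simulate_batch",
    "scale_species_tree",
    "perturb_nni",
    "make_crossed_cherries",
    "assign_supports",
    "random_topology",
]

#: 12-taxon ultrametric species tree, height 3 coalescent units. Terminal
#: branches of 0.4-2.0 coalescent units give substantial but not total
#: incomplete lineage sorting at k >= 2 samples.
DEFAULT_SPECIES_TREE = (
    "((((s1:0.5,s2:0.5):0.5,(s3:0.7,s4:0.7):0.3):1.0,"
    "((s5:0.6,s6:0.6):0.8,(s7:0.9,(s8:0.4,s9:0.4):0.5):0.5):0.6):1.0,"
    "((s10:1.2,s11:1.2):0.8,s12:2.0):1.0);"
)

#: baseline ("1x") duplication and loss rates, events per coalescent unit
#: of species-tree branch length
BASELINE_DUP_RATE = 0.1
BASELINE_LOSS_RATE = 0.1


@dataclass
class SimParams:
    """Simulation parameters.

    Rates are events per coalescent unit of species-tree branch length;
    ``samples_per_species`` is the number of haploid individuals sampled per
    extant species (uniform, or a per-species dict). The seed fixes the full
    output stream.
    """

    species_tree: str = DEFAULT_SPECIES_TREE
    dup_rate: float = BASELINE_DUP_RATE
    loss_rate: float = BASELINE_LOSS_RATE
    samples_per_species: int | dict[str, int] = 2
    seed: int = 0

    def k_for(self, species: str) -> int:
        if isinstance(self.samples_per_species, dict):
            return self.samples_per_species.get(species, 1)
        return self.samples_per_species


@dataclass
class SimFamily:
    """One simulated gene family with full provenance."""

    gene_tree: Optional[GeneTree]
    leaf_map: Optional[LeafMap]
    empty: bool  # all loci lost (or < 2 surviving genes)
    locus_events: list[dict] = field(default_factory=list)  # duplications and losses
    true_locus_of: dict[str, int] = field(default_factory=dict)  # gene -> locus-tree locus id


def scale_species_tree(newick: str, factor: float) -> str:
    """Multiply all branch lengths by ``factor`` (population-size axis)."""
    tree = read_gene_tree(newick)
    for node in tree.preorder():
        if node.length is not None:
            node.length *= factor
    return tree.to_newick(supports=False)


# -- internal species-tree scaffolding --------------------------------------


class _SpNode:
    __slots__ = ("name", "children", "parent", "t_top", "t_bot")

    def __init__(self, name, t_top, t_bot):
        self.name = name
        self.children: list["_SpNode"] = []
        self.parent: Optional["_SpNode"] = None
        self.t_top = t_top  # time (from root, increasing toward present) at branch top
        self.t_bot = t_bot  # time at the node itself


def _parse_species_tree(newick: str) -> tuple[_SpNode, list[_SpNode]]:
    gt = read_gene_tree(newick)
    nodes: list[_SpNode] = []

    def rec(gnode: Node, t_parent: float) -> _SpNode:
        length = gnode.length if gnode.length is not None else 1.0
        sp = _SpNode(gnode.name, t_parent, t_parent + length)
        nodes.append(sp)
        for c in gnode.children:
            child = rec(c, sp.t_bot)
            child.parent = sp
            sp.children.append(child)
        return sp

    root = _SpNode(gt.root.name, 0.0, 0.0)
    nodes.append(root)
    for c in gt.root.children:
        child = rec(c, 0.0)
        child.parent = root
        root.children.append(child)
    return root, nodes


# -- locus birth-death layer -------------------------------------------------


class _Locus:
    __slots__ = ("lid", "origin_node", "origin_time", "parent", "children", "tips")

    def __init__(self, lid, origin_node, origin_time, parent):
        self.lid = lid
        self.origin_node = origin_node  # species node whose branch hosts the origin
        self.origin_time = origin_time
        self.parent: Optional["_Locus"] = parent
        self.children: list["_Locus"] = []
        self.tips: list[_SpNode] = []  # extant species where this locus survives


def simulate_family(params: SimParams) -> SimFamily:
    """Simulate one gene family under the duplication-loss-coalescent model."""
    rng = random.Random(params.seed)
    sp_root, _ = _parse_species_tree(params.species_tree)

    loci: list[_Locus] = []
    events: list[dict] = []
    total_rate = params.dup_rate + params.loss_rate

    def evolve(locus: _Locus, sp: _SpNode, t_from: float) -> None:
        """Evolve ``locus`` along the branch into ``sp`` starting at t_from."""
        t = t_from
        while True:
            if total_rate > 0:
                dt = rng.expovariate(total_rate)
            else:
                dt = float("inf")
            if t + dt >= sp.t_bot:
                break
            t += dt
            if rng.random() < params.loss_rate / total_rate:
                events.append({"type": "loss", "locus": locus.lid, "species_branch": sp.name or "internal", "time": t})
                return
            child = _Locus(len(loci), sp, t, locus)
            loci.append(child)
            locus.children.append(child)
            events.append({"type": "duplication", "locus": locus.lid, "new_locus": child.lid, "species_branch": sp.name or "internal", "time": t})
            evolve(child, sp, t)
        if sp.children:
            for c in sp.children:
                evolve(locus, c, sp.t_bot)
        else:
            locus.tips.append(sp)

    root_locus = _Locus(0, sp_root, 0.0, None)
    loci.append(root_locus)
    for c in sp_root.children:
        evolve(root_locus, c, 0.0)
    if not sp_root.children:  # degenerate single-species tree
        root_locus.tips.append(sp_root)

    # a locus contributes iff it has surviving tips or a contributing child
    contributes: dict[int, bool] = {}
    for locus in sorted(loci, key=lambda l: -l.lid):
        contributes[locus.lid] = bool(locus.tips) or any(
            contributes[c.lid] for c in locus.children
        )

    # species-specific locus ids, in locus creation order per species
    sl_of: dict[tuple[str, int], SpeciesLocus] = {}
    counter: dict[str, int] = {}
    for locus in loci:
        for tip in sorted(locus.tips, key=lambda s: s.name):
            counter[tip.name] = counter.get(tip.name, 0) + 1
            sl_of[(tip.name, locus.lid)] = SpeciesLocus(tip.name, str(counter[tip.name]))

    # -- coalescent layer, deepest loci first --
    assignments: dict[str, SpeciesLocus] = {}
    samples: dict[str, Optional[str]] = {}
    true_locus: dict[str, int] = {}
    stems: dict[int, Node] = {}  # locus id -> stem lineage handed to parent
    stem_entry: dict[int, tuple[_SpNode, float]] = {}

    def coalesce_segment(lineages: list[Node], t_start: float, t_end: float) -> float:
        """Pairwise coalescence among ``lineages`` backward from t_start to t_end."""
        t = t_start
        while len(lineages) > 1:
            m = len(lineages)
            dt = rng.expovariate(m * (m - 1) / 2.0)
            if t - dt < t_end:
                return t_end
            t -= dt
            i, j = rng.sample(range(m), 2)
            a, b = lineages[i], lineages[j]
            parent = Node()
            parent.length = t  # temporary: node time; converted at the end
            parent.add_child(a)
            parent.add_child(b)
            for idx in sorted((i, j), reverse=True):
                lineages.pop(idx)
            lineages.append(parent)
        return t_end

    def run_locus(locus: _Locus) -> Optional[Node]:
        """Coalescent within one locus; returns its stem lineage node."""
        entries: dict[int, list[tuple[float, Node]]] = {}  # species node id -> (time, lineage)
        for tip in locus.tips:
            k = params.k_for(tip.name)
            sl = sl_of[(tip.name, locus.lid)]
            for s in range(1, k + 1):
                gene = f"{tip.name}|{sl.locus}|{s}"
                leaf = Node(name=gene)
                leaf.length = tip.t_bot  # node time
                assignments[gene] = sl
                samples[gene] = str(s)
                true_locus[gene] = locus.lid
                entries.setdefault(id(tip), []).append((tip.t_bot, leaf))
        for child in locus.children:
            if not contributes[child.lid]:
                continue
            sp, t0 = stem_entry[child.lid]
            entries.setdefault(id(sp), []).append((t0, stems[child.lid]))

        # process species nodes deepest-first so children precede parents
        involved: dict[int, _SpNode] = {}

        def mark(sp: _SpNode) -> None:
            while sp is not None and id(sp) not in involved:
                involved[id(sp)] = sp
                if sp is locus.origin_node:
                    break
                sp = sp.parent

        for tip in locus.tips:
            mark(tip)
        for child in locus.children:
            if contributes[child.lid]:
                mark(stem_entry[child.lid][0])
        order = sorted(involved.values(), key=lambda s: -s.t_bot)

        at_top: dict[int, list[Node]] = {}
        for sp in order:
            pool: list[tuple[float, Node]] = list(entries.get(id(sp), []))
            for c in sp.children:
                for lin in at_top.get(id(c), []):
                    pool.append((sp.t_bot, lin))
            # branch top: locus origin if on this branch, else species t_top
            top = locus.origin_time if sp is locus.origin_node else sp.t_top
            # walk backward through entry times
            pool.sort(key=lambda x: -x[0])
            active: list[Node] = []
            t = sp.t_bot
            for entry_t, lin in pool:
                coalesce_segment(active, min(t, sp.t_bot), entry_t)
                t = entry_t
                active.append(lin)
            coalesce_segment(active, t, top)
            if sp is locus.origin_node:
                if locus.parent is None:
                    # root locus: free coalescence above the species root
                    t = top
                    while len(active) > 1:
                        m = len(active)
                        t -= rng.expovariate(m * (m - 1) / 2.0)
                        i, j = rng.sample(range(m), 2)
                        a, b = active[i], active[j]
                        parent = Node()
                        parent.length = t
                        parent.add_child(a)
                        parent.add_child(b)
                        for idx in sorted((i, j), reverse=True):
                            active.pop(idx)
                        active.append(parent)
                    return active[0] if active else None
                # bottleneck: force remaining lineages to coalesce at the origin
                while len(active) > 1:
                    i, j = rng.sample(range(len(active)), 2)
                    a, b = active[i], active[j]
                    parent = Node()
                    parent.length = top
                    parent.add_child(a)
                    parent.add_child(b)
                    for idx in sorted((i, j), reverse=True):
                        active.pop(idx)
                    active.append(parent)
                stem = active[0] if active else None
                if stem is not None:
                    stems[locus.lid] = stem
                    stem_entry[locus.lid] = (sp, top)
                return stem
            at_top[id(sp)] = active
        return None

    root_lineage: Optional[Node] = None
    for locus in sorted(loci, key=lambda l: -l.lid):
        if not contributes[locus.lid]:
            continue
        result = run_locus(locus)
        if locus.lid == 0:
            root_lineage = result

    if root_lineage is None or len(assignments) < 2:
        return SimFamily(None, None, empty=True, locus_events=events, true_locus_of=true_locus)

    # convert node times (stored in .length) into branch lengths
    def fix_lengths(node: Node, parent_time: Optional[float]) -> None:
        t = node.length
        node.length = None if parent_time is None else max(t - parent_time, 0.0)
        for c in node.children:
            fix_lengths(c, t)

    fix_lengths(root_lineage, None)
    while len(root_lineage.children) == 1:
        root_lineage = root_lineage.children[0]
        root_lineage.parent = None
    gene_tree = GeneTree(root_lineage)
    leaf_map = LeafMap(assignments, samples)
    return SimFamily(gene_tree, leaf_map, empty=False, locus_events=events, true_locus_of=true_locus)


def simulate_batch(params: SimParams, n_families: int, max_retries: int = 50) -> list[SimFamily]:
    """n non-empty families; per-family seeds derived from ``params.seed``."""
    out: list[SimFamily] = []
    base = params.seed
    i = 0
    while len(out) < n_families:
        p = SimParams(
            species_tree=params.species_tree,
            dup_rate=params.dup_rate,
            loss_rate=params.loss_rate,
            samples_per_species=params.samples_per_species,
            seed=(base * 1_000_003 + i) % (2**31 - 1),
        )
        i += 1
        fam = simulate_family(p)
        if not fam.empty:
            out.append(fam)
        elif i > (n_families + 1) * max_retries:
            raise RuntimeError("too many empty families; check loss rate")
    return out


def random_topology(leaf_names: Sequence[str], seed: int = 0) -> GeneTree:
    """Random unrooted binary topology by repeated random joins."""
    rng = random.Random(seed)
    subtrees = list(leaf_names)
    if len(subtrees) < 3:
        raise ValueError("need at least 3 leaves")
    rng.shuffle(subtrees)
    while len(subtrees) > 3:
        i, j = sorted(rng.sample(range(len(subtrees)), 2), reverse=True)
        a = subtrees.pop(i)
        b = subtrees.pop(j)
        subtrees.append(f"({a},{b})")
    return read_gene_tree("(" + ",".join(subtrees) + ");")


# -- perturbations -----------------------------------------------------------


def perturb_nni(tree: GeneTree, n_moves: int, seed: int = 0) -> GeneTree:
    """Apply ``n_moves`` uniform random nearest-neighbor interchanges.

    Operates on the unrooted topology; the leaf set is preserved. Supports
    and branch lengths are dropped (an NNI-perturbed tree stands for an
    erroneous reconstruction; reattach supports with assign_supports).
    """
    if not tree.is_binary:
        raise ValueError("NNI perturbation requires a binary tree")
    if len(tree.leaves) < 4:
        return tree.copy()  # no internal edge to interchange across
    rng = random.Random(seed)
    adj, _ = tree._edge_table()
    names = {n.id: n.name for n in tree.preorder()}

    def is_leaf(nid: str) -> bool:
        return names.get(nid) is not None

    for _ in range(n_moves):
        internal_edges = sorted(
            (u, v)
            for u in adj
            for v in adj[u]
            if u < v and not is_leaf(u) and not is_leaf(v)
        )
        if not internal_edges:
            break
        u, v = rng.choice(internal_edges)
        a = rng.choice(sorted(x for x in adj[u] if x != v))
        b = rng.choice(sorted(x for x in adj[v] if x != u))
        adj[u][adj[u].index(a)] = b
        adj[v][adj[v].index(b)] = a
        adj[a][adj[a].index(u)] = v
        adj[b][adj[b].index(v)] = u

    some_leaf = min(n for n in adj if is_leaf(n))
    start = adj[some_leaf][0]

    def newick(nid: str, parent: Optional[str]) -> str:
        nbs = [x for x in adj[nid] if x != parent]
        if not nbs:
            return names[nid]
        return "(" + ",".join(newick(x, nid) for x in nbs) + ")"

    return read_gene_tree(newick(start, None) + ";")


def make_crossed_cherries(
    species: str = "A",
    loci: tuple[str, str] = ("1", "2"),
    background: Optional[tuple[GeneTree, LeafMap]] = None,
) -> tuple[GeneTree, LeafMap]:
    """The canonical infeasible quartet: two loci crossed across two individuals.

    Produces ((x1_i, x2_i), (x1_ii, x2_ii)): within each individual the two
    loci pair up, so every allele path covers the whole quartet and no
    branch is left for the required duplications. Optionally grafted next to
    a feasible background instance — the conflict survives embedding.
    """
    l1, l2 = loci
    g = {
        "a1i": (SpeciesLocus(species, l1), "i"),
        "a2i": (SpeciesLocus(species, l2), "i"),
        "a1ii": (SpeciesLocus(species, l1), "ii"),
        "a2ii": (SpeciesLocus(species, l2), "ii"),
    }
    names = {
        k: f"{species}|{sl.locus}|{smp}" for k, (sl, smp) in g.items()
    }
    nwk = f"(({names['a1i']},{names['a2i']}),({names['a1ii']},{names['a2ii']}));"
    quartet = read_gene_tree(nwk)
    qmap = LeafMap(
        {names[k]: sl for k, (sl, _) in g.items()},
        {names[k]: smp for k, (sl, smp) in g.items()},
    )
    if background is None:
        return quartet, qmap
    bg_tree, bg_map = background
    overlap = bg_tree.leaf_names & quartet.leaf_names
    if overlap:
        raise ValueError(f"background shares leaf names with the cherry: {sorted(overlap)}")
    combined_nwk = "(" + quartet.to_newick()[:-1] + "," + bg_tree.to_newick(supports=False)[:-1] + ");"
    combined = read_gene_tree(combined_nwk)
    assignments = dict(bg_map.assignments)
    assignments.update(qmap.assignments)
    smps = dict(bg_map.samples)
    smps.update(qmap.samples)
    return combined, LeafMap(assignments, smps)


def assign_supports(
    tree: GeneTree,
    rule: str = "constant",
    value: float = 100.0,
    seed: int = 0,
    leaf_map: Optional[LeafMap] = None,
    low: tuple[float, float] = (5.0, 45.0),
    high: tuple[float, float] = (55.0, 100.0),
) -> GeneTree:
    """Attach support values to internal branches by rule.

    ``constant``: every internal branch gets ``value``. ``random``: uniform
    draws on [0, 100]. ``conflict-aware``: branches in weak conflict (needs
    ``leaf_map``) draw from ``low``, others from ``high`` — emulating the
    empirical association between conflict and poor support without
    sequence bootstrapping.
    """
    rng = random.Random(seed)
    out = tree.copy()
    weak: set[str] = set()
    if rule == "conflict-aware":
        if leaf_map is None:
            raise ValueError("conflict-aware supports require a leaf map")
        plct = build_plct(out, leaf_map)
        leg = build_leg(plct)
        weak = set(conflicts(leg, plct).weak_conflict_branches)
    elif rule not in ("constant", "random"):
        raise ValueError(f"unknown support rule: {rule!r}")

    for node in out.preorder():
        if node.is_leaf or node is out.root:
            continue
        if rule == "constant":
            node.support = value
        elif rule == "random":
            node.support = round(rng.uniform(0.0, 100.0), 1)
        else:
            bid = out.branch_id_of(node)
            lo, hi = low if bid in weak else high
            node.support = round(rng.uniform(lo, hi), 1)
    # keep the two sides of a merged root branch consistent
    if len(out.root.children) == 2:
        sups = [c.support for c in out.root.children if not c.is_leaf and c.support is not None]
        if sups:
            for c in out.root.children:
                if not c.is_leaf:
                    c.support = min(sups)
    return GeneTree(out.root)
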