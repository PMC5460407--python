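"""Diagnostic statistics: monophyly of species-specific loci, bootstrap
support of conflicting branches, and feasibility sweeps under collapse of
poorly supported branches.

When all genes of a species-specific locus form a clade, the extra samples
agree on their placement and add no topological information; the fraction
of monophyletic loci therefore tracks how much the multiple samples
actually constrain the reconciliation. Collapsing branches below a support
threshold turns a binary tree multifurcating: an irreconcilable LEG still
proves infeasibility, but reconcilable multifurcating trees become UNKNOWN,
so sweeps over thresholds trade verdict certainty against robustness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats as sps

from .feasibility import Status, decide
from .labeling import build_plct
from .leg import build_leg, conflicts
from .tree import GeneTree, LeafMap, SpeciesLocus

__all__ = [
    "MonophylyReport",
    "CollapseSweepReport",
    "monophyly",
    "collapse_low_support",
    "collapse_sweep",
    "conflict_support_comparison",
    "batch_table",
]


@dataclass
class MonophylyReport:
    per_locus: dict[SpeciesLocus, bool]
    tree_monophyletic: bool  # all loci monophyletic
    fraction_loci: float
    mode: str  # "rooted" or "unrooted"


def monophyly(tree: GeneTree, leaf_map: LeafMap, mode: str = "rooted") -> MonophylyReport:
    """Per-locus monophyly: is each locus's gene set exactly a clade?

    ``mode="rooted"`` tests rooted clades; ``mode="unrooted"`` accepts either
    side of any branch bipartition (appropriate since the feasibility
    machinery itself is rooting-independent). Singleton loci are trivially
    monophyletic.
    """
    leaf_map.validate_against(tree)
    if mode not in ("rooted", "unrooted"):
        raise ValueError(f"unknown monophyly mode: {mode!r}")
    clades: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = frozenset([node.name])
        else:
            s = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = s
        clades.add(s)
    all_leaves = frozenset(tree.leaf_names)
    if mode == "unrooted":
        clades |= {all_leaves - s for s in list(clades)}

    per_locus: dict[SpeciesLocus, bool] = {}
    for sl, genes in leaf_map.genes_by_locus().items():
        per_locus[sl] = frozenset(genes) in clades
    n = len(per_locus)
    frac = sum(per_locus.values()) / n if n else 1.0
    return MonophylyReport(
        per_locus=per_locus,
        tree_monophyletic=all(per_locus.values()),
        fraction_loci=frac,
        mode=mode,
    )


def collapse_low_support(tree: GeneTree, threshold: float) -> GeneTree:
    """Contract every internal unrooted branch with known support < threshold.

    Leaf (pendant) branches are never contracted; branches with unknown
    support are kept. Returns a new tree; the input is untouched.
    """
    out = tree.copy()
    # internal non-root nodes in postorder so children move before parents act
    for node in list(out.postorder()):
        if node.is_leaf or node is out.root:
            continue
        if node.parent is out.root and len(out.root.children) == 2:
            continue  # merged root branch handled below
        if node.support is not None and node.support < threshold:
            parent = node.parent
            i = parent.children.index(node)
            for c in node.children:
                c.parent = parent
            parent.children[i : i + 1] = node.children
    if len(out.root.children) == 2:
        a, b = out.root.children
        if not a.is_leaf and not b.is_leaf:
            sup = [c.support for c in (a, b) if c.support is not None]
            if sup and min(sup) < threshold:
                kids = a.children + b.children
                for c in kids:
                    c.parent = out.root
                out.root.children = kids
    return GeneTree(out.root)


@dataclass
class CollapseSweepReport:
    thresholds: list[float]
    counts: dict[float, dict[Status, int]]  # per threshold, verdict counts
    verdicts: dict[float, list[Status]]  # per threshold, per-instance verdicts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "threshold": t,
                "n_feasible": self.counts[t].get(Status.FEASIBLE, 0),
                "n_infeasible": self.counts[t].get(Status.INFEASIBLE, 0),
                "n_unknown": self.counts[t].get(Status.UNKNOWN, 0),
            }
            for t in self.thresholds
        ]
        return pd.DataFrame(rows)


def collapse_sweep(
    instances: Sequence[tuple[GeneTree, LeafMap]], thresholds: Iterable[float]
) -> CollapseSweepReport:
    """Feasibility verdicts per instance after collapsing at each threshold."""
    thresholds = sorted(thresholds)
    counts: dict[float, dict[Status, int]] = {}
    verdicts: dict[float, list[Status]] = {}
    for t in thresholds:
        per: list[Status] = []
        for gtree, lmap in instances:
            v = decide(collapse_low_support(gtree, t), lmap)
            per.append(v.status)
        verdicts[t] = per
        c: dict[Status, int] = {}
        for s in per:
            c[s] = c.get(s, 0) + 1
        counts[t] = c
    return CollapseSweepReport(thresholds=list(thresholds), counts=counts, verdicts=verdicts)


def conflict_support_comparison(
    tree: GeneTree, leaf_map: LeafMap
) -> tuple[pd.DataFrame, dict[str, Optional[tuple[float, float]]]]:
    """Bootstrap support of conflicting vs non-conflicting internal branches.

    Returns a per-branch table (branch_id, support, conflict class: strong /
    weak / none, over internal branches with known support) and, for each
    conflict definition, the two-sided Wilcoxon rank-sum statistic and
    p-value (normal approximation) comparing conflicting vs non-conflicting
    supports — or None when either group is empty.
    """
    plct = build_plct(tree, leaf_map)
    leg = build_leg(plct)
    report = conflicts(leg, plct)
    strong = set(report.strong_conflict_branches)
    weak = set(report.weak_conflict_branches)

    rows = []
    for bid in tree.unrooted_branches():
        if tree.is_leaf_branch(bid):
            continue
        sup = tree.branch_support(bid)
        if sup is None:
            continue
        cls = "strong" if bid in strong else "weak" if bid in weak else "none"
        rows.append({"branch_id": bid, "support": sup, "conflict": cls})
    df = pd.DataFrame(rows, columns=["branch_id", "support", "conflict"])

    results: dict[str, Optional[tuple[float, float]]] = {}
    for definition, members in (("weak", weak), ("strong", strong)):
        if df.empty:
            results[definition] = None
            continue
        a = df.loc[df["branch_id"].isin(members), "support"]
        b = df.loc[~df["branch_id"].isin(members), "support"]
        if len(a) == 0 or len(b) == 0:
            results[definition] = None
        else:
            stat, p = sps.ranksums(a, b)
            results[definition] = (float(stat), float(p))
    return df, results


def batch_table(instances: Sequence[tuple[GeneTree, LeafMap]], mode: str = "rooted") -> dict:
    """Batch summary: tree/locus counts, monophyly fractions, infeasible fraction."""
    n_trees = len(instances)
    n_loci = 0
    mono_loci = 0
    mono_trees = 0
    infeasible = 0
    for gtree, lmap in instances:
        rep = monophyly(gtree, lmap, mode=mode)
        n_loci += len(rep.per_locus)
        mono_loci += sum(rep.per_locus.values())
        mono_trees += int(rep.tree_monophyletic)
        if decide(gtree, lmap).status is Status.INFEASIBLE:
            infeasible += 1
    return {
        "trees": n_trees,
        "loci": n_loci,
        "monophyletic_trees": mono_trees,
        "monophyletic_trees_pct": 100.0 * mono_trees / n_trees if n_trees else 0.0,
        "monophyletic_loci": mono_loci,
        "monophyletic_loci_pct": 100.0 * mono_loci / n_loci if n_loci else 0.0,
        "infeasible": infeasible,
        "infeasible_pct": 100.0 * infeasible / n_trees if n_trees else 0.0,
        "monophyly_mode": mode,
    }
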