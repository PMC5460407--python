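"""Reconciliation feasibility of a gene tree under duplication, loss and
coalescence with multiple haploid samples per species.

With several samples per species and several species-specific loci, a gene
tree topology may admit *no* valid reconciliation with any species tree:
allele constraints (no duplication between same-locus genes) can contradict
paralog constraints (>= 1 duplication between different-locus genes of one
species). The decision depends only on the gene tree topology and the leaf
map — not on the species tree or the rooting.

The pipeline is: build the PLCT, build the LEG, inspect its components.
For a binary gene tree the verdict is exact: feasible iff no LEG component
contains two loci of one species. For a multifurcating tree an
irreconcilable LEG still proves infeasibility, but a reconcilable LEG
leaves feasibility open, reported as the first-class verdict UNKNOWN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import NamedTuple, Optional

from .labeling import PLCT, build_plct
from .leg import LEG, ConflictReport, build_leg, conflicts
from .tree import GeneTree, LeafMap

__all__ = [
    "Status",
    "Verdict",
    "Violation",
    "decide",
    "witness_duplications",
    "validate_duplication_set",
    "verdict_report",
    "EXIT_CODES",
]


class Status(str, Enum):
    FEASIBLE = "FEASIBLE"
    INFEASIBLE = "INFEASIBLE"
    UNKNOWN = "UNKNOWN"


#: stable exit codes for shell pipelines
EXIT_CODES = {Status.FEASIBLE: 0, Status.INFEASIBLE: 3, Status.UNKNOWN: 4}


class Violation(NamedTuple):
    """One violated constraint between a pair of genes."""

    kind: str  # "allele" (duplication on an allele path) or "paralog" (none on a paralog path)
    gene_a: str
    gene_b: str


@dataclass
class Verdict:
    status: Status
    conflict: ConflictReport
    witness: Optional[frozenset[str]]  # duplication branches, only when FEASIBLE
    n_leaves: int
    is_binary: bool
    plct: PLCT
    leg: LEG


def decide(tree: GeneTree, leaf_map: LeafMap) -> Verdict:
    """Decide reconciliation feasibility of (tree, leaf map).

    Returns FEASIBLE (with a witness duplication set) or INFEASIBLE for
    binary trees; multifurcating trees yield INFEASIBLE or UNKNOWN.
    """
    plct = build_plct(tree, leaf_map)
    leg = build_leg(plct)
    report = conflicts(leg, plct)
    binary = tree.is_binary
    if report.has_conflict:
        status = Status.INFEASIBLE
        witness = None
    elif binary:
        status = Status.FEASIBLE
        witness = witness_duplications(plct)
    else:
        status = Status.UNKNOWN
        witness = None
    return Verdict(
        status=status,
        conflict=report,
        witness=witness,
        n_leaves=len(tree.leaves),
        is_binary=binary,
        plct=plct,
        leg=leg,
    )


def witness_duplications(plct: PLCT) -> frozenset[str]:
    """Maximal admissible duplication placement: every unlabeled branch.

    Valid whenever the LEG is reconcilable and the tree binary: labeled
    branches are never touched (allele constraints hold), and any
    same-species cross-locus pair lies in different label subtrees, so its
    path crosses at least one unlabeled branch. The maximal set is the
    canonical witness; it makes no claim of parsimony or probability.
    """
    leg = build_leg(plct)
    if conflicts(leg, plct).has_conflict:
        raise ValueError("witness requested for an irreconcilable LEG")
    if not plct.tree.is_binary:
        raise ValueError("witness construction requires a binary gene tree")
    return frozenset(b for b, s in plct.labels.items() if not s)


def validate_duplication_set(
    tree: GeneTree, leaf_map: LeafMap, dups: frozenset[str] | set[str]
) -> tuple[bool, list[Violation]]:
    """Check a duplication placement against allele and paralog constraints.

    Valid iff no duplication branch lies on the path between any two genes
    of the same species-specific locus, and at least one duplication branch
    lies on the path between every same-species pair of genes at different
    loci (regardless of individual).
    """
    leaf_map.validate_against(tree)
    dups = frozenset(dups)
    known = set(tree.unrooted_branches())
    unknown = dups - known
    if unknown:
        raise ValueError(f"duplication branch id(s) not in tree: {sorted(unknown)}")

    violations: list[Violation] = []
    by_locus = leaf_map.genes_by_locus()
    for genes in by_locus.values():
        for a, b in combinations(genes, 2):
            if tree.path_branches(a, b) & dups:
                violations.append(Violation("allele", a, b))
    by_species: dict[str, list] = {}
    for sl, genes in by_locus.items():
        by_species.setdefault(sl.species, []).append((sl.locus, genes))
    for groups in by_species.values():
        for (_, genes_x), (_, genes_y) in combinations(groups, 2):
            for a in genes_x:
                for b in genes_y:
                    if not (tree.path_branches(a, b) & dups):
                        violations.append(Violation("paralog", a, b))
    return (not violations), violations


def verdict_report(verdict: Verdict) -> dict:
    """JSON-ready report of a feasibility verdict."""
    return {
        "status": verdict.status.value,
        "conflicting_components": [
            {
                "members": [str(sl) for sl in comp],
                "species_with_multiple_loci": bad,
            }
            for comp, bad in verdict.conflict.conflicting_components
        ],
        "strong_conflict_branches": verdict.conflict.strong_conflict_branches,
        "weak_conflict_branches": verdict.conflict.weak_conflict_branches,
        "witness_branches": sorted(verdict.witness) if verdict.witness is not None else None,
        "n_leaves": verdict.n_leaves,
        "is_binary": verdict.is_binary,
    }


def verdict_json(verdict: Verdict, **kwargs) -> str:
    return json.dumps(verdict_report(verdict), indent=2, **kwargs)
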