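"""Locus equivalence graph (LEG).

Every branch of the gene tree is a gene lineage at a point in time and can
exist at only one locus; a branch carrying labels of several
species-specific loci therefore forces those loci to descend from a common
ancestral locus through speciations alone ("locus equivalence").
Equivalence is transitive, so the connected components of the graph whose
vertices are species-specific loci and whose edges join co-labeling loci
are sets of loci forced to be mutually orthologous. A component containing
two loci of one species is a contradiction — those loci must be paralogs —
and drives the infeasibility verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .labeling import PLCT
from .tree import SpeciesLocus

__all__ = ["LEG", "ConflictReport", "build_leg", "conflicts", "write_leg_tsv"]


@dataclass
class LEG:
    """Simple graph on species-specific loci; edges are forced equivalences.

    Components are canonically ordered by their lexicographically smallest
    member so that reports are byte-stable across input orderings. Isolated
    vertices form singleton components.
    """

    graph: nx.Graph
    components: list[tuple[SpeciesLocus, ...]] = field(default_factory=list)
    component_of: dict[SpeciesLocus, int] = field(default_factory=dict)

    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges()}


@dataclass
class ConflictReport:
    """Conflicting components and the branches implicated in them.

    A component conflicts if it contains >= 2 loci of one species. A branch
    is a *strong* conflict if its own label set already contains >= 2 loci
    of one species, and a *weak* conflict if any of its labels lies in a
    conflicting component; strong branches are always weak.
    """

    conflicting_components: list[tuple[tuple[SpeciesLocus, ...], dict[str, list[str]]]]
    strong_conflict_branches: list[str]
    weak_conflict_branches: list[str]

    @property
    def has_conflict(self) -> bool:
        return bool(self.conflicting_components)


def build_leg(plct: PLCT) -> LEG:
    """Construct the LEG from a PLCT.

    One vertex per species-specific locus in the leaf map (isolated vertices
    included); for every multi-labeled branch, an edge between every pair of
    its labels, annotated with the witnessing branch ids.
    """
    g = nx.Graph()
    g.add_nodes_from(plct.leaf_map.species_loci())
    for bid in plct.tree.unrooted_branches():
        labels = plct.labels[bid]
        if len(labels) < 2:
            continue
        for x, y in combinations(sorted(labels), 2):
            if g.has_edge(x, y):
                g[x][y]["witnesses"].append(bid)
            else:
                g.add_edge(x, y, witnesses=[bid])
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    component_of = {sl: i for i, comp in enumerate(comps) for sl in comp}
    return LEG(graph=g, components=comps, component_of=component_of)


def conflicts(leg: LEG, plct: PLCT) -> ConflictReport:
    """Identify conflicting components and strong/weak conflict branches."""
    conflicting: list[tuple[tuple[SpeciesLocus, ...], dict[str, list[str]]]] = []
    conflicting_vertices: set[SpeciesLocus] = set()
    for comp in leg.components:
        per_species: dict[str, list[str]] = {}
        for sl in comp:
            per_species.setdefault(sl.species, []).append(sl.locus)
        bad = {sp: sorted(loci) for sp, loci in per_species.items() if len(loci) >= 2}
        if bad:
            conflicting.append((comp, dict(sorted(bad.items()))))
            conflicting_vertices.update(comp)

    strong: list[str] = []
    weak: list[str] = []
    for bid in plct.tree.unrooted_branches():
        labels = plct.labels[bid]
        if not labels:
            continue
        species_counts: dict[str, int] = {}
        for sl in labels:
            species_counts[sl.species] = species_counts.get(sl.species, 0) + 1
        if any(c >= 2 for c in species_counts.values()):
            strong.append(bid)
        if any(sl in conflicting_vertices for sl in labels):
            weak.append(bid)
    return ConflictReport(
        conflicting_components=conflicting,
        strong_conflict_branches=strong,
        weak_conflict_branches=weak,
    )


def write_leg_tsv(leg: LEG, edge_path: str, component_path: str) -> None:
    """Export the LEG as an edge-list TSV and a component TSV."""
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("locus1\tlocus2\twitness_branch_ids\n")
        for x, y in sorted(tuple(sorted(e)) for e in leg.graph.edges()):
            wit = ",".join(leg.graph[x][y]["witnesses"])
            fh.write(f"{x}\t{y}\t{wit}\n")
    with open(component_path, "w", encoding="utf-8") as fh:
        fh.write("component_id\tmembers\n")
        for i, comp in enumerate(leg.components):
            fh.write(f"{i}\t{','.join(str(sl) for sl in comp)}\n")
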