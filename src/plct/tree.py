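"""Gene tree and leaf-map data model.

A gene tree here is the coalescent tree of a gene family: a rooted,
leaf-labeled tree whose internal nodes may carry bootstrap support values.
The feasibility machinery only ever looks at the *unrooted* view of this
tree, so the model exposes unrooted branches with stable identifiers: each
branch is named after its child node, and when the root has exactly two
children the two root edges are merged into a single unrooted branch with a
canonical composite identifier.

Leaf maps assign every gene (leaf) to a species-specific locus — a locus
identified within one species, e.g. via a reference genome — and optionally
to a sample (haploid individual). Sample identity never enters the
algorithm; it is carried for provenance only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional

import dendropy

__all__ = [
    "SpeciesLocus",
    "Node",
    "GeneTree",
    "LeafMap",
    "read_gene_tree",
    "read_leaf_map",
    "parse_leafmap_from_names",
    "write_gene_tree",
]


class SpeciesLocus(NamedTuple):
    """A species-specific locus: a locus identified within one species.

    Cross-species correspondence between loci is unknown a priori; equality
    is component-wise and ordering is lexicographic (species, then locus) so
    reports are deterministic.
    """

    species: str
    locus: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.species}:{self.locus}"


class Node:
    """Tree node. Branch attributes (length, support) live on the child."""

    __slots__ = ("id", "name", "parent", "children", "length", "support")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.id: str = ""
        self.name = name
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.length = length
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.id or self.name}>"


_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


class GeneTree:
    """Rooted gene tree with an unrooted-branch view.

    Invariants enforced at construction: single root, unique leaf names, no
    unifurcations (a root of out-degree 1 is suppressed while parsing).
    """

    def __init__(self, root: Node):
        self.root = root
        self.nodes: dict[str, Node] = {}
        self.leaves: dict[str, Node] = {}
        self._index()

    def _index(self) -> None:
        self.nodes.clear()
        self.leaves.clear()
        seen_names = set()
        for node in self.preorder():
            if node.is_leaf:
                if node.name is None or node.name == "":
                    raise ValueError("unnamed leaf in gene tree")
                if node.name in seen_names:
                    raise ValueError(f"duplicate leaf name: {node.name!r}")
                seen_names.add(node.name)
        counter = 0
        for node in self.preorder():
            if node.is_leaf:
                node.id = node.name  # type: ignore[assignment]
            else:
                nid = f"n{counter}"
                counter += 1
                while nid in seen_names:
                    nid = f"n{counter}"
                    counter += 1
                node.id = nid
            self.nodes[node.id] = node
            if node.is_leaf:
                self.leaves[node.name] = node  # type: ignore[index]

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    @property
    def leaf_names(self) -> set[str]:
        return set(self.leaves)

    # -- unrooted view -----------------------------------------------------

    @property
    def _root_merged(self) -> bool:
        return len(self.root.children) == 2

    @property
    def merged_root_branch_id(self) -> Optional[str]:
        if not self._root_merged:
            return None
        a, b = self.root.children
        return "+".join(sorted((a.id, b.id)))

    def branch_id_of(self, node: Node) -> str:
        """Unrooted branch identifier for the branch above ``node``."""
        if node is self.root:
            raise ValueError("the root has no branch above it")
        if node.parent is self.root and self._root_merged:
            return self.merged_root_branch_id  # type: ignore[return-value]
        return node.id

    def unrooted_branches(self) -> list[str]:
        """All branch ids of the unrooted view, in deterministic order."""
        seen: dict[str, None] = {}
        for node in self.preorder():
            if node is self.root:
                continue
            seen.setdefault(self.branch_id_of(node), None)
        return list(seen)

    def branch_nodes(self, branch_id: str) -> list[Node]:
        """Child node(s) realizing an unrooted branch (two for the merged root branch)."""
        if self._root_merged and branch_id == self.merged_root_branch_id:
            return list(self.root.children)
        node = self.nodes.get(branch_id)
        if node is None or node is self.root:
            raise KeyError(f"unknown branch id: {branch_id!r}")
        return [node]

    def is_leaf_branch(self, branch_id: str) -> bool:
        nodes = self.branch_nodes(branch_id)
        if len(nodes) == 2:  # merged root branch: pendant iff either side is a leaf
            return any(n.is_leaf for n in nodes)
        node = nodes[0]
        return node.is_leaf or (node.parent is self.root and self._root_merged)

    def branch_support(self, branch_id: str) -> Optional[float]:
        """Support of an unrooted branch (minimum of the two sides for the merged root branch)."""
        nodes = self.branch_nodes(branch_id)
        vals = [n.support for n in nodes if not n.is_leaf and n.support is not None]
        return min(vals) if vals else None

    @property
    def is_binary(self) -> bool:
        """True iff every internal node of the unrooted view has degree 3.

        Vacuously true for a two-leaf tree (a single unrooted branch).
        """
        if len(self.leaves) < 2:
            return False
        for node in self.preorder():
            if node.is_leaf:
                continue
            if node is self.root:
                if len(node.children) not in (2, 3):
                    return False
                # out-degree 2 root vanishes in the unrooted view; 3 is a
                # degree-3 unrooted node.
            elif len(node.children) != 2:
                return False
        return True

    # -- paths -------------------------------------------------------------

    def path_branches(self, leaf_a: str, leaf_b: str) -> frozenset[str]:
        """Branch ids (unrooted view) on the path between two leaves."""
        na, nb = self.leaves[leaf_a], self.leaves[leaf_b]
        anc_a = {}
        node: Optional[Node] = na
        while node is not None:
            anc_a[id(node)] = node
            node = node.parent
        path_nodes: list[Node] = []
        node = nb
        while id(node) not in anc_a:
            path_nodes.append(node)
            node = node.parent  # type: ignore[assignment]
        lca = node
        node = na
        while node is not lca:
            path_nodes.append(node)
            node = node.parent  # type: ignore[assignment]
        return frozenset(self.branch_id_of(n) for n in path_nodes)

    def branch_bipartitions(self) -> dict[str, frozenset[str]]:
        """Map branch id -> canonical leaf-set side of its bipartition.

        The canonical side is the one *not* containing the lexicographically
        smallest leaf, so bipartitions compare across rerootings.
        """
        ref = min(self.leaves)
        below: dict[int, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = {node.name}  # type: ignore[arg-type]
            else:
                s: set[str] = set()
                for c in node.children:
                    s |= below[id(c)]
                below[id(node)] = s
        all_leaves = self.leaf_names
        out: dict[str, frozenset[str]] = {}
        for bid in self.unrooted_branches():
            node = self.branch_nodes(bid)[0]
            side = below[id(node)]
            if ref in side:
                side = all_leaves - side
            out[bid] = frozenset(side)
        return out

    # -- structural operations ---------------------------------------------

    def copy(self) -> "GeneTree":
        def rec(node: Node) -> Node:
            clone = Node(node.name, node.length, node.support)
            for c in node.children:
                clone.add_child(rec(c))
            return clone

        return GeneTree(rec(self.root))

    def _edge_table(self) -> tuple[dict[str, list[str]], dict[frozenset, dict]]:
        """Unrooted adjacency keyed by node id plus per-edge attributes."""
        adj: dict[str, list[str]] = {n.id: [] for n in self.preorder()}
        attrs: dict[frozenset, dict] = {}

        def connect(u: str, v: str, length, support):
            adj[u].append(v)
            adj[v].append(u)
            attrs[frozenset((u, v))] = {"length": length, "support": support}

        if self._root_merged:
            a, b = self.root.children
            del adj[self.root.id]
            length = None
            if a.length is not None or b.length is not None:
                length = (a.length or 0.0) + (b.length or 0.0)
            support = self.branch_support(self.merged_root_branch_id)  # type: ignore[arg-type]
            connect(a.id, b.id, length, support)
            skip = {id(a), id(b)}
        else:
            skip = set()
        for node in self.preorder():
            if node is self.root or id(node) in skip:
                continue
            sup = node.support if not node.is_leaf else None
            connect(node.parent.id, node.id, node.length, sup)  # type: ignore[union-attr]
        return adj, attrs

    def reroot_on_branch(self, branch_id: str) -> "GeneTree":
        """New tree rooted in the middle of the given unrooted branch.

        Branch supports follow the unrooted branches they annotate; the split
        branch's length, if any, is halved across the two root edges.
        """
        adj, attrs = self._edge_table()
        nodes = self.branch_nodes(branch_id)
        if len(nodes) == 2:
            u, v = nodes[0].id, nodes[1].id
        else:
            child = nodes[0]
            u, v = child.parent.id, child.id  # type: ignore[union-attr]

        names = {n.id: n.name for n in self.preorder()}

        def build(nid: str, parent_id: Optional[str]) -> Node:
            node = Node(names[nid])
            for nb in adj[nid]:
                if nb == parent_id:
                    continue
                child = build(nb, nid)
                e = attrs[frozenset((nid, nb))]
                child.length = e["length"]
                if not child.is_leaf:
                    child.support = e["support"]
                node.add_child(child)
            return node

        root = Node()
        eu = attrs[frozenset((u, v))]
        half = eu["length"] / 2.0 if eu["length"] is not None else None
        cu = build(u, v)
        cv = build(v, u)
        for c in (cu, cv):
            c.length = half
            if not c.is_leaf:
                c.support = eu["support"]
            root.add_child(c)
        return GeneTree(root)

    # -- serialization -----------------------------------------------------

    def to_newick(self, lengths: bool = True, supports: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = _quote_label(node.name)  # type: ignore[arg-type]
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if supports and node.support is not None and node is not self.root:
                    s += _fmt_num(node.support)
            if lengths and node.length is not None and node is not self.root:
                s += f":{_fmt_num(node.length)}"
            return s

        return fmt(self.root) + ";"


def _fmt_num(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def _quote_label(label: str) -> str:
    if re.search(r"[\s()\[\]{}:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_gene_tree(source: str) -> GeneTree:
    """Parse a gene tree from a Newick string or a file path.

    Numeric internal-node labels are interpreted as branch support values
    (e.g. bootstrap percentages); non-numeric labels are ignored. A root of
    out-degree 1 is suppressed, as are internal unifurcations.
    """
    if "(" not in source and ";" not in source:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
            return Node(name=name, length=dnode.edge.length)
        support = None
        if dnode.label is not None and _NUMERIC_RE.match(dnode.label.strip()):
            support = float(dnode.label)
        node = Node(length=dnode.edge.length, support=support)
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    dtree.suppress_unifurcations()
    root = convert(dtree.seed_node)
    while len(root.children) == 1 and not root.children[0].is_leaf:
        root = root.children[0]
        root.parent = None
        root.length = None
        root.support = None
    return GeneTree(root)


def write_gene_tree(tree: GeneTree, path: str, **kwargs) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick(**kwargs) + "\n")


# ---------------------------------------------------------------------------
# Leaf maps


@dataclass
class LeafMap:
    """Assignment of each gene name to a species-specific locus (+ sample)."""

    assignments: dict[str, SpeciesLocus]
    samples: dict[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.assignments:
            self.samples.setdefault(g, None)

    @property
    def genes(self) -> set[str]:
        return set(self.assignments)

    def species_loci(self) -> list[SpeciesLocus]:
        """All distinct species-specific loci, lexicographically sorted."""
        return sorted(set(self.assignments.values()))

    def genes_by_locus(self) -> dict[SpeciesLocus, list[str]]:
        out: dict[SpeciesLocus, list[str]] = {}
        for g in sorted(self.assignments):
            out.setdefault(self.assignments[g], []).append(g)
        return out

    def loci_by_species(self) -> dict[str, list[str]]:
        out: dict[str, set[str]] = {}
        for sl in self.assignments.values():
            out.setdefault(sl.species, set()).add(sl.locus)
        return {sp: sorted(loci) for sp, loci in sorted(out.items())}

    def validate_against(self, tree: GeneTree) -> None:
        """Raise unless the map's domain equals the tree's leaf set exactly."""
        missing = tree.leaf_names - self.genes
        extra = self.genes - tree.leaf_names
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"unmapped leaves: {sorted(missing)}")
            if extra:
                parts.append(f"mapped genes absent from tree: {sorted(extra)}")
            raise ValueError("leaf map / gene tree mismatch: " + "; ".join(parts))

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            has_sample = any(s is not None for s in self.samples.values())
            cols = ["gene", "species", "locus"] + (["sample"] if has_sample else [])
            fh.write("\t".join(cols) + "\n")
            for g in sorted(self.assignments):
                sl = self.assignments[g]
                row = [g, sl.species, sl.locus]
                if has_sample:
                    row.append(self.samples.get(g) or "")
                fh.write("\t".join(row) + "\n")


def read_leaf_map(source) -> LeafMap:
    """Read a leaf map from TSV with header ``gene  species  locus  [sample]``."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"gene", "species", "locus"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"leaf map TSV missing required column(s): {sorted(missing)}")
    if df["gene"].duplicated().any():
        dups = sorted(df.loc[df["gene"].duplicated(), "gene"].unique())
        raise ValueError(f"duplicate gene row(s) in leaf map: {dups}")
    assignments = {}
    samples: dict[str, Optional[str]] = {}
    for row in df.itertuples(index=False):
        gene = str(row.gene)
        assignments[gene] = SpeciesLocus(str(row.species), str(row.locus))
        samples[gene] = str(row.sample) if "sample" in df.columns and not _isna(row.sample) else None
    return LeafMap(assignments, samples)


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and x != x)


def parse_leafmap_from_names(tree: GeneTree, delimiter: str = "|") -> LeafMap:
    """Derive a leaf map from leaf names of the form ``species<d>locus[<d>sample]``."""
    assignments = {}
    samples: dict[str, Optional[str]] = {}
    for name in sorted(tree.leaf_names):
        fields = name.split(delimiter)
        if len(fields) < 2:
            raise ValueError(
                f"leaf {name!r} does not split into species{delimiter}locus fields"
            )
        assignments[name] = SpeciesLocus(fields[0], fields[1])
        samples[name] = fields[2] if len(fields) > 2 else None
    return LeafMap(assignments, samples)
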