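"""Rooted phylogenetic tree with genome-bearing leaves.

The tree is the inference scaffold: every edge (parent -> child) is a
unit on which rearrangement events are reported, in ancestor ->
descendant direction.  Removing an edge bipartitions the leaves; the
candidate-adjacency construction works on those bipartitions, so edge
ids, leaf orderings and all listings are deterministic for a fixed
newick string.

Trees derived from unrooted analyses are conventionally represented
with a trifurcating root (the unrooted tree rooted at an internal
node), which keeps every edge's leaf bipartition distinct.  Branch
lengths in the input are ignored; internal node labels are honored when
present and otherwise assigned deterministically in pre-order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy

from .genome import Genome


@dataclass(frozen=True)
class Edge:
    """A parent -> child edge with a stable pre-order id."""

    id: int
    parent: int
    child: int


@dataclass(frozen=True)
class EdgePartition:
    """Leaf bipartition induced by removing one edge."""

    edge_id: int
    side_a: frozenset[str]  # leaves on the parent (ancestor) side
    side_b: frozenset[str]  # leaves below the child


class PhyloTree:
    """Rooted tree over named leaves, with optional genome bindings.

    Nodes are integer ids assigned in pre-order (root = 0); edges are
    numbered in pre-order as well, so identical newick input always
    yields identical ids.
    """

    def __init__(
        self,
        children: dict[int, list[int]],
        labels: dict[int, str],
        leaf_nodes: list[int],
    ) -> None:
        self.children = children
        self.labels = labels
        self.leaf_nodes = list(leaf_nodes)
        self.root = 0
        self.parent: dict[int, int] = {}
        self.edges: list[Edge] = []
        self._edge_by_id: dict[int, Edge] = {}
        self._assign_edges()
        self.leaves: list[str] = [labels[n] for n in self.leaf_nodes]
        if len(self.leaves) < 2:
            raise ValueError("tree must have at least 2 leaves")
        if len(set(self.leaves)) != len(self.leaves):
            raise ValueError("duplicate leaf names")
        self._leaf_bit = {name: 1 << i for i, name in enumerate(self.leaves)}
        self.full_mask = (1 << len(self.leaves)) - 1
        self._below_mask: dict[int, int] = {}
        self._fill_below(self.root)
        self.genomes: dict[str, Genome] = {}

    # -- construction --------------------------------------------------

    def _assign_edges(self) -> None:
        eid = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child in self.children.get(node, []):
                self.parent[child] = node
                edge = Edge(eid, node, child)
                self.edges.append(edge)
                self._edge_by_id[eid] = edge
                eid += 1
            # push in reverse so pre-order follows newick child order
            for child in reversed(self.children.get(node, [])):
                stack.append(child)

    def _fill_below(self, node: int) -> int:
        kids = self.children.get(node, [])
        if not kids:
            mask = self._leaf_bit[self.labels[node]]
        else:
            mask = 0
            for c in kids:
                mask |= self._fill_below(c)
        self._below_mask[node] = mask
        return mask

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"malformed newick: {exc}") from exc
        children: dict[int, list[int]] = {}
        labels: dict[int, str] = {}
        leaf_nodes: list[int] = []
        counter = 0
        auto = 0

        def walk(dnode, my_id: int) -> None:
            nonlocal counter, auto
            kids = dnode.child_nodes()
            if not kids:
                if dnode.taxon is None or not dnode.taxon.label:
                    raise ValueError("leaf without a name")
                labels[my_id] = dnode.taxon.label
                leaf_nodes.append(my_id)
                return
            if dnode.label:
                labels[my_id] = dnode.label
            else:
                auto += 1
                labels[my_id] = f"_anc{auto}"
            children[my_id] = []
            for k in kids:
                counter += 1
                kid_id = counter
                children[my_id].append(kid_id)
                walk(k, kid_id)

        root = dtree.seed_node
        # collapse a unary root produced by newick like "((A,B)X);"
        while len(root.child_nodes()) == 1:
            root = root.child_nodes()[0]
        walk(root, 0)
        return cls(children, labels, leaf_nodes)

    # -- queries -------------------------------------------------------

    def edge(self, edge_id: int) -> Edge:
        try:
            return self._edge_by_id[edge_id]
        except KeyError:
            raise KeyError(f"unknown edge id {edge_id}") from None

    def is_leaf(self, node: int) -> bool:
        return node not in self.children or not self.children[node]

    def label(self, node: int) -> str:
        return self.labels[node]

    def leaf_mask(self, names: Iterable[str]) -> int:
        mask = 0
        for n in names:
            mask |= self._leaf_bit[n]
        return mask

    def mask_names(self, mask: int) -> frozenset[str]:
        return frozenset(n for n in self.leaves if mask & self._leaf_bit[n])

    def side_mask(self, edge_id: int, endpoint: int) -> int:
        """Bitmask of the leaves on ``endpoint``'s side of the edge."""
        edge = self.edge(edge_id)
        below = self._below_mask[edge.child]
        if endpoint == edge.child:
            return below
        if endpoint == edge.parent:
            return self.full_mask ^ below
        raise ValueError(f"node {endpoint} is not an endpoint of edge {edge_id}")

    def edge_partition(self, edge_id: int) -> EdgePartition:
        edge = self.edge(edge_id)
        below = self._below_mask[edge.child]
        return EdgePartition(
            edge_id,
            side_a=self.mask_names(self.full_mask ^ below),
            side_b=self.mask_names(below),
        )

    def incident_edges(self, node: int) -> list[tuple[int, int]]:
        """(edge_id, far endpoint) for every edge touching ``node``,
        ordered by edge id."""
        out: list[tuple[int, int]] = []
        if node in self.parent:
            parent = self.parent[node]
            for e in self.edges:
                if e.parent == parent and e.child == node:
                    out.append((e.id, parent))
                    break
        for e in self.edges:
            if e.parent == node:
                out.append((e.id, e.child))
        return sorted(out)

    def incident_edges_excluding(self, node: int, edge_id: int) -> list[tuple[int, int]]:
        edge = self.edge(edge_id)
        if node not in (edge.parent, edge.child):
            raise ValueError(f"node {node} is not an endpoint of edge {edge_id}")
        return [(eid, far) for eid, far in self.incident_edges(node) if eid != edge_id]

    # -- genome binding ------------------------------------------------

    def bind_genomes(self, genomes: Iterable[Genome]) -> None:
        by_name = {g.name: g for g in genomes}
        missing = [n for n in self.leaves if n not in by_name]
        if missing:
            raise ValueError(f"no genome for leaves: {', '.join(missing)}")
        self.genomes = {n: by_name[n] for n in self.leaves}

    def leaf_genomes(self, mask: int) -> list[Genome]:
        if not self.genomes:
            raise ValueError("tree has no bound genomes")
        return [self.genomes[n] for n in self.leaves if mask & self._leaf_bit[n]]


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def caterpillar_newick(n_leaves: int, prefix: str = "L") -> str:
    """Ladder topology with a trifurcating root, the shape used by the
    simulation protocols: the root carries two leaves and a chain in
    which every internal node carries one leaf, the last one two.

    Yields 2n-3 edges for n leaves, matching the branch count of an
    unrooted binary tree.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    names = [f"{prefix}{i}" for i in range(1, n_leaves + 1)]
    if n_leaves == 2:
        return f"({names[0]},{names[1]});"
    if n_leaves == 3:
        return f"({names[0]},{names[1]},{names[2]});"
    sub = f"({names[-2]},{names[-1]})"
    for name in reversed(names[2:-2]):
        sub = f"({name},{sub})"
    return f"({names[0]},{names[1]},{sub});"
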