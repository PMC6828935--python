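"""Candidate adjacency sets Ca(e, N) per edge and endpoint.

For an edge e whose removal splits the leaves into the side of endpoint
N and the far side, Ca(e, N) collects the adjacencies that the method
attributes to the genome at N: evidence for what was present on N's
side of the edge and absent beyond it.  Admission happens in stages:

* step a: adjacencies present in every genome on N's side and in no
  genome on the far side;
* step b (N internal): adjacencies present in at least one genome of
  each subtree hanging off N (other than via e) and in no far-side
  genome — survives partial erosion by later events;
* step c (recursive): an adjacency a1 from a sub-edge's candidate set
  Ca(ei, ui) is promoted when it is block-disjoint from the sub-edge's
  near-side candidates and every other subtree contains a linked
  witness (an adjacency sharing a block with a1, itself linked to that
  sub-edge's near-side candidates) — the trace a displaced adjacency
  leaves across subtrees;
* RGRPT extension: a1 is promoted whenever every other subtree's deep
  candidate set merely contains some adjacency sharing a block with it
  (the step-c blocking conditions are waived).

EMRAE mode works on uncapped adjacencies; RGRPT mode caps every
chromosome with the telomere sentinel 0 first, which is what lets
events at chromosome ends ("frontier" events) leave admissible
evidence, and additionally applies the extension rule.

Two adjacencies "overlap" when they share a block by absolute label;
telomere caps never count.  Admitted adjacencies carry a provenance tag
(first-admitting stage wins, in order a, b, c, ext).  All stages
post-assert the side condition: a candidate for Ca(e, N) occurs in at
least one genome on N's side and in none on the far side.

The step-c recursion descends strictly away from the edge being
computed (deep sets are fully recursive; the near-side sets it checks
against are the direct step-a/b sets), which keeps the recursion
well-founded; results are memoized per (edge, endpoint, mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .genome import Adjacency, adjacencies, blocks_overlap
from .tree import PhyloTree

Mode = Literal["emrae", "rgrpt"]
MODES = ("emrae", "rgrpt")


@dataclass(frozen=True)
class CandidateSet:
    edge_id: int
    node: int
    adjacencies: frozenset[Adjacency]
    provenance: dict[Adjacency, str]

    def sorted(self) -> list[Adjacency]:
        return sorted(self.adjacencies)


def _overlaps_any(a: Adjacency, coll: Iterable[Adjacency]) -> bool:
    return any(blocks_overlap(a, b) for b in coll)


class CandidateComputer:
    """Computes and memoizes Ca(e, N) for one tree and mode."""

    def __init__(self, tree: PhyloTree, mode: Mode) -> None:
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        if not tree.genomes:
            raise ValueError("tree has no bound genomes")
        self.tree = tree
        self.mode = mode
        capped = mode == "rgrpt"
        self._adj_mask: dict[Adjacency, int] = {}
        for i, name in enumerate(tree.leaves):
            for a in adjacencies(tree.genomes[name], capped=capped):
                self._adj_mask[a] = self._adj_mask.get(a, 0) | (1 << i)
        self._universe = sorted(self._adj_mask)
        self._memo: dict[tuple[int, int], CandidateSet] = {}
        self._ab_memo: dict[tuple[int, int], dict[Adjacency, str]] = {}

    # -- admission stages ---------------------------------------------

    def _step_ab(self, edge_id: int, node: int) -> dict[Adjacency, str]:
        """Steps a and b for one (edge, endpoint); adjacency -> stage."""
        key = (edge_id, node)
        if key in self._ab_memo:
            return self._ab_memo[key]
        side = self.tree.side_mask(edge_id, node)
        far = self.tree.full_mask ^ side
        subs = self.tree.incident_edges_excluding(node, edge_id)
        sub_sides = [
            self.tree.side_mask(eid, far_node) for eid, far_node in subs
        ]
        out: dict[Adjacency, str] = {}
        for a in self._universe:
            m = self._adj_mask[a]
            if m & far:
                continue
            if (side & ~m) == 0:
                out[a] = "a"
            elif sub_sides and all(m & s for s in sub_sides):
                out[a] = "b"
        self._ab_memo[key] = out
        return out

    def step_a(self, edge_id: int, node: int) -> frozenset[Adjacency]:
        return frozenset(
            a for a, s in self._step_ab(edge_id, node).items() if s == "a"
        )

    def step_b(self, edge_id: int, node: int) -> frozenset[Adjacency]:
        return frozenset(
            a for a, s in self._step_ab(edge_id, node).items() if s == "b"
        )

    def candidates(self, edge_id: int, node: int) -> CandidateSet:
        key = (edge_id, node)
        if key in self._memo:
            return self._memo[key]
        side = self.tree.side_mask(edge_id, node)
        far = self.tree.full_mask ^ side
        prov = dict(self._step_ab(edge_id, node))
        subs = self.tree.incident_edges_excluding(node, edge_id)
        if subs:
            deep = [self.candidates(eid, far_node).adjacencies for eid, far_node in subs]
            near = [self._step_ab(eid, node) for eid, _ in subs]
            for i, di in enumerate(deep):
                for a1 in sorted(di):
                    if a1 in prov:
                        continue
                    if not self._side_ok(a1, side, far):
                        continue
                    if not _overlaps_any(a1, near[i]):
                        if all(
                            any(
                                blocks_overlap(a1, a2) and _overlaps_any(a2, near[j])
                                for a2 in deep[j]
                            )
                            for j in range(len(deep))
                            if j != i
                        ):
                            prov[a1] = "c"
                            continue
                    if self.mode == "rgrpt" and all(
                        _overlaps_any(a1, deep[j])
                        for j in range(len(deep))
                        if j != i
                    ):
                        prov[a1] = "ext"
        cs = CandidateSet(edge_id, node, frozenset(prov), prov)
        self._memo[key] = cs
        return cs

    def _side_ok(self, a: Adjacency, side: int, far: int) -> bool:
        m = self._adj_mask.get(a, 0)
        return bool(m & side) and not (m & far)

    # -- reporting -----------------------------------------------------

    def all_candidates(self) -> list[CandidateSet]:
        out = []
        for edge in self.tree.edges:
            out.append(self.candidates(edge.id, edge.parent))
            out.append(self.candidates(edge.id, edge.child))
        return out

    def dump_tsv(self) -> str:
        """Debug dump: edge_id, endpoint label, adjacency, admitting step."""
        lines = ["edge_id\tnode\tadjacency\tstep"]
        for cs in self.all_candidates():
            label = self.tree.label(cs.node)
            for a in cs.sorted():
                lines.append(f"{cs.edge_id}\t{label}\t{a[0]},{a[1]}\t{cs.provenance[a]}")
        return "\n".join(lines) + "\n"
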