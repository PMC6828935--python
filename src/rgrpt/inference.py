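"""Edge-wise inference of rearrangement events from candidate sets.

For an edge e = (A, B) with A the ancestor-side endpoint, destroyed
adjacencies are sought in Ca(e, A) and created ones in Ca(e, B), so
every emitted event reads ancestor -> descendant.  Writing an adjacency
between blocks u and v as a(u, v), the rule families are:

* reversal/translocation: a1 = a(p, x), a2 = a(y, q) on the A side and
  b1 = a(p, -y), b2 = a(-x, q) on the B side are exactly the adjacency
  changes of reversing the segment x..y (p, q may be telomere caps).
  The same quadruple shape also covers both translocation forms, read
  with one adjacency in its flipped orientation, so the event type is
  decided by context: a reversal when all genomes are uni-chromosomal,
  or when some genome on each side carries the four blocks of its
  witness pair on a single chromosome; otherwise a translocation.
* transposition: a1 = a(p, x), a2 = a(y, q), a3 = a(z, w) against
  b1 = a(p, q), b2 = a(z, x), b3 = a(y, w) — the fragment x..y excised
  and reinserted after z.  On multichromosomal data the call requires,
  with m the number of A-side genomes carrying both a1 and a2, at least
  m/2 genomes placing the blocks of a1 and a2 (or of a2 and a3) on one
  chromosome.
* fission: a single surviving adjacency a = a(u, v) on the A side is
  called a fission when every B-side genome could have arisen from the
  split — concretely, every B-side genome carries the capped
  adjacencies a(u, 0) and a(0, v), i.e. u ends a chromosome and v
  begins one, signs respected up to whole-chromosome flips.  A fusion
  is the same pattern read from the B side.

Witnesses are consumed greedily: each candidate adjacency backs at most
one event per edge, and rule families run in fixed order (reversal/
translocation, then transposition, then fission/fusion) with quadruples
and sextuples enumerated in canonical sort order, so output is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .candidates import CandidateComputer, CandidateSet, Mode
from .genome import (
    Adjacency,
    Event,
    Genome,
    adjacencies,
    adjacency_blocks,
    adjacency_orientations,
    canonical_adjacency,
)
from .tree import Edge, PhyloTree


@dataclass(frozen=True)
class Prediction:
    """An inferred event with its method tag and witnessing adjacencies."""

    event: Event
    method: str
    witnesses_a: frozenset[Adjacency]
    witnesses_b: frozenset[Adjacency]


class _EdgeContext:
    """Per-tree context shared by the rule families."""

    def __init__(self, tree: PhyloTree) -> None:
        self.tree = tree
        self.all_unichromosomal = all(
            len(g.chromosomes) == 1 for g in tree.genomes.values()
        )
        self.capped_adjs = {
            name: adjacencies(g, capped=True) for name, g in tree.genomes.items()
        }
        self.block_chrom = {
            name: g.block_chromosome() for name, g in tree.genomes.items()
        }
        # forward oriented (capped) adjacency pairs per genome, with the
        # chromosome each pair sits on -- the reading-frame evidence
        self.oriented_pairs: dict[str, dict[tuple[int, int], int]] = {}
        for name, g in tree.genomes.items():
            pairs: dict[tuple[int, int], int] = {}
            for ci, chrom in enumerate(g.chromosomes):
                seq = (0,) + chrom + (0,)
                for u, v in zip(seq, seq[1:]):
                    pairs[(u, v)] = ci
            self.oriented_pairs[name] = pairs

    def co_chromosomal(self, name: str, blocks: frozenset[int]) -> bool:
        """All given blocks on a single chromosome of genome ``name``."""
        chrom = self.block_chrom[name]
        ids = {chrom[b] for b in blocks if b in chrom}
        return len(ids) == 1 and all(b in chrom for b in blocks)

    def frame_consistent(self, name: str, readings: list[tuple[int, int]]) -> bool:
        """Check that the oriented readings are jointly realizable in
        genome ``name``: each chromosome may be traversed in one
        direction only, so two readings on one chromosome must not
        demand opposite traversals.  Readings whose adjacency the genome
        does not carry impose no constraint."""
        pairs = self.oriented_pairs[name]
        demand: dict[int, bool] = {}  # chromosome -> forward?
        for u, v in readings:
            if (u, v) in pairs:
                ci, fwd = pairs[(u, v)], True
            elif (-v, -u) in pairs:
                ci, fwd = pairs[(-v, -u)], False
            else:
                continue
            if demand.setdefault(ci, fwd) != fwd:
                return False
        return True


class _Pools:
    """Greedy consumption pools for one edge."""

    def __init__(self, ca_a: CandidateSet, ca_b: CandidateSet) -> None:
        self.a: set[Adjacency] = set(ca_a.adjacencies)
        self.b: set[Adjacency] = set(ca_b.adjacencies)

    def oriented(self, side: str) -> list[tuple[Adjacency, int, int]]:
        pool = self.a if side == "a" else self.b
        out = []
        for adj in sorted(pool):
            for u, v in adjacency_orientations(adj):
                out.append((adj, u, v))
        return out

    def by_first(self, side: str) -> dict[int, list[tuple[Adjacency, int]]]:
        idx: dict[int, list[tuple[Adjacency, int]]] = {}
        for adj, u, v in self.oriented(side):
            idx.setdefault(u, []).append((adj, v))
        return idx

    def by_second(self, side: str) -> dict[int, list[tuple[Adjacency, int]]]:
        idx: dict[int, list[tuple[Adjacency, int]]] = {}
        for adj, u, v in self.oriented(side):
            idx.setdefault(v, []).append((adj, u))
        return idx

    def consume(self, wa: set[Adjacency], wb: set[Adjacency]) -> None:
        self.a -= wa
        self.b -= wb


def _cap_pair(a: Adjacency) -> frozenset[Adjacency]:
    """The two capped adjacencies a split of ``a`` would create
    (orientation-invariant)."""
    return frozenset(
        {canonical_adjacency(a[0], 0), canonical_adjacency(0, a[1])}
    )


def infer_reversal_or_translocation(
    pools: _Pools,
    ctx: _EdgeContext,
    side_a: frozenset[str],
    side_b: frozenset[str],
    method: str,
    edge_id: int,
) -> list[Prediction]:
    preds: list[Prediction] = []
    while True:
        match = _find_quadruple(pools, ctx, side_a, side_b)
        if match is None:
            return preds
        a1, a2, b1, b2, p, x, y, q, etype = match
        wa, wb = {a1, a2}, {b1, b2}
        ev = Event(
            etype,
            destroyed=frozenset(wa),
            created=frozenset(wb),
            params=(p, x, y, q),
            edge_id=edge_id,
        )
        preds.append(Prediction(ev, method, frozenset(wa), frozenset(wb)))
        pools.consume(wa, wb)


def _find_quadruple(
    pools: _Pools, ctx: _EdgeContext, side_a: frozenset[str], side_b: frozenset[str]
):
    b_first = pools.by_first("b")
    a_first = pools.by_first("a")
    for a1, p, x in pools.oriented("a"):
        if x == 0:
            continue
        for b1, neg_y in sorted(b_first.get(p, [])):
            y = -neg_y
            if y == 0 or b1 == a1:
                continue
            for a2, q in sorted(a_first.get(y, [])):
                if a2 == a1:
                    continue
                b2 = canonical_adjacency(-x, q)
                if b2 == b1 or b2 not in pools.b:
                    continue
                etype = _reversal_or_translocation_type(
                    ctx, side_a, side_b, a1, a2, b1, b2
                )
                if etype is None:
                    continue
                return a1, a2, b1, b2, p, x, y, q, etype
    return None


def _reversal_or_translocation_type(
    ctx: _EdgeContext,
    side_a: frozenset[str],
    side_b: frozenset[str],
    a1: Adjacency,
    a2: Adjacency,
    b1: Adjacency,
    b2: Adjacency,
) -> Optional[str]:
    if ctx.all_unichromosomal:
        return "reversal"
    blocks_a = adjacency_blocks(a1) | adjacency_blocks(a2)
    blocks_b = adjacency_blocks(b1) | adjacency_blocks(b2)
    same_a = any(ctx.co_chromosomal(n, blocks_a) for n in sorted(side_a))
    same_b = any(ctx.co_chromosomal(n, blocks_b) for n in sorted(side_b))
    if same_a and same_b:
        return "reversal"
    # translocation splits are interior by definition: a quadruple that
    # touches a telomere cap can only describe a frontier reversal, and
    # without one-chromosome support it matches no single operation
    if any(0 in adj for adj in (a1, a2, b1, b2)):
        return None
    return "translocation"


def infer_transposition(
    pools: _Pools,
    ctx: _EdgeContext,
    side_a: frozenset[str],
    side_b: frozenset[str],
    method: str,
    edge_id: int,
) -> list[Prediction]:
    preds: list[Prediction] = []
    while True:
        match = _find_sextuple(pools, ctx, side_a, side_b)
        if match is None:
            return preds
        a1, a2, a3, b1, b2, b3, params = match
        wa, wb = {a1, a2, a3}, {b1, b2, b3}
        ev = Event(
            "transposition",
            destroyed=frozenset(wa),
            created=frozenset(wb),
            params=params,
            edge_id=edge_id,
        )
        preds.append(Prediction(ev, method, frozenset(wa), frozenset(wb)))
        pools.consume(wa, wb)


def _find_sextuple(
    pools: _Pools, ctx: _EdgeContext, side_a: frozenset[str], side_b: frozenset[str]
):
    b_first = pools.by_first("b")
    a_second = pools.by_second("a")
    for a1, p, x in pools.oriented("a"):
        if x == 0:
            continue
        for b1, q in sorted(b_first.get(p, [])):
            if p == 0 and q == 0:
                continue
            for a2, y in sorted(a_second.get(q, [])):
                if y == 0 or a2 == a1:
                    continue
                for b3, w in sorted(b_first.get(y, [])):
                    if b3 == b1:
                        continue
                    for a3, z in sorted(a_second.get(w, [])):
                        if a3 in (a1, a2):
                            continue
                        b2 = canonical_adjacency(z, x)
                        if b2 in (b1, b3) or b2 not in pools.b:
                            continue
                        # a transposition preserves fragment orientation:
                        # the six readings must be realizable in a single
                        # reading frame on each side
                        if not all(
                            ctx.frame_consistent(n, [(p, x), (y, q), (z, w)])
                            for n in sorted(side_a)
                        ):
                            continue
                        if not all(
                            ctx.frame_consistent(n, [(p, q), (z, x), (y, w)])
                            for n in sorted(side_b)
                        ):
                            continue
                        if not _transposition_supported(
                            ctx, side_a, a1, a2, a3
                        ):
                            continue
                        return a1, a2, a3, b1, b2, b3, (p, x, y, q, z, w)
    return None


def _transposition_supported(
    ctx: _EdgeContext,
    side_a: frozenset[str],
    a1: Adjacency,
    a2: Adjacency,
    a3: Adjacency,
) -> bool:
    if ctx.all_unichromosomal:
        return True
    names = sorted(side_a)
    m = sum(
        1
        for n in names
        if a1 in ctx.capped_adjs[n] and a2 in ctx.capped_adjs[n]
    )
    blocks12 = adjacency_blocks(a1) | adjacency_blocks(a2)
    blocks23 = adjacency_blocks(a2) | adjacency_blocks(a3)
    c12 = sum(1 for n in names if ctx.co_chromosomal(n, blocks12))
    c23 = sum(1 for n in names if ctx.co_chromosomal(n, blocks23))
    return 2 * c12 >= m or 2 * c23 >= m


def _sign_compatible(a: Adjacency, genomes: list[Genome], ctx: _EdgeContext) -> bool:
    """True when every genome could descend from splitting ``a``: each
    carries a(u, 0) and a(0, v), i.e. the left block ends a chromosome
    and the right block begins one (up to whole-chromosome flips)."""
    caps = _cap_pair(a)
    return all(caps <= ctx.capped_adjs[g.name] for g in genomes)


def infer_fission_fusion(
    pools: _Pools,
    ctx: _EdgeContext,
    side_a: frozenset[str],
    side_b: frozenset[str],
    method: str,
    edge_id: int,
) -> list[Prediction]:
    preds: list[Prediction] = []
    genomes_a = [ctx.tree.genomes[n] for n in sorted(side_a)]
    genomes_b = [ctx.tree.genomes[n] for n in sorted(side_b)]
    for a in sorted(pools.a):
        if 0 in a:
            continue
        if _sign_compatible(a, genomes_b, ctx):
            caps = _cap_pair(a)
            ev = Event(
                "fission",
                destroyed=frozenset({a}),
                created=caps,
                params=a,
                edge_id=edge_id,
            )
            preds.append(Prediction(ev, method, frozenset({a}), caps & pools.b))
            pools.consume({a}, set(caps))
    for a in sorted(pools.b):
        if 0 in a:
            continue
        if _sign_compatible(a, genomes_a, ctx):
            caps = _cap_pair(a)
            ev = Event(
                "fusion",
                destroyed=caps,
                created=frozenset({a}),
                params=a,
                edge_id=edge_id,
            )
            preds.append(Prediction(ev, method, caps & pools.a, frozenset({a})))
            pools.consume(set(caps), {a})
    return preds


def infer_edge(
    tree: PhyloTree,
    edge: Edge,
    mode: Mode,
    computer: Optional[CandidateComputer] = None,
    ctx: Optional[_EdgeContext] = None,
) -> list[Prediction]:
    """All predictions for one edge, ancestor -> descendant."""
    if computer is None:
        computer = CandidateComputer(tree, mode)
    if ctx is None:
        ctx = _EdgeContext(tree)
    ca_a = computer.candidates(edge.id, edge.parent)
    ca_b = computer.candidates(edge.id, edge.child)
    part = tree.edge_partition(edge.id)
    pools = _Pools(ca_a, ca_b)
    preds: list[Prediction] = []
    preds += infer_reversal_or_translocation(
        pools, ctx, part.side_a, part.side_b, mode, edge.id
    )
    preds += infer_transposition(pools, ctx, part.side_a, part.side_b, mode, edge.id)
    preds += infer_fission_fusion(
        pools, ctx, part.side_a, part.side_b, mode, edge.id
    )
    return preds


def infer_all(tree: PhyloTree, mode: Mode) -> dict[int, list[Prediction]]:
    """Predictions for every edge of the tree, keyed by edge id."""
    computer = CandidateComputer(tree, mode)
    ctx = _EdgeContext(tree)
    return {
        edge.id: infer_edge(tree, edge, mode, computer, ctx)
        for edge in tree.edges
    }


def predictions_tsv(tree: PhyloTree, preds: dict[int, list[Prediction]]) -> str:
    """Predictions as TSV: edge, endpoints, type, params, adjacency sets."""

    def fmt(adjs: frozenset[Adjacency]) -> str:
        return ";".join(f"{u},{v}" for u, v in sorted(adjs)) or "-"

    lines = ["edge_id\tancestor\tdescendant\ttype\tparams\tdestroyed\tcreated\tmethod"]
    for edge in tree.edges:
        for pr in preds.get(edge.id, []):
            ev = pr.event
            lines.append(
                "\t".join(
                    [
                        str(edge.id),
                        tree.label(edge.parent),
                        tree.label(edge.child),
                        ev.etype,
                        ",".join(str(v) for v in ev.params),
                        fmt(ev.destroyed),
                        fmt(ev.created),
                        pr.method,
                    ]
                )
            )
    return "\n".join(lines) + "\n"
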