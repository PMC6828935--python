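"""Forward simulation of rearrangement evolution along a tree.

An ancestor genome placed at the root evolves edge by edge in
pre-order: on each edge a number of events k is drawn uniformly from a
configured range and k events are sampled and applied sequentially.
Leaves receive the final genomes; every applied event is logged per
edge with its full adjacency signature, so replaying the log from the
ancestor reproduces the leaf genomes exactly.

Two study protocols are provided:

* ``protocol_reversal_only`` — uni-chromosomal ancestors of m = 50, 60,
  ..., 150 blocks (11 datasets per leaf count), leaf counts 3..10 on a
  caterpillar topology, k ~ Uniform{3..10} reversals per edge.
  Single-block reversals are rare in real data, so a reversal spans one
  block with probability 1/4 and otherwise a uniformly chosen longer
  segment (a 1:3 one-gene to multi-gene ratio in expectation).
* ``protocol_all_events`` — a 5-chromosome x 100-block ancestor on a
  4-leaf caterpillar, k ~ Uniform{1..mu} per edge for mu in {6, 12, 18,
  24}, 10 replicates per mu, event types drawn in the ratio
  reversal : translocation : transposition : fusion/fission =
  10 : 2 : 2 : 0.1 (the fusion/fission weight split evenly between the
  two).

Event types that are structurally impossible for the current genome
(e.g. a translocation on a single chromosome) are excluded from the
draw and the weights renormalized.  All randomness flows from a single
integer seed; a fixed seed reproduces datasets and truth logs exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .genome import (
    Event,
    Genome,
    apply_event_params,
    apply_fission,
    apply_fusion,
    apply_reversal,
    apply_translocation,
    apply_transposition,
)
from .tree import PhyloTree, caterpillar_newick, parse_newick

DEFAULT_MIX = {
    "reversal": 10.0,
    "translocation": 2.0,
    "transposition": 2.0,
    "fusion": 0.05,
    "fission": 0.05,
}

ONE_GENE_REVERSAL_P = 0.25  # one-gene : multi-gene reversals = 1:3


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset."""

    n_leaves: int
    n_chromosomes: int
    blocks_per_chromosome: int
    k_min: int
    k_max: int
    mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    one_gene_reversal_p: float = ONE_GENE_REVERSAL_P
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 0 or self.k_max < self.k_min:
            raise ValueError("invalid events-per-edge range")
        if not any(w > 0 for w in self.mix.values()):
            raise ValueError("event mix must have a positive weight")
        if any(w < 0 for w in self.mix.values()):
            raise ValueError("event mix weights must be non-negative")


@dataclass
class TruthLog:
    """Ordered per-edge record of the events actually applied."""

    events: dict[int, list[Event]]

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.events.values())

    def all_events(self) -> list[Event]:
        return [ev for eid in sorted(self.events) for ev in self.events[eid]]


@dataclass
class SimDataset:
    """One simulated dataset: tree with bound leaf genomes + truth."""

    tree: PhyloTree
    ancestor: Genome
    truth: TruthLog
    config: SimConfig


def make_ancestor(
    n_chromosomes: int, blocks_per_chromosome: int, name: str = "ancestor"
) -> Genome:
    """Identity genome: chromosome c carries consecutive labels."""
    chroms = []
    nxt = 1
    for _ in range(n_chromosomes):
        chroms.append(tuple(range(nxt, nxt + blocks_per_chromosome)))
        nxt += blocks_per_chromosome
    return Genome(name, tuple(chroms))


# ----------------------------------------------------------------------
# Event sampling
# ----------------------------------------------------------------------


def _feasible_types(g: Genome, mix: dict) -> list[tuple[str, float]]:
    multi = len(g.chromosomes) >= 2
    splittable = any(len(c) >= 2 for c in g.chromosomes)
    two_long = sum(1 for c in g.chromosomes if len(c) >= 2) >= 2
    feasible = []
    for etype, w in sorted(mix.items()):
        if w <= 0:
            continue
        if etype == "reversal" and splittable:
            feasible.append((etype, w))
        elif etype == "translocation" and multi and two_long:
            feasible.append((etype, w))
        elif etype == "transposition" and g.n_blocks >= 2:
            feasible.append((etype, w))
        elif etype == "fusion" and multi:
            feasible.append((etype, w))
        elif etype == "fission" and splittable:
            feasible.append((etype, w))
    return feasible


def sample_event(
    g: Genome,
    rng: random.Random,
    mix: Optional[dict] = None,
    one_gene_p: float = ONE_GENE_REVERSAL_P,
) -> tuple[Genome, Event]:
    """Draw one feasible event (type ~ mix, placement uniform) and apply it."""
    mix = mix if mix is not None else DEFAULT_MIX
    feasible = _feasible_types(g, mix)
    if not feasible:
        raise ValueError("no event type is feasible for this genome")
    types, weights = zip(*feasible)
    etype = rng.choices(types, weights=weights)[0]
    if etype == "reversal":
        return _sample_reversal(g, rng, one_gene_p)
    if etype == "translocation":
        return _sample_translocation(g, rng)
    if etype == "transposition":
        return _sample_transposition(g, rng)
    if etype == "fusion":
        c1, c2 = rng.sample(range(len(g.chromosomes)), 2)
        return apply_fusion(g, c1, c2, rng.choice(["same", "flip"]))
    # fission
    chrom = rng.choice([i for i, c in enumerate(g.chromosomes) if len(c) >= 2])
    pos = rng.randint(1, len(g.chromosomes[chrom]) - 1)
    return apply_fission(g, chrom, pos)


def _sample_reversal(
    g: Genome, rng: random.Random, one_gene_p: float
) -> tuple[Genome, Event]:
    chrom = rng.choice([i for i, c in enumerate(g.chromosomes) if len(c) >= 2])
    n = len(g.chromosomes[chrom])
    if rng.random() < one_gene_p:
        i = j = rng.randint(1, n)
    else:
        i, j = sorted(rng.sample(range(1, n + 1), 2))
    return apply_reversal(g, chrom, i, j)


def _sample_translocation(g: Genome, rng: random.Random) -> tuple[Genome, Event]:
    longs = [i for i, c in enumerate(g.chromosomes) if len(c) >= 2]
    cx, cy = rng.sample(longs, 2)
    i = rng.randint(2, len(g.chromosomes[cx]))
    j = rng.randint(2, len(g.chromosomes[cy]))
    mode = rng.choice(["prefix-prefix", "prefix-suffix"])
    return apply_translocation(g, cx, cy, i, j, mode)


def _sample_transposition(g: Genome, rng: random.Random) -> tuple[Genome, Event]:
    for _ in range(100):
        chrom = rng.randrange(len(g.chromosomes))
        n = len(g.chromosomes[chrom])
        i = rng.randint(1, n)
        j = rng.randint(i, n)
        targets = []
        for d, c in enumerate(g.chromosomes):
            if d == chrom:
                targets.extend(
                    (d, k) for k in range(0, n + 1) if not (i - 1 <= k <= j)
                )
            elif j - i + 1 < n:  # moving a whole chromosome is a fusion, not a tp
                targets.extend((d, k) for k in range(0, len(c) + 1))
        if targets:
            d, k = targets[rng.randrange(len(targets))]
            return apply_transposition(g, chrom, i, j, d, k)
    raise ValueError("could not place a transposition")


# ----------------------------------------------------------------------
# Evolution along a tree
# ----------------------------------------------------------------------


def evolve(
    tree: PhyloTree, ancestor: Genome, cfg: SimConfig, rng: random.Random
) -> tuple[dict[str, Genome], TruthLog]:
    """Apply k ~ Uniform{k_min..k_max} sampled events on every edge in
    pre-order; returns leaf genomes and the per-edge truth log."""
    node_genome: dict[int, Genome] = {tree.root: ancestor}
    log: dict[int, list[Event]] = {}
    for edge in tree.edges:  # pre-order
        g = node_genome[edge.parent]
        k = rng.randint(cfg.k_min, cfg.k_max)
        events = []
        for _ in range(k):
            g, ev = sample_event(g, rng, cfg.mix, cfg.one_gene_reversal_p)
            events.append(ev.on_edge(edge.id))
        log[edge.id] = events
        node_genome[edge.child] = g
    leaf_genomes = {
        tree.label(n): Genome(tree.label(n), node_genome[n].chromosomes)
        for n in tree.leaf_nodes
    }
    return leaf_genomes, TruthLog(log)


def replay(tree: PhyloTree, ancestor: Genome, truth: TruthLog) -> dict[str, Genome]:
    """Re-apply a truth log from the ancestor; used to verify log
    soundness."""
    node_genome: dict[int, Genome] = {tree.root: ancestor}
    for edge in tree.edges:
        g = node_genome[edge.parent]
        for ev in truth.events.get(edge.id, []):
            g, applied = apply_event_params(g, ev.params)
            if applied.destroyed != ev.destroyed or applied.created != ev.created:
                raise ValueError("truth log replay mismatch")
        node_genome[edge.child] = g
    return {
        tree.label(n): Genome(tree.label(n), node_genome[n].chromosomes)
        for n in tree.leaf_nodes
    }


def simulate_dataset(cfg: SimConfig, newick: Optional[str] = None) -> SimDataset:
    """Simulate one dataset on the caterpillar topology (or a custom
    newick) under ``cfg``."""
    rng = random.Random(cfg.seed)
    tree = parse_newick(newick or caterpillar_newick(cfg.n_leaves))
    ancestor = make_ancestor(cfg.n_chromosomes, cfg.blocks_per_chromosome)
    leaf_genomes, truth = evolve(tree, ancestor, cfg, rng)
    tree.bind_genomes(leaf_genomes.values())
    return SimDataset(tree, ancestor, truth, cfg)


# ----------------------------------------------------------------------
# Study protocols
# ----------------------------------------------------------------------

REVERSAL_ONLY_SIZES = tuple(range(50, 151, 10))  # 11 datasets per leaf count


def protocol_reversal_only(n_leaves: int, seed: int) -> list[SimDataset]:
    """Reversal-only protocol: 11 uni-chromosomal datasets (m = 50..150
    step 10) for one leaf count, 3-10 reversals per edge."""
    if not 3 <= n_leaves <= 10:
        raise ValueError("leaf count must be in 3..10")
    base = random.Random(seed)
    out = []
    for m in REVERSAL_ONLY_SIZES:
        cfg = SimConfig(
            n_leaves=n_leaves,
            n_chromosomes=1,
            blocks_per_chromosome=m,
            k_min=3,
            k_max=10,
            mix={"reversal": 1.0},
            seed=base.getrandbits(31),
        )
        out.append(simulate_dataset(cfg))
    return out


def protocol_all_events(mu: int, seed: int, n_replicates: int = 10) -> list[SimDataset]:
    """Mixed-event protocol: 5x100-block ancestor, 4-leaf caterpillar,
    k ~ Uniform{1..mu} events per edge, mix 10:2:2:0.1."""
    if mu < 1:
        raise ValueError("mu must be >= 1")
    base = random.Random(seed)
    out = []
    for _ in range(n_replicates):
        cfg = SimConfig(
            n_leaves=4,
            n_chromosomes=5,
            blocks_per_chromosome=100,
            k_min=1,
            k_max=mu,
            seed=base.getrandbits(31),
        )
        out.append(simulate_dataset(cfg))
    return out


def truth_tsv(tree: PhyloTree, truth: TruthLog) -> str:
    """Truth log as TSV: edge, step index, type, params, adjacency sets."""

    def fmt(adjs) -> str:
        return ";".join(f"{u},{v}" for u, v in sorted(adjs)) or "-"

    lines = ["edge_id\tstep\ttype\tparams\tdestroyed\tcreated"]
    for eid in sorted(truth.events):
        for step, ev in enumerate(truth.events[eid], 1):
            lines.append(
                "\t".join(
                    [
                        str(eid),
                        str(step),
                        ev.etype,
                        ",".join(str(v) for v in ev.params),
                        fmt(ev.destroyed),
                        fmt(ev.created),
                    ]
                )
            )
    return "\n".join(lines) + "\n"
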