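"""Genomes as signed permutations of synteny blocks, and the five
rearrangement operators.

A chromosome is an ordered sequence of signed integer block labels; a
genome is a named collection of chromosomes in which every absolute
label occurs exactly once.  A chromosome read backwards with all signs
flipped denotes the same chromosome (``X == -X``), so all set-valued
quantities derived here (adjacencies in particular) are invariant under
that identification.

An *adjacency* ``a(x, y)`` is an ordered pair of consecutive signed
labels; ``a(x, y)`` and ``a(-y, -x)`` are the same adjacency and are
stored in a single canonical form.  The label ``0`` is reserved as a
telomere cap: when adjacency sets are extracted "capped", every
chromosome additionally contributes ``a(0, c1)`` and ``a(cn, 0)`` so
that events at chromosome ends leave a detectable signature.

Every operator application returns the rewritten genome together with an
:class:`Event` recording the adjacencies it destroyed and created, in
capped canonical form.  These destroyed/created sets are the common
currency used by the candidate-set construction, the inference rules,
the simulator truth logs and the evaluation matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

Adjacency = tuple[int, int]
Chromosome = tuple[int, ...]

EVENT_TYPES = ("reversal", "translocation", "transposition", "fusion", "fission")


def canonical_adjacency(x: int, y: int) -> Adjacency:
    """Return the canonical representative of the adjacency ``a(x, y)``.

    ``a(x, y)`` and ``a(-y, -x)`` denote the same adjacency; the
    lexicographically smaller of the two orderings is stored.  At most one
    of ``x, y`` may be the telomere cap ``0``.
    """
    if x == 0 and y == 0:
        raise ValueError("invalid adjacency: both sides are telomere caps")
    alt = (-y, -x)
    return min((x, y), alt)


def adjacency_orientations(a: Adjacency) -> list[tuple[int, int]]:
    """Both oriented readings of a canonical adjacency (deduplicated)."""
    alt = (-a[1], -a[0])
    return [a] if alt == a else [a, alt]


def adjacency_blocks(a: Adjacency) -> frozenset[int]:
    """Absolute block labels of an adjacency; caps are not blocks."""
    return frozenset(abs(v) for v in a if v != 0)


def blocks_overlap(a1: Adjacency, a2: Adjacency) -> bool:
    """True iff the two adjacencies share at least one block by absolute
    label.  Telomere caps never count as shared."""
    return bool(adjacency_blocks(a1) & adjacency_blocks(a2))


def _rc(chrom: Sequence[int]) -> Chromosome:
    """Reverse complement of a chromosome (same chromosome, other reading)."""
    return tuple(-v for v in reversed(chrom))


def normalize_chromosome(chrom: Sequence[int]) -> Chromosome:
    """Pick the representative of {X, -X} with the smaller
    (|label|, sign) sequence.  Used only for comparisons; storage keeps
    the orientation the caller supplied."""
    c = tuple(chrom)
    r = _rc(c)
    key = lambda seq: tuple((abs(v), v < 0) for v in seq)
    return c if key(c) <= key(r) else r


@dataclass(frozen=True)
class Genome:
    """A named multichromosomal genome of signed synteny blocks."""

    name: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "chromosomes", tuple(tuple(c) for c in self.chromosomes)
        )
        seen: set[int] = set()
        for chrom in self.chromosomes:
            if len(chrom) == 0:
                raise ValueError(f"genome {self.name!r}: empty chromosome")
            for v in chrom:
                if v == 0:
                    raise ValueError(
                        f"genome {self.name!r}: 0 is reserved for telomere caps"
                    )
                if abs(v) in seen:
                    raise ValueError(
                        f"genome {self.name!r}: duplicated block {abs(v)}"
                    )
                seen.add(abs(v))

    # -- derived views -------------------------------------------------

    @property
    def n_blocks(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def block_set(self) -> frozenset[int]:
        return frozenset(abs(v) for c in self.chromosomes for v in c)

    def block_chromosome(self) -> dict[int, int]:
        """Map absolute block label -> index of the chromosome carrying it."""
        out: dict[int, int] = {}
        for ci, chrom in enumerate(self.chromosomes):
            for v in chrom:
                out[abs(v)] = ci
        return out

    def normalized(self) -> tuple[Chromosome, ...]:
        return tuple(sorted(normalize_chromosome(c) for c in self.chromosomes))

    def equivalent(self, other: "Genome") -> bool:
        """Equality up to chromosome order and the X == -X identification."""
        return self.normalized() == other.normalized()


def chromosome_adjacencies(chrom: Sequence[int], capped: bool = False) -> Iterator[Adjacency]:
    if capped:
        yield canonical_adjacency(0, chrom[0])
    for i in range(len(chrom) - 1):
        yield canonical_adjacency(chrom[i], chrom[i + 1])
    if capped:
        yield canonical_adjacency(chrom[-1], 0)


def adjacencies(g: Genome, capped: bool = False) -> frozenset[Adjacency]:
    """All adjacencies of a genome in canonical form.

    Uncapped, a chromosome of length n contributes its n-1 internal
    adjacencies; capped, it additionally contributes the two telomere
    adjacencies ``a(0, c1)`` and ``a(cn, 0)``.
    """
    return frozenset(
        a for chrom in g.chromosomes for a in chromosome_adjacencies(chrom, capped)
    )


def effective_adjacencies(
    genomes: Iterable[Genome], capped: bool = False
) -> frozenset[Adjacency]:
    """Adjacencies present in at least one but not all of the genomes."""
    sets = [adjacencies(g, capped) for g in genomes]
    if len(sets) < 2:
        raise ValueError("effective adjacencies need at least 2 genomes")
    union = frozenset().union(*sets)
    inter = sets[0].intersection(*sets[1:])
    return union - inter


# ----------------------------------------------------------------------
# Events and operators
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class Event:
    """A typed rearrangement with its adjacency signature.

    ``destroyed`` and ``created`` are canonical capped adjacencies:
    recomputing the capped adjacency set after the operation equals
    ``(before - destroyed) | created``.  ``params`` carries the
    operator-specific indices needed to replay the event; ``edge_id`` is
    attached once the event is placed on a tree edge.
    """

    etype: str
    destroyed: frozenset[Adjacency]
    created: frozenset[Adjacency]
    params: tuple = ()
    edge_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.etype!r}")
        if self.destroyed & self.created:
            raise ValueError("destroyed and created adjacency sets overlap")

    def on_edge(self, edge_id: int) -> "Event":
        return Event(self.etype, self.destroyed, self.created, self.params, edge_id)


def _diff_event(etype: str, before: Genome, after_chroms: list[Chromosome],
                params: tuple) -> tuple[Genome, Event]:
    after = Genome(before.name, tuple(after_chroms))
    old = adjacencies(before, capped=True)
    new = adjacencies(after, capped=True)
    ev = Event(etype, frozenset(old - new), frozenset(new - old), params)
    return after, ev


def apply_reversal(g: Genome, chrom: int, i: int, j: int) -> tuple[Genome, Event]:
    """Reverse blocks i..j (1-based, inclusive) of a chromosome, flipping
    their signs."""
    c = list(g.chromosomes[chrom])
    if not (1 <= i <= j <= len(c)):
        raise ValueError(f"reversal r({i},{j}) out of range for length {len(c)}")
    seg = [-v for v in reversed(c[i - 1 : j])]
    out = list(g.chromosomes)
    out[chrom] = tuple(c[: i - 1] + seg + c[j:])
    return _diff_event("reversal", g, out, ("r", chrom, i, j))


def apply_translocation(
    g: Genome, cx: int, cy: int, i: int, j: int, mode: str = "prefix-prefix"
) -> tuple[Genome, Event]:
    """Exchange end segments of two chromosomes.

    Splits X before position i and Y before position j (1-based), both
    splits interior so all four segments are non-empty.  prefix-prefix
    forms Y1 X2 and X1 Y2; prefix-suffix forms -Y2 X2 and X1 -Y1.
    """
    if cx == cy:
        raise ValueError("translocation needs two distinct chromosomes")
    X = g.chromosomes[cx]
    Y = g.chromosomes[cy]
    if not (2 <= i <= len(X)) or not (2 <= j <= len(Y)):
        raise ValueError(
            "translocation split would produce an empty chromosome "
            f"(tl({i},{j}) on lengths {len(X)},{len(Y)})"
        )
    X1, X2 = X[: i - 1], X[i - 1 :]
    Y1, Y2 = Y[: j - 1], Y[j - 1 :]
    if mode == "prefix-prefix":
        newX, newY = Y1 + X2, X1 + Y2
    elif mode == "prefix-suffix":
        newX, newY = _rc(Y2) + X2, X1 + _rc(Y1)
    else:
        raise ValueError(f"unknown translocation mode {mode!r}")
    out = list(g.chromosomes)
    out[cx], out[cy] = newX, newY
    return _diff_event("translocation", g, out, ("tl", cx, cy, i, j, mode))


def apply_transposition(
    g: Genome, chrom: int, i: int, j: int, dest_chrom: int, k: int
) -> tuple[Genome, Event]:
    """Excise blocks i..j of ``chrom`` and reinsert them, orientation
    preserved, immediately after position k of ``dest_chrom`` (k = 0
    inserts at the chromosome start).

    Intra-chromosomal moves require k outside [i-1, j]; k = i-1 or k = j
    would reinsert the fragment where it came from.
    """
    c = list(g.chromosomes[chrom])
    if not (1 <= i <= j <= len(c)):
        raise ValueError(f"transposition fragment ({i},{j}) out of range")
    frag = c[i - 1 : j]
    rest = c[: i - 1] + c[j:]
    out = list(g.chromosomes)
    if dest_chrom == chrom:
        if i - 1 <= k <= j:
            raise ValueError("transposition target inside the moved fragment")
        if not (0 <= k <= len(c)):
            raise ValueError("transposition target out of range")
        # position of c_k in the fragment-free chromosome
        kk = k if k < i else k - len(frag)
        out[chrom] = tuple(rest[:kk] + frag + rest[kk:])
        if not out[chrom]:
            raise ValueError("transposition may not empty a chromosome")
    else:
        d = list(g.chromosomes[dest_chrom])
        if not (0 <= k <= len(d)):
            raise ValueError("transposition target out of range")
        if not rest:
            raise ValueError("transposition may not move a whole chromosome")
        out[chrom] = tuple(rest)
        out[dest_chrom] = tuple(d[:k] + frag + d[k:])
    return _diff_event("transposition", g, out, ("tp", chrom, i, j, dest_chrom, k))


def apply_fusion(g: Genome, c1: int, c2: int, orient: str = "same") -> tuple[Genome, Event]:
    """Join two chromosomes into one: X1 X2 (same) or X1 -X2 (flip)."""
    if c1 == c2:
        raise ValueError("fusion needs two distinct chromosomes")
    X1 = g.chromosomes[c1]
    X2 = g.chromosomes[c2]
    joined = X1 + (X2 if orient == "same" else _rc(X2))
    if orient not in ("same", "flip"):
        raise ValueError(f"unknown fusion orientation {orient!r}")
    out = [c for idx, c in enumerate(g.chromosomes) if idx not in (c1, c2)]
    out.append(joined)
    return _diff_event("fusion", g, out, ("fu", c1, c2, orient))


def apply_fission(g: Genome, chrom: int, pos: int) -> tuple[Genome, Event]:
    """Split a chromosome between positions pos and pos+1 (1 <= pos < len)."""
    c = g.chromosomes[chrom]
    if not (1 <= pos < len(c)):
        raise ValueError(f"fission position {pos} not interior for length {len(c)}")
    out = [ch for idx, ch in enumerate(g.chromosomes) if idx != chrom]
    out.extend([c[:pos], c[pos:]])
    return _diff_event("fission", g, out, ("fi", chrom, pos))


def apply_event_params(g: Genome, params: tuple) -> tuple[Genome, Event]:
    """Replay an event from its recorded params (simulator truth logs)."""
    op = params[0]
    if op == "r":
        return apply_reversal(g, *params[1:])
    if op == "tl":
        return apply_translocation(g, *params[1:])
    if op == "tp":
        return apply_transposition(g, *params[1:])
    if op == "fu":
        return apply_fusion(g, *params[1:])
    if op == "fi":
        return apply_fission(g, *params[1:])
    raise ValueError(f"unknown event params {params!r}")
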