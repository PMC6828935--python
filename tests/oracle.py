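"""Brute-force oracle: enumerate every single rearrangement operation
applicable to a genome, with its adjacency signature.

Independent of the inference path: it simply applies each operator at
every legal placement and records the (type, destroyed, created)
signature, for checking emitted predictions on small instances.
"""

from __future__ import annotations

from rgrpt.genome import (
    Event,
    Genome,
    apply_fission,
    apply_fusion,
    apply_reversal,
    apply_translocation,
    apply_transposition,
)


def all_single_operations(g: Genome) -> list[Event]:
    events: list[Event] = []
    n_chrom = len(g.chromosomes)
    for ci, chrom in enumerate(g.chromosomes):
        n = len(chrom)
        for i in range(1, n + 1):
            for j in range(i, n + 1):
                events.append(apply_reversal(g, ci, i, j)[1])
        for pos in range(1, n):
            events.append(apply_fission(g, ci, pos)[1])
        # transpositions from this chromosome
        for i in range(1, n + 1):
            for j in range(i, n + 1):
                for d, dest in enumerate(g.chromosomes):
                    if d == ci:
                        for k in range(0, n + 1):
                            if i - 1 <= k <= j:
                                continue
                            events.append(
                                apply_transposition(g, ci, i, j, d, k)[1]
                            )
                    elif j - i + 1 < n:
                        for k in range(0, len(dest) + 1):
                            events.append(
                                apply_transposition(g, ci, i, j, d, k)[1]
                            )
    for c1 in range(n_chrom):
        for c2 in range(n_chrom):
            if c1 == c2:
                continue
            for orient in ("same", "flip"):
                events.append(apply_fusion(g, c1, c2, orient)[1])
            x, y = g.chromosomes[c1], g.chromosomes[c2]
            if len(x) >= 2 and len(y) >= 2 and c1 < c2:
                for i in range(2, len(x) + 1):
                    for j in range(2, len(y) + 1):
                        for mode in ("prefix-prefix", "prefix-suffix"):
                            events.append(
                                apply_translocation(g, c1, c2, i, j, mode)[1]
                            )
    return events


def signature_set(events: list[Event]) -> set[tuple]:
    return {(e.etype, e.destroyed, e.created) for e in events}
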