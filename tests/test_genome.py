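"""Core genome model: canonical adjacencies, operators, invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgrpt.genome import (
    Genome,
    adjacencies,
    apply_event_params,
    apply_fission,
    apply_fusion,
    apply_reversal,
    apply_translocation,
    apply_transposition,
    blocks_overlap,
    canonical_adjacency,
    chromosome_adjacencies,
    effective_adjacencies,
    normalize_chromosome,
)

nonzero = st.integers(min_value=-50, max_value=50).filter(lambda v: v != 0)


class TestCanonicalAdjacency:
    @pytest.mark.parametrize(
        "pair, same_as",
        [((2, 3), (-3, -2)), ((0, 1), (-1, 0)), ((1, -3), (3, -1))],
    )
    def test_reverse_complement_pairs_identify(self, pair, same_as):
        assert canonical_adjacency(*pair) == canonical_adjacency(*same_as)

    def test_double_cap_rejected(self):
        with pytest.raises(ValueError):
            canonical_adjacency(0, 0)

    @given(x=nonzero, y=nonzero)
    @settings(max_examples=100, derandomize=True)
    def test_symmetry_and_idempotence(self, x, y):
        a = canonical_adjacency(x, y)
        assert a == canonical_adjacency(-y, -x)
        assert canonical_adjacency(*a) == a

    def test_overlap_by_absolute_label_caps_excluded(self):
        a = canonical_adjacency
        assert blocks_overlap(a(1, 2), a(2, 3))
        assert blocks_overlap(a(1, 2), a(-2, 4))
        assert not blocks_overlap(a(0, 1), a(0, -2))


class TestAdjacencies:
    def test_chain_chromosome(self):
        g = Genome("X", ((1, 2, 3, 4),))
        expect = {canonical_adjacency(*p) for p in [(1, 2), (2, 3), (3, 4)]}
        assert adjacencies(g) == expect

    def test_caps_added_per_chromosome(self):
        gx = Genome("X", ((1, 2, 3, 4),))
        gy = Genome("Y", ((-2, -1, 3, 4),))
        assert canonical_adjacency(0, 1) in adjacencies(gx, capped=True)
        assert canonical_adjacency(0, -2) in adjacencies(gy, capped=True)

    def test_single_block_chromosome(self):
        g = Genome("S", ((5,),))
        assert adjacencies(g) == frozenset()
        assert adjacencies(g, capped=True) == {
            canonical_adjacency(0, 5),
            canonical_adjacency(5, 0),
        }

    def test_counts(self):
        g = Genome("G", ((1, 2, 3), (4, 5), (6,)))
        assert len(adjacencies(g)) == 3
        assert len(adjacencies(g, capped=True)) == 3 + 2 * 3

    def test_reverse_complement_invariance(self):
        g = Genome("G", ((1, -3, 2, 4),))
        rc = Genome("G", (tuple(-v for v in reversed((1, -3, 2, 4))),))
        assert adjacencies(g) == adjacencies(rc)
        assert adjacencies(g, capped=True) == adjacencies(rc, capped=True)


class TestEffectiveAdjacencies:
    def test_reversal_example(self):
        # G2 = G1 with the segment 2..3 reversed: the interior adjacency
        # a(2,3) survives as a(-3,-2) (same canonical adjacency), so the
        # effective set is the two old breakpoints + the two new ones
        g1 = Genome("G1", ((1, 2, 3, 4),))
        g2 = Genome("G2", ((1, -3, -2, 4),))
        expect = {
            canonical_adjacency(*p) for p in [(1, 2), (3, 4), (1, -3), (-2, 4)]
        }
        assert effective_adjacencies([g1, g2]) == expect

    def test_identical_genomes_have_none(self):
        g = Genome("A", ((1, 2, 3),))
        h = Genome("B", ((1, 2, 3),))
        assert effective_adjacencies([g, h]) == frozenset()

    def test_majority_presence_is_still_effective(self):
        g1 = Genome("A", ((1, 2, 3),))
        g2 = Genome("B", ((1, 2, 3),))
        g3 = Genome("C", ((2, 1, 3),))
        assert canonical_adjacency(1, 2) in effective_adjacencies([g1, g2, g3])

    def test_requires_two_genomes(self):
        with pytest.raises(ValueError):
            effective_adjacencies([Genome("A", ((1,),))])


class TestGenomeValidation:
    def test_duplicate_block_rejected(self):
        with pytest.raises(ValueError):
            Genome("bad", ((1, 2), (-2, 3)))

    def test_zero_label_rejected(self):
        with pytest.raises(ValueError):
            Genome("bad", ((1, 0, 2),))

    def test_empty_chromosome_rejected(self):
        with pytest.raises(ValueError):
            Genome("bad", ((1, 2), ()))


class TestOperators:
    def test_reversal_fig_example(self):
        g = Genome("A", ((1, 2, 3, 4),))
        out, ev = apply_reversal(g, 0, 2, 3)
        assert out.chromosomes == ((1, -3, -2, 4),)
        assert ev.destroyed == {canonical_adjacency(1, 2), canonical_adjacency(3, 4)}
        assert ev.created == {canonical_adjacency(1, -3), canonical_adjacency(-2, 4)}

    def test_one_block_reversal_flips_sign(self):
        g = Genome("A", ((1, 2, 3),))
        out, _ = apply_reversal(g, 0, 2, 2)
        assert out.chromosomes == ((1, -2, 3),)

    def test_reversal_is_involution(self):
        g = Genome("A", ((5, -1, 3, 2, -4),))
        once, _ = apply_reversal(g, 0, 2, 4)
        twice, _ = apply_reversal(once, 0, 2, 4)
        assert twice.chromosomes == g.chromosomes

    def test_reversal_out_of_range(self):
        with pytest.raises(ValueError):
            apply_reversal(Genome("A", ((1, 2),)), 0, 1, 3)

    def test_translocation_prefix_prefix(self):
        g = Genome("G", ((1, 2, 3), (4, 5, 6)))
        out, ev = apply_translocation(g, 0, 1, 2, 2, "prefix-prefix")
        assert out.chromosomes == ((4, 2, 3), (1, 5, 6))
        assert ev.destroyed == {canonical_adjacency(1, 2), canonical_adjacency(4, 5)}
        assert ev.created == {canonical_adjacency(4, 2), canonical_adjacency(1, 5)}

    def test_translocation_prefix_suffix(self):
        g = Genome("G", ((1, 2), (3, 4)))
        out, _ = apply_translocation(g, 0, 1, 2, 2, "prefix-suffix")
        assert out.chromosomes == ((-4, 2), (1, -3))

    def test_translocation_conserves_blocks(self):
        g = Genome("G", ((1, 2, 3), (4, 5, 6)))
        out, _ = apply_translocation(g, 0, 1, 3, 2, "prefix-suffix")
        assert out.block_set() == g.block_set()

    def test_translocation_empty_side_rejected(self):
        g = Genome("G", ((1, 2), (3, 4)))
        with pytest.raises(ValueError):
            apply_translocation(g, 0, 1, 1, 2, "prefix-prefix")

    def test_transposition_moves_fragment_after_target(self):
        g = Genome("G", ((1, 2, 3, 4, 5),))
        out, ev = apply_transposition(g, 0, 2, 3, 0, 5)
        assert out.chromosomes == ((1, 4, 5, 2, 3),)
        assert ev.destroyed == {
            canonical_adjacency(1, 2),
            canonical_adjacency(3, 4),
            canonical_adjacency(5, 0),
        }

    def test_transposition_inside_fragment_rejected(self):
        g = Genome("G", ((1, 2, 3, 4, 5),))
        with pytest.raises(ValueError):
            apply_transposition(g, 0, 2, 4, 0, 3)

    def test_transposition_noop_placement_rejected(self):
        g = Genome("G", ((1, 2, 3, 4),))
        with pytest.raises(ValueError):
            apply_transposition(g, 0, 2, 3, 0, 1)

    def test_fusion_same_and_flip(self):
        g = Genome("G", ((1, 2), (3, 4)))
        assert apply_fusion(g, 0, 1, "same")[0].chromosomes == ((1, 2, 3, 4),)
        assert apply_fusion(g, 0, 1, "flip")[0].chromosomes == ((1, 2, -4, -3),)

    def test_fission_splits_and_records_junction(self):
        g = Genome("G", ((1, 2, 3, 4),))
        out, ev = apply_fission(g, 0, 2)
        assert set(out.chromosomes) == {(1, 2), (3, 4)}
        assert canonical_adjacency(2, 3) in ev.destroyed

    def test_fission_fusion_inverse(self):
        g = Genome("G", ((1, 2, 3, 4),))
        split, _ = apply_fission(g, 0, 2)
        back, _ = apply_fusion(split, 0, 1, "same")
        assert back.equivalent(g)

    def test_fission_boundary_rejected(self):
        with pytest.raises(ValueError):
            apply_fission(Genome("G", ((1, 2),)), 0, 2)


@st.composite
def genomes(draw, max_blocks=10, max_chroms=3):
    n = draw(st.integers(min_value=2, max_value=max_blocks))
    perm = draw(st.permutations(list(range(1, n + 1))))
    signs = draw(st.lists(st.booleans(), min_size=n, max_size=n))
    signed = [v if s else -v for v, s in zip(perm, signs)]
    k = draw(st.integers(min_value=1, max_value=min(max_chroms, n)))
    cuts = sorted(draw(st.permutations(list(range(1, n))))[: k - 1])
    chroms, prev = [], 0
    for c in cuts + [n]:
        chroms.append(tuple(signed[prev:c]))
        prev = c
    return Genome("G", tuple(chroms))


class TestOperatorProperties:
    @given(g=genomes(), data=st.data())
    @settings(max_examples=120, derandomize=True)
    def test_event_signature_matches_adjacency_diff(self, g, data):
        """For any operator application, (before - destroyed) | created
        equals the capped adjacency set afterwards, and blocks are
        conserved."""
        ops = []
        for ci, chrom in enumerate(g.chromosomes):
            if len(chrom) >= 1:
                ops.append(("rev", ci))
            if len(chrom) >= 2:
                ops.append(("fis", ci))
        if len(g.chromosomes) >= 2:
            ops.append(("fus", None))
        op, ci = data.draw(st.sampled_from(ops))
        if op == "rev":
            n = len(g.chromosomes[ci])
            i = data.draw(st.integers(1, n))
            j = data.draw(st.integers(i, n))
            after, ev = apply_reversal(g, ci, i, j)
        elif op == "fis":
            pos = data.draw(st.integers(1, len(g.chromosomes[ci]) - 1))
            after, ev = apply_fission(g, ci, pos)
        else:
            c2 = data.draw(
                st.integers(0, len(g.chromosomes) - 1).filter(lambda v: v != 0)
            )
            after, ev = apply_fusion(g, 0, c2, data.draw(st.sampled_from(["same", "flip"])))
        before_adj = adjacencies(g, capped=True)
        after_adj = adjacencies(after, capped=True)
        assert after_adj == (before_adj - ev.destroyed) | ev.created
        assert ev.destroyed == before_adj - after_adj
        assert ev.created == after_adj - before_adj
        assert after.block_set() == g.block_set()
        # events replay from their params
        replayed, rev = apply_event_params(g, ev.params)
        assert replayed.chromosomes == after.chromosomes

    @given(g=genomes())
    @settings(max_examples=60, derandomize=True)
    def test_normalize_chromosome_is_canonical(self, g):
        for chrom in g.chromosomes:
            rc = tuple(-v for v in reversed(chrom))
            assert normalize_chromosome(chrom) == normalize_chromosome(rc)
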