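# Methods

## Genome model

A genome is a set of linear chromosomes, each an ordering of signed
synteny blocks; absolute block labels are unique genome-wide, and all
genomes under comparison share the same block content (equal gene
content, no duplications or losses — see Limitations).  A chromosome is
identified with its reverse complement (`X ≡ −X`), so every derived
set-valued quantity is invariant under flipping a whole chromosome.

An adjacency `a(x, y)` is an ordered pair of consecutive signed labels;
`a(x, y)` and `a(−y, −x)` are the same object and are stored as the
lexicographically smaller of the two orderings.  The label `0` is
reserved as a telomere cap: in capped form every chromosome also
contributes `a(0, c1)` and `a(cn, 0)`, and at most one side of an
adjacency may be a cap.  An adjacency is *effective* for a genome set
if it occurs in at least one genome but not all — the raw signal of
rearrangement.  Note that interior adjacencies of a reversed segment
are preserved under the `X ≡ −X` identification (reversing `2 3` in
`1 2 3 4` keeps `a(2,3)` as `a(−3,−2)`), so only breakpoint adjacencies
become effective.

Five operators rewrite genomes: reversal `r(i, j)` (segment reversed,
signs flipped), translocation (end-segment exchange between two
chromosomes, prefix–prefix forming `Y1X2 / X1Y2` or prefix–suffix
forming `−Y2X2 / X1−Y1`; all four segments non-empty), transposition
(fragment `ci…cj` excised and reinserted after `ck`, orientation
preserved, intra- or inter-chromosomal), fusion (`X1X2` or `X1−X2`)
and fission (interior split).  Every application returns an `Event`
recording the adjacencies it destroyed and created **in capped
canonical form**, computed as the set difference of capped adjacency
sets before/after.  This makes `(before ∖ destroyed) ∪ created =
after` an enforced identity, gives fissions/fusions non-empty created
sets, and provides the single currency in which simulator truth logs
and predictions are compared.  Indices are 1-based and inclusive;
translocations with an empty exchanged segment are rejected rather than
silently treated as fusion/fission, keeping the operator types
disjoint in truth logs.

## Trees

Trees are rooted; events on an edge are reported ancestor → descendant.
Edge ids are assigned in pre-order, so identical newick input yields
identical ids and deterministic output.  Trees that represent unrooted
analyses use a trifurcating root (the unrooted tree rooted at an
internal node).  This matters for inference: with a binary root, the
two root edges induce the same leaf bipartition, and any event on one
of them would be inferred twice — once per root edge, in mirrored
orientation — an unavoidable systematic false positive.  With a
trifurcating root every edge has a distinct bipartition, and the edge
count (2n − 3 for n leaves) equals the branch count of the unrooted
phylogeny.  The simulator's caterpillar topology is built this way.

## Candidate adjacency sets

For edge `e` and endpoint `N`, `Ca(e, N)` collects adjacencies
attributable to the genome at `N`, admitted in stages (each candidate
is tagged with the first stage that admitted it):

* **a** — present in every genome on `N`'s side, absent from every
  genome on the far side.
* **b** (internal `N`) — present in ≥ 1 genome of *each* subtree
  hanging off `N` other than via `e`, absent from the far side.  The
  per-subtree quantifier is read as "at least one" (not "exactly one").
* **c** (recursive) — a candidate `a1` of a sub-edge's deep set
  `Ca(ei, ui)` is promoted when it shares no block with the sub-edge's
  near-side candidates and, for every other sub-edge `ej`, some
  `a2 ∈ Ca(ej, uj)` shares a block with `a1` and itself shares a block
  with `ej`'s near-side candidates.  "Sharing a block" means sharing an
  absolute label; caps never count.
* **extension** (rgrpt mode only) — `a1` is promoted whenever every
  other sub-edge's deep set contains some adjacency sharing a block
  with it; the step-c blocking conditions are waived.

Mode `emrae` works on uncapped adjacencies; mode `rgrpt` caps all
chromosomes first, so frontier events leave admissible evidence.

Two numerical/structural choices keep the recursion well defined.
First, taken literally the recursion is circular: the near-side set of
a sub-edge depends, through its own step c, on the set being computed.
The deep sets `Ca(ei, ui)` therefore recurse fully (they descend
strictly away from the focal edge, so this terminates), while the
near-side sets used in the blocking/anchoring comparisons are their
step-a ∪ step-b parts.  Results are memoized per (edge, endpoint,
mode), giving O(edges) set computations per tree.  Second, every
step-c/extension promotion is post-filtered by the side condition
(occurs in ≥ 1 genome on `N`'s side, in none on the far side), which
holds by construction for steps a and b and is asserted for the
recursive stages.  In rgrpt mode the candidate sets restricted to
uncapped adjacencies provably contain the emrae sets, which the test
suite checks on simulated data.

## Inference rules

For edge `e = (A, B)` with `A` ancestral, destroyed adjacencies are
sought in `Ca(e, A)`, created in `Ca(e, B)`.  Rule families run in
fixed order — reversal/translocation, transposition, fission/fusion —
and each candidate adjacency backs at most one event per edge (greedy
consumption, quadruples/sextuples enumerated in canonical sort order;
output is deterministic).

**Reversal / translocation.**  The quadruple `a1 = a(p, x), a2 =
a(y, q)` vs `b1 = a(p, −y), b2 = a(−x, q)` is exactly the signature of
reversing segment `x…y` (with `p` or `q` possibly a cap).  Read with
one adjacency in flipped orientation, the same quadruple also covers
both translocation forms — the printed second pattern is algebraically
subsumed, so a single matcher handles all three and no event is found
twice.  The type is decided by context: reversal when all genomes are
uni-chromosomal, or when on each side some genome carries the four
witness blocks on one chromosome; otherwise translocation.  Two
refinements follow from the operator definitions: a quadruple touching
a telomere cap cannot be a translocation (translocation splits are
interior by definition), so it is typed reversal when one-chromosome
support exists and otherwise matches no single operation and is
skipped.  The type decision is the method's weakest point at high
event density: once later events scatter the witness blocks across
chromosomes in every extant genome, a true reversal is indistinguishable
from a translocation on observational evidence (see Limitations).

**Transposition.**  The sextuple `a1 = a(p, x), a2 = a(y, q), a3 =
a(z, w)` vs `b1 = a(p, q), b2 = a(z, x), b3 = a(y, w)` describes
fragment `x…y` reinserted after `z`.  Because the operator preserves
fragment orientation, the six readings must be jointly realizable in a
single reading frame: on each side, no genome may place two of the
witness readings on one chromosome in opposite traversal directions.
Without this check, pairs of reversals sharing a breakpoint combine
into signatures realizable only as orientation-flipping moves, which
the operator set does not contain — on reversal-only data these were
the dominant false-positive class.  On multichromosomal data the call
additionally requires, with `m` the number of A-side genomes carrying
both `a1` and `a2`, that ≥ m/2 genomes place the blocks of `a1, a2`
(or of `a2, a3`) on one chromosome (integer comparison `2c ≥ m`, no
rounding).

**Fission / fusion.**  A surviving single adjacency `a = a(u, v)` in
`Ca(e, A)` is called a fission when every B-side genome is
*sign-compatible* with the split.  Sign-compatibility is formalized via
caps: genome `G` is compatible iff `a(u, 0)` and `a(0, v)` are capped
adjacencies of `G`, i.e. `u` ends a chromosome and `v` begins one, up
to whole-chromosome flips.  This is exactly "G could descend from
splitting `a`", is invariant under `X ≡ −X`, and rejects the remnants
of reversals, transpositions and translocations, which would otherwise
all surface as spurious fissions.  A fusion on `(A, B)` is the same
pattern read from the B side.  Cap adjacencies may serve as fusion
witnesses in rgrpt mode.

## Simulator

`evolve` walks the tree in pre-order; on each edge it draws
`k ~ Uniform{k_min..k_max}` and applies `k` sampled events.  Event
types are drawn proportionally to a weight map restricted to the types
structurally feasible for the current genome; placements are uniform
over legal positions.  Reversals span one block with probability 1/4
and otherwise a uniformly drawn longer segment (the 1:3 one-gene to
multi-gene ratio is enforced in expectation, not by quota).
Translocation mode (prefix–prefix vs prefix–suffix) and fusion
orientation are uniform; the fusion/fission weight in the mixed
protocol (0.1) is split evenly between the two.  Every applied event
is logged per edge with its capped adjacency signature and replay
parameters; replaying the log from the ancestor byte-exactly reproduces
the leaf genomes (tested), and a fixed seed reproduces everything.

The two study protocols:

* **Reversal-only** — for each leaf count 3…10, eleven datasets with
  uni-chromosomal identity ancestors of m = 50, 60, …, 150 blocks,
  3–10 reversals per edge, on the trifurcating caterpillar.
* **Mixed-event** — 5 chromosomes × 100 blocks, 4-leaf caterpillar,
  `k ~ Uniform{1..μ}` per edge for μ ∈ {6, 12, 18, 24}, ten replicates
  per μ, type weights 10 : 2 : 2 : 0.1.

What the generator emulates — and does not.  It reproduces the
rearrangement process itself (uniform breakpoints, configurable type
mix, multi-event edges) on equal-content genomes.  Real synteny-block
data additionally contain block boundary noise, lineage-specific block
gain/loss, unequal resolution between species, and rate variation
across branches; none of these are simulated, so passing benchmarks
demonstrate correctness of the inference machinery under the stated
process, not robustness to map noise.

## Evaluation

Predictions are matched to truth-log events per edge by maximum
one-to-one bipartite matching; a pair is admissible when the types
agree (fusion and fission pooled — their direction depends on which
endpoint is ancestral) and the created-adjacency sets intersect in
capped canonical form.  Matching on created-set overlap tolerates
equivalent index descriptions of one event while still tying a
prediction to specific breakpoints; a strict variant (exact created-set
equality) is available as a flag.  Sensitivity is correct/true,
specificity correct/predicted; zero denominators are reported as
absent, not zero.  Study tables report per-group means, then grand
means, on the scale of one decimal percent.

## Problem sizes

The benchmark drivers run the full study protocols (88 reversal-only
datasets, 40 mixed-event datasets, both predictor modes): one full pass
takes a few seconds on one CPU, and the acceptance script repeats it
from a single seed.  The test suite re-runs the studies over three
fixed seed batches.

## Known limitations

* Equal block content is assumed; duplicated or missing blocks and
  circular chromosomes are rejected at parse time.
* Direction of an event on an edge is fixed by the rooting convention;
  on a two-leaf (cherry) tree both pendant edges carry the same
  bipartition and a single event is attributed, mirrored, to both —
  only the trifurcating representation avoids this for larger trees.
* Reversal-vs-translocation typing relies on co-chromosome evidence in
  extant genomes.  At high event density this evidence decays: a true
  reversal whose witness blocks were later scattered across chromosomes
  in every leaf genome is typed as a translocation ("otherwise" branch
  of the rule), which simultaneously costs one false positive and one
  missed event.  This is the dominant error mode in the mixed-event
  study at large μ and is irreducible without reconstructing ancestral
  chromosome assignments, which is out of scope.
* Events whose adjacency signature is empty under `X ≡ −X` (e.g. a
  whole-chromosome reversal) are undetectable in principle; the
  simulator still counts them as true events.
* Within an edge, the order of multiple events is not inferred.
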