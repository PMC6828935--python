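# rgrpt

Inference of genome rearrangement events — reversals, translocations,
transpositions, fusions and fissions — on the edges of a phylogenetic
tree, from the signed synteny-block orders of extant genomes.

## The problem

Comparative maps reduce each genome to an ordering of conserved synteny
blocks: every chromosome is a signed permutation `X = c1 c2 ... cn`,
where the sign of a block records its orientation and `X` equals `−X`
(the reverse reading with flipped signs).  Rearrangement events rewrite
these orderings.  Given the block orders of present-day species and
their phylogeny `T`, the task is not to compute a distance or an
ancestral genome, but to name the individual events and attribute each
one to a specific edge of `T`.

The unit of evidence is the *adjacency* `a(ci, ci+1)`, an ordered pair
of consecutive signed blocks, with `a(x, y) ≡ a(−y, −x)`.  Every event
destroys a small set of adjacencies and creates another: a reversal
`r(i, j)` turns `a1 = a(c_{i−1}, c_i)`, `a2 = a(c_j, c_{j+1})` into
`b1 = a(c_{i−1}, −c_j)`, `b2 = a(−c_i, c_{j+1})`; a transposition
changes three adjacencies, a translocation two, fusion/fission one.
For each edge `e = (A, B)`, removing `e` splits the leaves into sides
`S_A` and `S_B`, and candidate sets `Ca(e, A)`, `Ca(e, B)` collect the
adjacencies attributable to each endpoint (present on that side, absent
beyond the edge — admitted by direct conservation, per-subtree
presence, or a recursive rule that follows displaced adjacencies across
subtrees).  Typed events are then read off by matching the
destroyed/created patterns above between the two candidate sets.

Two predictor modes are provided:

* **emrae** — the adjacency-based baseline, blind to events at
  chromosome ends (a reversal touching position 1 leaves only one
  detectable breakpoint);
* **rgrpt** — the same inference rules after capping every chromosome
  with the telomere sentinel `0`, which turns chromosome ends into
  ordinary adjacencies (`a(0, c1)`, `a(cn, 0)`), plus a relaxed
  candidate-promotion rule; this recovers the "frontier" events the
  baseline provably misses.

The package also contains the forward simulator used to measure both
modes (events drawn along a caterpillar phylogeny with configurable
per-edge counts and type mix) and the evaluation layer that matches
predictions one-to-one against simulation truth logs and reports
sensitivity (correct / true events) and specificity (correct /
predicted events).

## Worked example

Simulate a small dataset (4 leaves, 2 chromosomes of 25 blocks, 1–3
events per edge), infer events, and score them:

```
$ rgrpt simulate --leaves 4 --chromosomes 2 --blocks 25 \
      --k-min 1 --k-max 3 --seed 7 --out demo
wrote 11 events over 5 edges to demo

$ rgrpt infer --genomes demo/genomes.txt --tree demo/tree.nwk --method rgrpt
edge_id  ancestor  descendant  type           params           destroyed          created            method
0        _anc1     L1          translocation  -28,-27,18,19    -28,-27;-19,-18    -28,-18;-19,-27    rgrpt
0        _anc1     L1          transposition  -47,-46,...      -47,-46;-46,-45;.. -47,-45;-46,-4;..  rgrpt
1        _anc1     L2          reversal       -29,-28,-28,-27  -29,-28;-28,-27    -29,28;27,-28      rgrpt
...

$ rgrpt evaluate --genomes demo/genomes.txt --tree demo/tree.nwk \
      --truth demo/truth.tsv --method rgrpt
{
  "n_true": 11,
  "n_predicted": 7,
  "n_correct": 7,
  "sensitivity": 0.6363636363636364,
  "specificity": 1.0
}
```

Each prediction row names the edge (ancestor → descendant), the event
type, and the adjacencies the event destroyed and created — e.g. the
`L2` row is a reversal whose two breakpoints rewrote `a(−29,−28),
a(−28,−27)` into `a(−29,28), a(27,−28)` (a one-block reversal of block
28).  Here 7 of the 11 simulated events are recovered, all 7
predictions being correct; the misses are events whose adjacency
evidence was overwritten by later events on the same lineage.

Genome files use the GRIMM convention (`>name` headers, one chromosome
per line of signed integers ending in `$`); trees are newick with leaf
names matching genome names.  The library API mirrors the CLI:
`rgrpt.infer_all(tree, mode)`, `rgrpt.simulate_dataset(cfg)`,
`rgrpt.score(predictions, truth)`.

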