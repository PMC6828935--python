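import random

import pytest

from rgrpt.genome import Genome
from rgrpt.tree import parse_newick


def quartet_tree(ancestral: Genome, derived: Genome):
    """Trifurcating-root quartet: two leaves carry the ancestral state,
    two (below the internal edge, id 0) the derived state."""
    tree = parse_newick("((B1,B2)P,A1,A2)R;")
    tree.bind_genomes(
        [
            Genome("A1", ancestral.chromosomes),
            Genome("A2", ancestral.chromosomes),
            Genome("B1", derived.chromosomes),
            Genome("B2", derived.chromosomes),
        ]
    )
    return tree


@pytest.fixture
def make_quartet():
    return quartet_tree


@pytest.fixture
def rng():
    return random.Random(20240917)


def random_genome(rng: random.Random, n_blocks: int, n_chromosomes: int = 1,
                  name: str = "G") -> Genome:
    labels = list(range(1, n_blocks + 1))
    rng.shuffle(labels)
    signed = [l if rng.random() < 0.5 else -l for l in labels]
    if n_chromosomes == 1:
        return Genome(name, (tuple(signed),))
    cuts = sorted(rng.sample(range(1, n_blocks), n_chromosomes - 1))
    chroms, prev = [], 0
    for c in cuts + [n_blocks]:
        chroms.append(tuple(signed[prev:c]))
        prev = c
    return Genome(name, tuple(chroms))
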