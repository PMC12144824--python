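import random

import pytest

from spplin.genomes import Genome, parse_unimog
from spplin.simulate import random_genome, worked_example


@pytest.fixture
def example_pair():
    """The five-marker genome pair with its resolved homology."""
    genome_a, genome_b, families, matching = worked_example()
    return genome_a, genome_b, matching


def random_pair(rng: random.Random, max_markers: int = 5, n_families: int = 4):
    """A random tiny genome pair over a small family universe (at most two
    families end up duplicated)."""
    universe = [str(i + 1) for i in range(n_families)]
    fams_a = [rng.choice(universe) for _ in range(rng.randint(0, max_markers))]
    fams_b = [rng.choice(universe) for _ in range(rng.randint(0, max_markers))]
    a = random_genome(rng, "A", fams_a)
    b = random_genome(rng, "B", fams_b)
    return a, b


def random_degenerate(rng: random.Random, max_markers: int = 4, max_adj: int = 10):
    """A random degenerate genome with at most ``max_adj`` adjacencies."""
    from spplin.genomes import DegenerateGenome, Extremity

    fams = {f"m{i}": f"m{i}" for i in range(rng.randint(1, max_markers))}
    d = DegenerateGenome("D", fams)
    exts = d.extremities()
    n_telo = 0
    for _ in range(rng.randint(0, max_adj)):
        u = rng.choice(exts)
        if rng.random() < 0.25:
            n_telo += 1
            v = Extremity(f"t{n_telo}", "o")
        else:
            v = rng.choice(exts)
            if v == u:
                continue
        d.add_adjacency(u, v)
    return d
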