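import random

import pytest

from spplin.genomes import AdjacencyWeights, DegenerateGenome, Extremity, parse_unimog
from spplin.linearize import (
    augment_local_guarantees,
    augment_safer,
    brute_force_linearizable,
    linearizability_weight,
    try_linearize,
)

from conftest import random_degenerate


class TestWeights:
    def test_extremity_extremity(self):
        assert linearizability_weight((Extremity("1", "h"), Extremity("2", "t"))) == 2

    def test_extremity_telomere(self):
        assert linearizability_weight((Extremity("1", "t"), Extremity("t1", "o"))) == 1

    def test_telomere_telomere_rejected(self):
        with pytest.raises(ValueError):
            linearizability_weight((Extremity("t1", "o"), Extremity("t2", "o")))


class TestTryLinearize:
    def test_uncoverable_extremity_infeasible(self):
        d = DegenerateGenome("D", {"a": "a", "b": "b"})
        d.add_adjacency(Extremity("a", "h"), Extremity("b", "t"))
        d.add_adjacency(Extremity("a", "h"), Extremity("b", "h"))
        res = try_linearize(d)
        assert not res.feasible and res.linearization is None

    def test_proper_genome_linearizes_to_itself(self):
        (g,) = parse_unimog(">A\n1 2 |\n3 )")
        res = try_linearize(g)
        assert res.feasible
        assert res.linearization.adjacencies == g.adjacencies
        assert res.matching_weight == 2 * len(g.families)

    def test_matching_weight_counts_covered_extremities(self):
        rng = random.Random(77)
        for _ in range(30):
            d = random_degenerate(rng)
            res = try_linearize(d)
            if res.feasible:
                assert res.matching_weight == 2 * len(d.families)
                res.linearization.validate()

    def test_feasibility_matches_exhaustive_subset_search(self):
        rng = random.Random(99)
        for _ in range(80):
            d = random_degenerate(rng)
            assert try_linearize(d).feasible == brute_force_linearizable(d)

    def test_weights_break_ties_toward_heavy_adjacencies(self):
        # two conflicting linearizations of a 2-marker circle; the weighted
        # one must win
        d = DegenerateGenome("D", {"1": "1", "2": "2"})
        h1, t1 = Extremity("1", "h"), Extremity("1", "t")
        h2, t2 = Extremity("2", "h"), Extremity("2", "t")
        for u, v in ((h1, t2), (h2, t1), (h1, h2), (t1, t2)):
            d.add_adjacency(u, v)
        w = AdjacencyWeights()
        w.set(h1, h2, 5.0)
        w.set(t1, t2, 5.0)
        res = try_linearize(d, w)
        assert res.feasible
        assert (min(h1, h2), max(h1, h2)) in res.linearization.adjacencies


class TestAugmentation:
    def test_even_path_component_unchanged(self):
        (g,) = parse_unimog(">A\n1 |")  # t - 1t - 1h - t, size 4 path
        aug = augment_local_guarantees(g)
        assert aug.adjacencies == g.adjacencies

    def test_odd_component_gets_telomeres(self):
        d = DegenerateGenome("D", {"1": "1"})
        d.add_adjacency(Extremity("1", "t"), Extremity("t1", "o"))
        # component {t1, 1t, 1h} has odd size: every extremity is augmented
        aug = augment_local_guarantees(d)
        assert len(aug.adjacencies) > len(d.adjacencies)
        assert try_linearize(aug).feasible

    def test_fully_connected_component_unchanged(self):
        d = DegenerateGenome("D", {"1": "1", "2": "2"})
        exts = d.extremities()
        for i, u in enumerate(exts):
            for v in exts[i + 1 :]:
                d.add_adjacency(u, v)
        aug = augment_local_guarantees(d)
        assert aug.adjacencies == d.adjacencies

    def test_local_guarantees_make_random_genomes_linearizable(self):
        rng = random.Random(13)
        for _ in range(40):
            d = random_degenerate(rng)
            assert try_linearize(augment_local_guarantees(d)).feasible

    def test_safer_adds_one_telomere_per_extremity(self):
        rng = random.Random(14)
        for _ in range(20):
            d = random_degenerate(rng)
            n_ext = 2 * len(d.families)
            aug, delta = augment_safer(d, telomere_weight=0.0)
            assert len(aug.adjacencies) == len(d.adjacencies) + n_ext
            assert len(list(delta.items())) == n_ext
            assert try_linearize(aug).feasible

    def test_safer_is_idempotent(self):
        rng = random.Random(15)
        d = random_degenerate(rng)
        aug, _ = augment_safer(d)
        aug2, delta2 = augment_safer(aug)
        assert aug2.adjacencies == aug.adjacencies
        assert not list(delta2.items())
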