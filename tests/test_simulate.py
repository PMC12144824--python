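import pytest

from spplin.cfmrd import census, distance_max_matching, distance_resolved
from spplin.simulate import (
    SimulationConfig,
    add_noise,
    evolve,
    simulate,
    worked_example,
)


class TestEvolve:
    def test_zero_operations_keeps_all_genomes_identical(self):
        truth = evolve(SimulationConfig(markers=10, ops_per_branch=0, noise=0, seed=1))
        from spplin.cfmrd import genome_state

        states = {genome_state(truth.phylogeny.genome(n)) for n in truth.phylogeny.nodes}
        assert len(states) == 1

    def test_identical_seeds_reproduce_identical_truths(self):
        cfg = SimulationConfig(markers=15, ops_per_branch=6, noise=4, seed=77)
        t1, t2 = simulate(cfg), simulate(SimulationConfig(**cfg.__dict__))
        for n in t1.phylogeny.nodes:
            assert (
                t1.phylogeny.genome(n).adjacencies
                == t2.phylogeny.genome(n).adjacencies
            )
        for n in t1.candidates:
            assert t1.candidates[n].adjacencies == t2.candidates[n].adjacencies

    def test_every_simulated_genome_is_valid(self):
        truth = evolve(SimulationConfig(markers=12, ops_per_branch=8, seed=3))
        for n in truth.phylogeny.nodes:
            truth.phylogeny.genome(n).validate()

    def test_operation_log_matches_configured_count(self):
        cfg = SimulationConfig(markers=10, ops_per_branch=5, noise=0, seed=2)
        truth = evolve(cfg)
        assert all(len(ops) == 5 for ops in truth.operations.values())

    def test_branch_distance_bounded_by_operation_count(self):
        # each operation changes the distance by at most one
        cfg = SimulationConfig(markers=6, ops_per_branch=3, noise=0, seed=13)
        truth = evolve(cfg)
        for (p, c), ops in truth.operations.items():
            d = distance_max_matching(
                truth.phylogeny.genome(p), truth.phylogeny.genome(c)
            )
            assert d <= len(ops)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(dup_rate=0.8, del_rate=0.3).validate()


class TestNoise:
    def test_zero_noise_candidates_equal_truth(self):
        truth = simulate(SimulationConfig(markers=10, ops_per_branch=3, noise=0, seed=4))
        for node in truth.phylogeny.internal:
            assert (
                truth.candidates[node].adjacencies
                == truth.phylogeny.genome(node).adjacencies
            )

    def test_noise_count_and_disjointness(self):
        truth = evolve(SimulationConfig(markers=10, ops_per_branch=3, noise=0, seed=5))
        true_sets = truth.true_adjacency_sets()
        add_noise(truth, k=7, seed=9)
        for node in truth.phylogeny.internal:
            cand = truth.candidates[node].adjacencies
            noise = cand - true_sets[node]
            assert len(noise) == 7
            assert not noise & true_sets[node]

    def test_excessive_noise_rejected(self):
        truth = evolve(SimulationConfig(markers=2, ops_per_branch=0, noise=0, seed=6))
        with pytest.raises(ValueError):
            add_noise(truth, k=10_000)


class TestWorkedExample:
    def test_census_reproduces_the_printed_counts(self):
        a, b, families, matching = worked_example()
        c = census(a, b, matching)
        assert (c.c, c.p_AB, c.p_ab, c.p_aB, c.p_Ab) == (2, 1, 1, 1, 1)
        assert distance_resolved(c) == 3

    def test_both_genomes_are_single_linear_five_marker_chromosomes(self):
        a, b, _, _ = worked_example()
        for g in (a, b):
            assert len(g.families) == 5
            (chrom,) = g.chromosomes()
            assert chrom[0] == "linear"

    def test_families_partition_as_printed(self):
        a, b, families, matching = worked_example()
        got = {}
        for g in (a, b):
            for m, f in g.families.items():
                got.setdefault(f, []).append(m)
        assert {f: sorted(ms) for f, ms in got.items()} == families

    def test_printed_path_vertex_sequences_occur(self):
        # the paths listed for the resolved diagram arise as components
        from spplin.cfmrd import _matching_edges
        from spplin.genomes import Extremity

        a, b, _, matching = worked_example()
        vertices, adj, ext, selfp = _matching_edges(a, b, matching)
        nbr = {}
        for u, v in adj + ext:  # self edges ignored
            nbr.setdefault(u, set()).add(v)
            nbr.setdefault(v, set()).add(u)

        def component(start):
            comp, stack = {start}, [start]
            while stack:
                x = stack.pop()
                for y in nbr.get(x, ()):
                    if y not in comp:
                        comp.add(y)
                        stack.append(y)
            return comp

        ab_path = component(("A", Extremity("4_1", "t")))
        assert ab_path == {
            ("A", Extremity("4_1", "t")),
            ("A", Extremity("2_1", "h")),
            ("B", Extremity("2_2", "h")),
            ("B", Extremity("5_1", "t")),
        }
        aB_path = component(("A", Extremity("4_1", "h")))
        assert {("A", Extremity("3_1", "h")), ("B", Extremity("3_2", "h"))} <= aB_path
        assert any(v[1].is_telomere and v[0] == "B" for v in aB_path)
        Ab_path = component(("B", Extremity("5_1", "h")))
        assert {("A", Extremity("3_1", "t")), ("B", Extremity("3_2", "t"))} <= Ab_path
        assert any(v[1].is_telomere and v[0] == "A" for v in Ab_path)
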