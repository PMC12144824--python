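import random

import numpy as np
import pytest

from spplin.cfmrd import distance_max_matching
from spplin.genomes import (
    DegenerateGenome,
    FamilyBounds,
    Genome,
    Phylogeny,
    parse_unimog,
)
from spplin.ilp_model import (
    build_spp_model,
    pairwise_distance_ilp,
    solve,
)
from spplin.simulate import SimulationConfig, simulate

from conftest import random_pair


class TestPairwiseDistance:
    def test_example_pair_optimum(self, example_pair):
        a, b, _ = example_pair
        assert pairwise_distance_ilp(a, b) == 3

    def test_identical_circular_genomes(self):
        a, b = parse_unimog(">A\n1 2 3 )\n>B\n1 2 3 )")
        assert pairwise_distance_ilp(a, b) == 0

    def test_matches_enumeration_oracle_on_random_pairs(self):
        rng = random.Random(2024)
        for _ in range(25):
            a, b = random_pair(rng)
            assert pairwise_distance_ilp(a, b) == distance_max_matching(a, b)

    def test_forced_circular_singleton_costs_one_indel(self):
        (a,) = parse_unimog(">A\n1 )")
        b = parse_unimog(">B\n2 |")[0]
        # the circular chromosome of the singular marker adds s = 1
        assert pairwise_distance_ilp(a, b) == 2


class TestCircularSingletonEncodings:
    @pytest.mark.parametrize("text_a,text_b", [
        (">A\n1 )", ">B\n2 |"),
        (">A\n1 )\n2 )", ">B\n3 |"),
        (">A\n1 2 )\n3 )", ">B\n4 5 |"),
    ])
    def test_enumerate_and_count_agree(self, text_a, text_b):
        a = parse_unimog(text_a)[0]
        b = parse_unimog(text_b)[0]
        d_enum = pairwise_distance_ilp(a, b, singleton_mode="enumerate")
        d_count = pairwise_distance_ilp(a, b, singleton_mode="count")
        assert d_enum == d_count == distance_max_matching(a, b)

    def test_auto_mode_engages_gadget_beyond_candidate_threshold(self):
        # a degenerate ancestor offering every adjacency among singular
        # markers has exponentially many candidate singletons
        n = 4
        fams = {f"s{i}": f"s{i}" for i in range(n)}
        anc = DegenerateGenome("X", fams)
        exts = anc.extremities()
        for i, u in enumerate(exts):
            for v in exts[i + 1 :]:
                anc.add_adjacency(u, v)
        from spplin.linearize import augment_safer

        aug, _ = augment_safer(anc)
        leaf = parse_unimog(">L\n9 |")[0]
        phylo = Phylogeny([("X", "L")], "X")
        phylo.bind(aug)
        phylo.bind(leaf)
        spp = build_spp_model(phylo, alpha=1.0, singleton_mode="auto")
        (ctx,) = spp.edges
        assert ctx.singleton_mode == "count"
        # with few candidate adjacencies enumeration stays active
        anc2 = DegenerateGenome("X", {"s0": "s0"})
        anc2.add_adjacency(*anc2.extremities())
        aug2, _ = augment_safer(anc2)
        phylo2 = Phylogeny([("X", "L")], "X")
        phylo2.bind(aug2)
        phylo2.bind(parse_unimog(">L\n9 |")[0])
        spp2 = build_spp_model(phylo2, alpha=1.0, singleton_mode="auto")
        assert spp2.edges[0].singleton_mode == "enumerate"


class TestGlobalLevel:
    def test_leaf_selection_is_fully_forced(self):
        a, b = parse_unimog(">A\n1 2 |\n>B\n1 2 |")
        phylo = Phylogeny([("A", "B")], "A")
        phylo.bind(a)
        phylo.bind(b)
        spp = build_spp_model(phylo, alpha=1.0)
        # the leaf's variables are fixed outright
        for var in spp.adj_vars["B"].values():
            assert var.lb == var.ub == 1
        # the root carries a proper genome: presence is forced and the
        # one-adjacency-per-extremity rule leaves no freedom either
        for var in spp.g_vars["A"].values():
            if not var.name.split("|")[2].startswith("t"):
                assert var.lb == var.ub == 1
        sol = solve(spp)
        assert sol.linearizations["A"].adjacencies == a.adjacencies

    def test_family_bounds_allow_dropping_a_copy(self):
        # ancestor with two copies of family 1 but bounds (1, 1): the ILP
        # must drop one copy to match the single-copy leaves
        anc = DegenerateGenome("X", {"1_1": "1", "1_2": "1"})
        t1, h1 = anc.extremities()[0:2]
        from spplin.linearize import augment_safer

        aug, _ = augment_safer(anc)
        leaf_a, leaf_b = parse_unimog(">La\n1 |\n>Lb\n1 |")
        phylo = Phylogeny([("X", "La"), ("X", "Lb")], "X")
        phylo.bind(aug)
        phylo.bind(leaf_a)
        phylo.bind(leaf_b)
        fb = FamilyBounds()
        fb.set("X", "1", 1, 1)
        spp = build_spp_model(phylo, bounds=fb, alpha=1.0)
        sol = solve(spp)
        assert len(sol.linearizations["X"].families) == 1
        assert sum(sol.distances.values()) == 0

    def test_infeasible_bounds_reported(self):
        anc = DegenerateGenome("X", {"1_1": "1"})  # no adjacencies at all
        leaf = parse_unimog(">L\n1 |")[0]
        phylo = Phylogeny([("X", "L")], "X")
        phylo.bind(anc)
        phylo.bind(leaf)
        spp = build_spp_model(phylo, alpha=1.0)
        with pytest.raises(RuntimeError):
            solve(spp)


class TestSppConsistency:
    def test_two_leaf_tree_equals_pairwise_distance(self):
        rng = random.Random(7)
        for _ in range(5):
            a, b = random_pair(rng)
            a2 = Genome("P", a.families, a.adjacencies, a.telomeres)
            b2 = Genome("C", b.families, b.adjacencies, b.telomeres)
            phylo = Phylogeny([("P", "C")], "P")
            phylo.bind(a2)
            phylo.bind(b2)
            sol = solve(build_spp_model(phylo, alpha=1.0))
            assert round(sol.objective) == distance_max_matching(a, b)

    def test_star_tree_with_true_candidates_has_distance_zero(self):
        (g,) = parse_unimog(">G\n1 2 3 |\n4 -5 )")
        phylo = Phylogeny([("Anc", f"L{i}") for i in (1, 2, 3)], "Anc")
        for i in (1, 2, 3):
            phylo.bind(Genome(f"L{i}", g.families, g.adjacencies, g.telomeres))
        phylo.bind(DegenerateGenome("Anc", g.families, g.adjacencies, g.telomeres))
        sol = solve(build_spp_model(phylo, alpha=1.0))
        assert sum(sol.distances.values()) == 0

    def test_monotonicity_enlarging_candidates_never_hurts(self):
        # adding candidate adjacencies can only keep or lower the optimum
        truth = simulate(SimulationConfig(markers=6, ops_per_branch=2, noise=0, seed=21))
        base = truth.spp_phylogeny()
        o1 = solve(build_spp_model(base, alpha=1.0)).objective
        noisy = simulate(SimulationConfig(markers=6, ops_per_branch=2, noise=0, seed=21))
        from spplin.simulate import add_noise

        add_noise(noisy, k=4, seed=1)
        o2 = solve(build_spp_model(noisy.spp_phylogeny(), alpha=1.0)).objective
        assert o2 <= o1 + 1e-9

    def test_decoded_genomes_are_valid_and_distances_recomputed(self):
        truth = simulate(SimulationConfig(markers=8, ops_per_branch=3, noise=3, seed=4))
        from spplin.linearize import augment_safer
        from spplin.genomes import AdjacencyWeights

        phylo = truth.spp_phylogeny()
        weights = AdjacencyWeights(1.0)
        p2 = Phylogeny(phylo.edges, phylo.root)
        for leaf in phylo.leaves:
            p2.bind(phylo.genome(leaf))
        for node in phylo.internal:
            aug, delta = augment_safer(phylo.genome(node))
            for adj, w in delta.items():
                weights._w[adj] = w
            p2.bind(aug)
        spp = build_spp_model(p2, weights=weights, alpha=0.5)
        sol = solve(spp)
        for node, genome in sol.linearizations.items():
            genome.validate()  # raises on any inconsistency
        for (p, c), d in sol.distances.items():
            assert d == distance_max_matching(
                sol.linearizations[p], sol.linearizations[c]
            )


class TestIlpSize:
    def test_size_grows_linearly_with_diagram_size(self):
        sizes = []
        for markers in (6, 12, 24, 48):
            truth = simulate(
                SimulationConfig(markers=markers, ops_per_branch=3, noise=3, seed=11)
            )
            spp = build_spp_model(truth.spp_phylogeny(), alpha=1.0)
            total_cfmrd = sum(ctx.cfmrd.size() for ctx in spp.edges)
            sizes.append((total_cfmrd, spp.model.n_vars + spp.model.n_constrs))
        x = np.array([s for s, _ in sizes], dtype=float)
        y = np.array([t for _, t in sizes], dtype=float)
        coeffs = np.polyfit(x, y, 1)
        residuals = y - np.polyval(coeffs, x)
        assert np.max(np.abs(residuals)) / np.mean(y) < 0.05
        ratios = y / x
        assert ratios.max() / ratios.min() < 1.6
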