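import random

import pytest

from spplin.genomes import AdjacencyWeights, Phylogeny
from spplin.ilp_model import build_spp_model, solve
from spplin.linearize import augment_safer
from spplin.preprocess import (
    NotLinearizableError,
    initial_solution,
    leaf_pair_lower_bounds,
)
from spplin.simulate import SimulationConfig, simulate


def noisy_model(seed, markers=8, ops=3, noise=3, alpha=0.5):
    truth = simulate(
        SimulationConfig(markers=markers, ops_per_branch=ops, noise=noise, seed=seed)
    )
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
    return build_spp_model(p2, weights=weights, alpha=alpha), truth


class TestInitialSolution:
    def test_assignment_satisfies_every_constraint(self):
        for seed in (0, 1, 2):
            spp, _ = noisy_model(seed)
            ws = initial_solution(spp)
            assert spp.model.check_assignment(ws.assignment) == []

    def test_objective_is_an_upper_bound_on_the_optimum(self):
        for seed in (3, 4):
            spp, _ = noisy_model(seed)
            ws = initial_solution(spp)
            sol = solve(spp)
            assert ws.objective >= sol.objective - 1e-9

    def test_identical_leaf_pair_reaches_distance_zero(self):
        truth = simulate(SimulationConfig(markers=6, ops_per_branch=0, noise=0, seed=5))
        spp = build_spp_model(truth.spp_phylogeny(), alpha=1.0)
        ws = initial_solution(spp)
        assert ws.objective == 0.0

    def test_solver_accepts_the_start_without_repair(self):
        spp, _ = noisy_model(6)
        ws = initial_solution(spp)
        sol = solve(spp, warm_start=ws.assignment)
        assert sol.status.startswith("optimal")
        assert sol.objective <= ws.objective + 1e-9

    def test_non_linearizable_node_is_reported(self):
        from spplin.genomes import DegenerateGenome, parse_unimog

        anc = DegenerateGenome("X", {"1_1": "1"})  # uncoverable extremities
        leaf = parse_unimog(">L\n1 |")[0]
        phylo = Phylogeny([("X", "L")], "X")
        phylo.bind(anc)
        phylo.bind(leaf)
        spp = build_spp_model(phylo, alpha=1.0)
        with pytest.raises(NotLinearizableError):
            initial_solution(spp)


class TestLeafPairBounds:
    def test_two_leaf_bound_is_tight(self):
        from spplin.genomes import DegenerateGenome

        truth = simulate(SimulationConfig(markers=6, ops_per_branch=2, noise=0, seed=8))
        phylo = truth.phylogeny
        a, b = phylo.genome("A"), phylo.genome("B")
        two = Phylogeny([("R", "A"), ("R", "B")], "R")
        two.bind(a)
        two.bind(b)
        # the root ancestor may adopt A's gene order outright
        two.bind(DegenerateGenome("R", a.families, a.adjacencies, a.telomeres))
        spp = build_spp_model(two, alpha=1.0)
        dists = leaf_pair_lower_bounds(spp)
        sol = solve(spp)
        assert round(sol.objective) == dists[("A", "B")]

    def test_bounds_do_not_change_the_optimum(self):
        for seed in (9, 10):
            spp1, _ = noisy_model(seed, alpha=1.0)
            o1 = solve(spp1).objective
            spp2, _ = noisy_model(seed, alpha=1.0)
            leaf_pair_lower_bounds(spp2)
            o2 = solve(spp2).objective
            assert abs(o1 - o2) < 1e-9

    def test_four_leaf_tree_emits_all_six_pairs(self):
        spp, _ = noisy_model(11, alpha=1.0)
        dists = leaf_pair_lower_bounds(spp)
        assert len(dists) == 6
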