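import pytest

from spplin.evaluate import score
from spplin.genomes import Genome, Phylogeny
from spplin.ilp_model import Solution, build_spp_model, solve
from spplin.simulate import SimulationConfig, simulate


def solved_instance(seed=5, noise=0):
    truth = simulate(
        SimulationConfig(markers=8, ops_per_branch=3, noise=noise, seed=seed)
    )
    sol = solve(build_spp_model(truth.spp_phylogeny(), alpha=1.0))
    return truth, sol


class TestScore:
    def test_perfect_recovery_scores_one(self):
        truth, _ = solved_instance()
        perfect = Solution(
            {
                n: truth.phylogeny.genome(n)
                for n in truth.phylogeny.nodes
            },
            {},
            0.0,
            "optimal",
            None,
        )
        sc = score(perfect, truth)
        assert sc.precision == sc.recall == sc.f1 == 1.0
        assert sc.pooled_f1 == 1.0

    def test_zero_noise_reconstruction_is_exact(self):
        truth, sol = solved_instance()
        sc = score(sol, truth)
        assert sc.f1 == 1.0

    def test_empty_recovery_convention(self):
        truth, _ = solved_instance()
        empty = Solution(
            {n: Genome(n, {}) for n in truth.phylogeny.nodes}, {}, 0.0, "x", None
        )
        sc = score(empty, truth)
        assert sc.recall == 0.0
        assert sc.precision == 1.0  # defined as 1 on the empty set, flagged
        assert all(ns.empty_recovery for ns in sc.per_node.values())

    def test_score_invariant_under_adjacency_orientation(self):
        truth, sol = solved_instance(seed=6)
        flipped = {}
        for n, g in sol.linearizations.items():
            flipped[n] = Genome(
                n, g.families, [(v, u) for u, v in g.adjacencies], g.telomeres
            )
        sc1 = score(sol, truth)
        sc2 = score(Solution(flipped, {}, 0.0, "x", None), truth)
        assert sc1.f1 == sc2.f1 and sc1.precision == sc2.precision

    def test_missing_node_rejected(self):
        truth, sol = solved_instance(seed=7)
        broken = dict(sol.linearizations)
        broken.pop(truth.phylogeny.internal[0])
        with pytest.raises(ValueError):
            score(Solution(broken, {}, 0.0, "x", None), truth)

    def test_telomere_modes(self):
        truth, sol = solved_instance(seed=8)
        for mode in ("auto", "include", "exclude"):
            sc = score(sol, truth, telomeres=mode)
            assert 0.0 <= sc.f1 <= 1.0
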