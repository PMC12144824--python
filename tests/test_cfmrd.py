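import random

import pytest

from spplin.cfmrd import (
    BudgetExceededError,
    bfs_operation_oracle,
    build_cfmrd,
    census,
    distance_max_matching,
    distance_resolved,
    iter_maximum_matchings,
)
from spplin.genomes import Genome, parse_unimog

from conftest import random_pair


class TestDiagram:
    def test_example_pair_unresolved_homology_edge_counts(self, example_pair):
        a, b, _ = example_pair
        diagram = build_cfmrd(a, b, self_edges="singular")
        assert diagram.n_self_edges == 2  # markers 4_1 and 5_1
        assert len(diagram.ext_pairs) == 4 + 1 + 1  # 2x2 for family 1, 2, 3
        assert 2 * len(diagram.ext_pairs) == 12  # extremity edges

    def test_identical_single_marker_genomes(self):
        a, b = parse_unimog(">A\n1 |\n>B\n1 |")
        diagram = build_cfmrd(a, b)
        assert diagram.ext_pairs == [("1_1", "1_2")]
        assert diagram.self_markers == []

    def test_disjoint_families_all_self_edges(self):
        a, b = parse_unimog(">A\n1 2 |\n>B\n3 4 |")
        diagram = build_cfmrd(a, b)
        assert diagram.ext_pairs == []
        assert len(diagram.self_markers) == 4

    def test_ranks_are_a_bijection_with_telomeres_first(self):
        a, b = parse_unimog(">A\n1 2 |\n>B\n1 )")
        diagram = build_cfmrd(a, b)
        ranks = sorted(diagram.ranks.values())
        assert ranks == list(range(1, len(diagram.vertices) + 1))
        telo_ranks = [r for v, r in diagram.ranks.items() if v[1].is_telomere]
        ext_ranks = [r for v, r in diagram.ranks.items() if not v[1].is_telomere]
        assert max(telo_ranks) < min(ext_ranks)


class TestCensus:
    def test_example_pair_printed_counts(self, example_pair):
        a, b, matching = example_pair
        c = census(a, b, matching)
        assert (c.c, c.p_AB, c.p_ab, c.p_aB, c.p_Ab) == (2, 1, 1, 1, 1)
        assert c.p_Aa == c.p_Bb == c.s == 0
        assert c.n == 4

    def test_self_comparison_circular_genome(self):
        (g,) = parse_unimog(">A\n1 2 3 )")
        other = Genome("B", g.families, g.adjacencies, g.telomeres)
        matching = [(m, m) for m in g.families]
        c = census(g, other, matching)
        assert c.c == 3 and c.n == 3 and c.s == 0
        assert all(v == 0 for k, v in c.as_dict().items() if k.startswith("p_"))

    def test_single_marker_versus_empty(self):
        (a,) = parse_unimog(">A\n1 |")
        b = Genome("B", {})
        c = census(a, b, [])
        assert c.p_Aa == 2 and c.n == 0 and c.c == 0
        assert distance_resolved(c) == 1

    def test_unresolved_matching_rejected(self):
        a, b = parse_unimog(">A\n1 |\n>B\n1 1 |")
        with pytest.raises(ValueError):
            census(a, b, [("1_1", "1_2"), ("1_1", "1_3")])


class TestDistanceFormula:
    def test_example_pair_distance(self, example_pair):
        a, b, matching = example_pair
        assert distance_resolved(census(a, b, matching)) == 3

    def test_identical_genomes_distance_zero(self):
        a, b = parse_unimog(">A\n1 2 |\n3 )\n>B\n1 2 |\n3 )")
        matching = [("1_1", "1_2"), ("2_1", "2_2"), ("3_1", "3_2")]
        assert distance_resolved(census(a, b, matching)) == 0

    def test_maximum_matching_enumerates_family_pairings(self, example_pair):
        a, b, _ = example_pair
        matchings = list(iter_maximum_matchings(a, b))
        assert len(matchings) == 2  # the two pairings of family 1
        assert distance_max_matching(a, b) == 3

    def test_single_copy_families_have_one_matching(self):
        a, b = parse_unimog(">A\n1 2 |\n>B\n2 1 |")
        assert len(list(iter_maximum_matchings(a, b))) == 1

    def test_matching_budget_refusal(self):
        a, b = parse_unimog(">A\n1 1 1 1 1 |\n>B\n1 1 1 1 1 |")
        with pytest.raises(BudgetExceededError):
            list(iter_maximum_matchings(a, b, budget=10))


class TestBfsOracle:
    def test_equal_genomes(self):
        a, b = parse_unimog(">A\n1 2 |\n>B\n1 2 |")
        assert bfs_operation_oracle(a, b) == 0

    def test_single_inversion(self):
        a, b = parse_unimog(">A\n1 2 |\n>B\n1 -2 |")
        assert bfs_operation_oracle(a, b) == 1

    def test_single_deletion(self):
        (a,) = parse_unimog(">A\n1 |")
        assert bfs_operation_oracle(a, Genome("B", {})) == 1

    def test_depth_budget_refusal(self):
        a, b = parse_unimog(">A\n1 2 3 4 |\n>B\n-3 1 -4 2 |")
        with pytest.raises(BudgetExceededError):
            bfs_operation_oracle(a, b, max_ops=1)


class TestDistanceProperties:
    """Symmetry, identity, and three-way oracle agreement on random pairs."""

    def test_symmetry_and_identity(self):
        rng = random.Random(42)
        for _ in range(15):
            a, b = random_pair(rng)
            assert distance_max_matching(a, b) == distance_max_matching(b, a)
            aa = Genome("A2", a.families, a.adjacencies, a.telomeres)
            assert distance_max_matching(a, aa) == 0

    def test_formula_agrees_with_operation_search(self):
        rng = random.Random(1234)
        compared = 0
        for _ in range(40):
            a, b = random_pair(rng)
            d_formula = distance_max_matching(a, b)
            if d_formula > 4:
                continue
            try:
                d_ops = bfs_operation_oracle(a, b, max_ops=4)
            except BudgetExceededError:
                continue
            assert d_ops == d_formula, (a.adjacencies, b.adjacencies)
            compared += 1
        assert compared >= 20
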