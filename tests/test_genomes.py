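import random

import pytest
from hypothesis import given, settings, strategies as st

from spplin.genomes import (
    DegenerateGenome,
    Extremity,
    FamilyBounds,
    Genome,
    GenomeError,
    ParseError,
    parse_adjacency_table,
    parse_family_bounds,
    parse_newick,
    parse_unimog,
    write_unimog,
)


class TestParseUnimog:
    def test_two_marker_linear(self):
        (g,) = parse_unimog(">A\n1 2 |")
        assert sorted(g.families) == ["1_1", "2_1"]
        assert len(g.telomeres) == 2
        assert (Extremity("1_1", "h"), Extremity("2_1", "t")) in g.adjacencies

    def test_example_pair_copy_numbering_spans_the_file(self):
        a, b = parse_unimog(">A\n1 1 2 4 -3 |\n>B\n1 1 2 5 3 |")
        assert sorted(a.families) == ["1_1", "1_2", "2_1", "3_1", "4_1"]
        assert sorted(b.families) == ["1_3", "1_4", "2_2", "3_2", "5_1"]
        assert [k for k, _ in a.chromosomes()] == ["linear"]

    def test_circular_chromosome(self):
        (g,) = parse_unimog(">C\n1 -2 )")
        assert not g.telomeres
        assert (Extremity("1_1", "h"), Extremity("2_1", "h")) in g.adjacencies
        assert (Extremity("1_1", "t"), Extremity("2_1", "t")) in g.adjacencies

    @pytest.mark.parametrize(
        "text",
        [
            ">A\n1 2",  # missing terminator
            ">A\n|",  # empty chromosome
            ">A\n1 |\n>A\n2 |",  # duplicate name
            "1 2 |",  # data before header
        ],
    )
    def test_malformed_input_raises(self, text):
        with pytest.raises(ParseError):
            parse_unimog(text)

    def test_telomere_count_matches_linear_chromosomes(self):
        gs = parse_unimog(">A\n1 2 |\n3 )\n4 |\n>B\n5 6 7 |")
        for g in gs:
            n_linear = sum(1 for kind, _ in g.chromosomes() if kind == "linear")
            assert len(g.telomeres) == 2 * n_linear


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_write_then_parse_is_identity_on_the_genome_graph(data):
    rng = random.Random(data.draw(st.integers(0, 10_000)))
    from spplin.simulate import random_genome

    fams = [str(rng.randint(1, 4)) for _ in range(rng.randint(1, 6))]
    g = random_genome(rng, "G", fams)
    (g2,) = parse_unimog(write_unimog([g]))
    # equality up to marker-copy renaming: compare chromosome multisets
    from spplin.cfmrd import genome_state

    assert genome_state(g) == genome_state(g2)


class TestGenomeInvariants:
    def test_adjacency_matching_is_validated(self):
        with pytest.raises(GenomeError):
            Genome(
                "X",
                {"1": "1"},
                [
                    (Extremity("1", "t"), Extremity("1", "h")),
                    (Extremity("1", "t"), Extremity("t1", "o")),
                ],
            )

    def test_every_genome_is_a_degenerate_genome(self):
        (g,) = parse_unimog(">A\n1 2 |")
        assert isinstance(g, DegenerateGenome)
        assert not g.is_degenerate

    def test_telomere_telomere_adjacency_rejected(self):
        d = DegenerateGenome("D", {"1": "1"})
        with pytest.raises(GenomeError):
            d.add_adjacency(Extremity("t1", "o"), Extremity("t2", "o"))


class TestAdjacencyTable:
    def test_single_row(self):
        genomes, weights = parse_adjacency_table("X\t1\th\t2\tt\t1.0")
        d = genomes["X"]
        assert len(d.adjacencies) == 1
        (adj,) = d.adjacencies
        assert weights.get(*adj) == 1.0

    def test_conflicting_adjacencies_are_both_retained(self):
        genomes, _ = parse_adjacency_table("X\t1\th\t2\tt\t1.0\nX\t1\th\t3\tt\t0.5")
        assert len(genomes["X"].adjacencies) == 2
        assert genomes["X"].is_degenerate

    def test_double_telomere_row_rejected(self):
        with pytest.raises(ParseError):
            parse_adjacency_table("X\t1\to\t2\to\t1.0")

    def test_unknown_side_code_rejected(self):
        with pytest.raises(ParseError):
            parse_adjacency_table("X\t1\th\t2\tq\t1.0\nX\t1\tt\t2\th\t0")


class TestNewick:
    def test_balanced_four_leaf_topology(self):
        p = parse_newick("(((A:1.0,B:1.0)F:1.0),((C:1.0,D:1.0)G:1.0))Root;")
        assert len(p.nodes) == 7
        assert len(p.edges) == 6
        assert p.leaves == ["A", "B", "C", "D"]

    def test_two_leaves(self):
        p = parse_newick("(A,B)R;")
        assert len(p.edges) == 2
        assert p.root == "R"

    def test_unlabeled_internal_node_rejected(self):
        with pytest.raises(ParseError):
            parse_newick("(A,B);")

    def test_path_edges(self):
        p = parse_newick("(((A,B)F),((C,D)G))Root;")
        assert p.path_edges("A", "C") == [
            ("F", "A"),
            ("G", "C"),
            ("Root", "F"),
            ("Root", "G"),
        ]


class TestFamilyBounds:
    def test_default_bounds_collapse_to_all_copies(self):
        (g,) = parse_unimog(">A\n1 1 2 |")
        fb = FamilyBounds()
        assert fb.get(g, "1") == (2, 2)
        assert fb.get(g, "2") == (1, 1)

    def test_explicit_bounds_and_validation(self):
        (g,) = parse_unimog(">A\n1 1 |")
        fb = parse_family_bounds("A\t1\t0\t1\n")
        assert fb.get(g, "1") == (0, 1)
        fb.set("A", "1", 0, 5)
        with pytest.raises(ValueError):
            fb.get(g, "1")  # high exceeds candidate copies
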