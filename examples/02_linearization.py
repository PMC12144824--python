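"""Testing and restoring linearizability of a conflicting candidate set.

Ancestral-adjacency inference tools frequently propose conflicting
adjacencies (the same extremity in several of them), and sometimes leave an
extremity uncoverable.  This script shows the maximum-weight-matching test,
a failure case, and the safer augmentation that offers every extremity its
own telomere.
"""

from spplin.genomes import DegenerateGenome, Extremity, parse_adjacency_table
from spplin.linearize import augment_safer, try_linearize

table = """\
X\t1\th\t2\tt\t2.0
X\t1\th\t2\th\t0.5
X\t2\tt\t1\tt\t1.0
X\t1\tt\t0\to\t0.0
X\t2\th\t0\to\t0.0
"""
genomes, weights = parse_adjacency_table(table)
candidate = genomes["X"]
print(f"candidate set: {len(candidate.adjacencies)} adjacencies, "
      f"{2 * len(candidate.families)} extremities, degenerate: "
      f"{candidate.is_degenerate}")

result = try_linearize(candidate, weights)
print("linearizable:", result.feasible)
print("chosen adjacencies (conflicts resolved toward heavier candidates):")
for u, v in sorted(result.linearization.adjacencies):
    print(f"  {u} -- {v}   weight {weights.get(u, v):g}")

# an uncoverable extremity makes the whole genome non-linearizable ...
broken = DegenerateGenome("Y", {"a": "a", "b": "b"})
broken.add_adjacency(Extremity("a", "h"), Extremity("b", "t"))
broken.add_adjacency(Extremity("a", "h"), Extremity("b", "h"))
print("\nY linearizable:", try_linearize(broken).feasible,
      " (extremity a^t sits in no candidate adjacency)")

# ... and safer augmentation always repairs it
augmented, delta = augment_safer(broken, telomere_weight=0.0)
print("after safer augmentation:", try_linearize(augmented).feasible,
      f"({len(list(delta.items()))} telomeric adjacencies added at weight 0)")
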