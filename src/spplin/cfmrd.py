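"""Capping-free comparison diagrams and DCJ-indel distances.

The Capping-Free Multi-Relational Diagram (CFMRD) of two genomes puts both
genome graphs side by side and adds *extremity edges* between homologous
marker extremities and *self edges* (the marker edge) for markers without a
homolog.  On a resolved homology -- one in which every marker is matched to
at most one marker of the other genome -- the diagram decomposes into simple
cycles and simple paths, and the DCJ-indel distance is a closed formula over
the component census:

    d = n - c + ceil((p_ab + max(p_Aa, p_aB) + max(p_Ab, p_Bb) - p_AB)/2) + s

with ``n`` matched markers, ``c`` cycles, ``s`` circular singletons, and the
``p_xy`` path counts keyed by their endpoints (uppercase: telomere, lowercase:
stop at a singular extremity; read from genome A to genome B).  For
unresolved homologies the distance is the minimum of this formula over all
*maximum* matchings of the family assignment.  This module implements the
diagram, the census, the closed formula, and two independent oracles: an
exhaustive enumeration over maximum matchings and a breadth-first search over
actual DCJ/indel operations (tiny instances only).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genomes import (
    HEAD,
    TAIL,
    DegenerateGenome,
    Extremity,
    Genome,
)

#: CFMRD vertices are genome-tagged extremities; tags are "A" and "B".
Vertex = tuple[str, Extremity]


class BudgetExceededError(RuntimeError):
    """An exhaustive oracle refused to run beyond its combinatorial budget."""


# ---------------------------------------------------------------------------
# diagram
# ---------------------------------------------------------------------------


@dataclass
class CFMRD:
    """Comparison diagram of one genome pair.

    ``ext_pairs`` groups the two sibling extremity edges of a candidate
    marker pairing, i.e. one entry per pair of homologous markers; the
    tail--tail and head--head edges of a pairing are always selected
    together.  ``self_markers`` lists the markers owning a self edge.
    """

    genome_a: DegenerateGenome
    genome_b: DegenerateGenome
    vertices: list[Vertex]
    ranks: dict[Vertex, int]
    adj_edges: list[tuple[Vertex, Vertex]]
    ext_pairs: list[tuple[str, str]]  # (marker id in A, marker id in B)
    self_markers: list[Vertex]  # tagged marker ids owning a self edge

    @property
    def n_self_edges(self) -> int:
        return len(self.self_markers)

    def size(self) -> int:
        """Vertices plus edges -- the size measure of the diagram."""
        return len(self.vertices) + len(self.adj_edges) + 2 * len(self.ext_pairs) + len(
            self.self_markers
        )

    def self_edge_vertices(self, tag_marker: Vertex) -> tuple[Vertex, Vertex]:
        tag, m = tag_marker
        return (tag, Extremity(m, TAIL)), (tag, Extremity(m, HEAD))


def build_cfmrd(
    genome_a: DegenerateGenome,
    genome_b: DegenerateGenome,
    self_edges: str = "singular",
) -> CFMRD:
    """Build the comparison diagram of ``genome_a`` (side A) vs ``genome_b``.

    Homology is taken from the family labels of the markers.  With
    ``self_edges="singular"`` only markers whose family is absent from the
    other genome receive a self edge (the plain diagram of the definition);
    with ``"all"`` every marker does, as required when the matching itself is
    subject to optimisation.

    Vertex ranks are deterministic: telomeres of A, telomeres of B,
    extremities of A, extremities of B, each block sorted.  Ranking all
    telomeres below all extremities pins the minimum-rank vertex of every
    cycle to an A-extremity and of every telomere-to-telomere path to a
    telomere, which the component-reporting constraints of the ILP rely on.
    """
    if self_edges not in ("singular", "all"):
        raise ValueError("self_edges must be 'singular' or 'all'")
    fams_a = genome_a.family_members()
    fams_b = genome_b.family_members()

    vertices: list[Vertex] = []
    vertices += [("A", t) for t in sorted(genome_a.telomeres)]
    vertices += [("B", t) for t in sorted(genome_b.telomeres)]
    vertices += [("A", e) for e in genome_a.extremities()]
    vertices += [("B", e) for e in genome_b.extremities()]
    ranks = {v: i for i, v in enumerate(vertices, start=1)}

    adj_edges: list[tuple[Vertex, Vertex]] = []
    for tag, g in (("A", genome_a), ("B", genome_b)):
        for u, v in sorted(g.adjacencies):
            adj_edges.append(((tag, u), (tag, v)))

    ext_pairs: list[tuple[str, str]] = []
    for fam, members_a in sorted(fams_a.items()):
        for ma in members_a:
            for mb in fams_b.get(fam, []):
                ext_pairs.append((ma, mb))

    self_markers: list[Vertex] = []
    for tag, g, other in (("A", genome_a, fams_b), ("B", genome_b, fams_a)):
        for fam, members in sorted(g.family_members().items()):
            if self_edges == "all" or fam not in other:
                self_markers.extend((tag, m) for m in members)

    return CFMRD(genome_a, genome_b, vertices, ranks, adj_edges, ext_pairs, self_markers)


# ---------------------------------------------------------------------------
# component census
# ---------------------------------------------------------------------------


@dataclass
class ComponentCensus:
    """Counts of CFMRD components under a resolved homology.

    Path labels are canonized reading from genome A to genome B; uppercase
    letters denote telomeric ends, lowercase ends stopping at a singular
    extremity.  ``p_AA``/``p_BB``/``p_aa``/``p_bb`` are counted for
    completeness but carry coefficient 0 in the distance formula.
    """

    n: int = 0
    c: int = 0
    s: int = 0
    p_ab: int = 0
    p_Aa: int = 0
    p_aB: int = 0
    p_Ab: int = 0
    p_Bb: int = 0
    p_AB: int = 0
    p_AA: int = 0
    p_BB: int = 0
    p_aa: int = 0
    p_bb: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


_PATH_FIELD = {
    frozenset(("A", "B")): "p_AB",
    frozenset(("a", "b")): "p_ab",
    frozenset(("A", "a")): "p_Aa",
    frozenset(("a", "B")): "p_aB",
    frozenset(("A", "b")): "p_Ab",
    frozenset(("B", "b")): "p_Bb",
    frozenset(("A",)): "p_AA",
    frozenset(("B",)): "p_BB",
    frozenset(("a",)): "p_aa",
    frozenset(("b",)): "p_bb",
}


def classify_components(
    vertices: Iterable[Vertex],
    adj_edges: Iterable[tuple[Vertex, Vertex]],
    ext_edges: Iterable[tuple[Vertex, Vertex]],
    self_edges: Iterable[tuple[Vertex, Vertex]],
) -> ComponentCensus:
    """Census of a resolved decomposition given explicit edge selections.

    ``adj_edges`` and ``ext_edges`` must each be a matching on the vertex
    set, ``self_edges`` pair tail/head of unmatched markers.  Matched
    markers are counted from tail--tail extremity edges.
    """
    vertices = list(vertices)
    vset = set(vertices)
    adj: dict[Vertex, Vertex] = {}
    ext: dict[Vertex, Vertex] = {}
    selfp: dict[Vertex, Vertex] = {}
    n = 0
    for table, edges in ((adj, adj_edges), (ext, ext_edges), (selfp, self_edges)):
        for u, v in edges:
            if u not in vset or v not in vset:
                raise ValueError(f"edge {u}-{v} leaves the vertex set")
            if u in table or v in table:
                raise ValueError(f"vertex covered twice in {u}-{v}: not a matching")
            table[u] = v
            table[v] = u
    for u, v in ext.items():
        if u[1].side == TAIL and v[1].side == TAIL and u < v:
            n += 1

    census = ComponentCensus(n=n)
    seen: set[Vertex] = set()

    for start in vertices:
        if start in seen:
            continue
        # collect the component over all three edge kinds
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            x = stack.pop()
            for table in (adj, ext, selfp):
                y = table.get(x)
                if y is not None and y not in seen:
                    seen.add(y)
                    comp.append(y)
                    stack.append(y)
        if len(comp) == 1 and start not in adj and start not in ext and start not in selfp:
            continue  # isolated vertex: no component
        # circular singleton: every vertex pairs one adjacency and one self
        # edge, no extremity edges involved
        if all(x in adj and x in selfp and x not in ext for x in comp):
            census.s += 1
            continue
        # ignore self edges; the remainder splits into cycles and paths
        sub_seen: set[Vertex] = set()
        for v0 in comp:
            if v0 in sub_seen or (v0 not in adj and v0 not in ext):
                continue
            sub = [v0]
            sub_seen.add(v0)
            stack = [v0]
            while stack:
                x = stack.pop()
                for table in (adj, ext):
                    y = table.get(x)
                    if y is not None and y not in sub_seen:
                        sub_seen.add(y)
                        sub.append(y)
                        stack.append(y)
            ends = [x for x in sub if (x in adj) + (x in ext) == 1]
            if not ends:
                census.c += 1
                continue
            assert len(ends) == 2, f"path with {len(ends)} endpoints"
            labels = [
                (tag if e.is_telomere else tag.lower()) for tag, e in ends
            ]
            key = frozenset(labels)
            setattr(census, _PATH_FIELD[key], getattr(census, _PATH_FIELD[key]) + 1)
    return census


def _matching_edges(
    genome_a: DegenerateGenome,
    genome_b: DegenerateGenome,
    matching: Sequence[tuple[str, str]],
) -> tuple[list[Vertex], list, list, list]:
    """Vertex/edge selections induced by a resolved matching."""
    matched_a = set()
    matched_b = set()
    for ma, mb in matching:
        if genome_a.families[ma] != genome_b.families[mb]:
            raise ValueError(f"matched markers {ma},{mb} are not homologous")
        if ma in matched_a or mb in matched_b:
            raise ValueError("homology is not resolved: marker matched twice")
        matched_a.add(ma)
        matched_b.add(mb)
    vertices: list[Vertex] = [("A", v) for v in genome_a.vertices()] + [
        ("B", v) for v in genome_b.vertices()
    ]
    adj = [(("A", u), ("A", v)) for u, v in genome_a.adjacencies] + [
        (("B", u), ("B", v)) for u, v in genome_b.adjacencies
    ]
    ext = []
    for ma, mb in matching:
        for side in (TAIL, HEAD):
            ext.append((("A", Extremity(ma, side)), ("B", Extremity(mb, side))))
    selfp = []
    for tag, g, matched in (("A", genome_a, matched_a), ("B", genome_b, matched_b)):
        for m in g.families:
            if m not in matched:
                selfp.append(((tag, Extremity(m, TAIL)), (tag, Extremity(m, HEAD))))
    return vertices, adj, ext, selfp


def census(
    genome_a: Genome,
    genome_b: Genome,
    matching: Sequence[tuple[str, str]],
) -> ComponentCensus:
    """Component census of the CFMRD under a resolved homology.

    ``matching`` lists matched marker-id pairs (A-side, B-side); every
    unmatched marker is treated as singular and receives a self edge.
    """
    return classify_components(*_matching_edges(genome_a, genome_b, matching))


def distance_resolved(cens: ComponentCensus) -> int:
    """DCJ-indel distance of a resolved homology from its component census."""
    q = math.ceil(
        (cens.p_ab + max(cens.p_Aa, cens.p_aB) + max(cens.p_Ab, cens.p_Bb) - cens.p_AB)
        / 2
    )
    d = cens.n - cens.c + q + cens.s
    assert d >= 0, f"negative distance from census {cens}"
    return d


# ---------------------------------------------------------------------------
# maximum-matching distance (exhaustive oracle)
# ---------------------------------------------------------------------------


def iter_maximum_matchings(
    genome_a: DegenerateGenome,
    genome_b: DegenerateGenome,
    budget: int = 1_000_000,
):
    """Yield every maximum matching of the family homology as pair lists.

    A maximum matching matches ``min(#copies in A, #copies in B)`` markers of
    every family.  Intended for tiny instances; raises
    :class:`BudgetExceededError` when the number of matchings exceeds
    ``budget``.
    """
    fams_a = genome_a.family_members()
    fams_b = genome_b.family_members()
    per_family: list[list[list[tuple[str, str]]]] = []
    total = 1
    for fam in sorted(set(fams_a) | set(fams_b)):
        la, lb = fams_a.get(fam, []), fams_b.get(fam, [])
        k = min(len(la), len(lb))
        if k == 0:
            continue
        options: list[list[tuple[str, str]]] = []
        if len(la) <= len(lb):
            for perm in itertools.permutations(lb, k):
                options.append(list(zip(la, perm)))
        else:
            for perm in itertools.permutations(la, k):
                options.append(list(zip(perm, lb)))
        total *= len(options)
        if total > budget:
            raise BudgetExceededError(
                f"more than {budget} maximum matchings; refusing exhaustive sweep"
            )
        per_family.append(options)
    for combo in itertools.product(*per_family):
        yield [pair for block in combo for pair in block]


def distance_max_matching(
    genome_a: Genome,
    genome_b: Genome,
    budget: int = 1_000_000,
) -> int:
    """DCJ-indel distance under the maximum matching model, by enumeration.

    This is the reference oracle for the ILP; it scans every maximum
    matching of the family homology and minimises the closed formula.
    """
    best: Optional[int] = None
    for matching in iter_maximum_matchings(genome_a, genome_b, budget=budget):
        d = distance_resolved(census(genome_a, genome_b, matching))
        if best is None or d < best:
            best = d
    if best is None:  # no family shared: still defined, all singular
        best = distance_resolved(census(genome_a, genome_b, []))
    return best


# ---------------------------------------------------------------------------
# BFS operation oracle
# ---------------------------------------------------------------------------

# states are canonical chromosome multisets over *family* labels:
#   (("C"|"L", ((fam, sign), ...)), ...) sorted


def _canon_linear(seq: tuple[tuple[str, int], ...]) -> tuple[tuple[str, int], ...]:
    rev = tuple((f, -s) for f, s in reversed(seq))
    return min(seq, rev)


def _canon_circular(seq: tuple[tuple[str, int], ...]) -> tuple[tuple[str, int], ...]:
    best = None
    for oriented in (seq, tuple((f, -s) for f, s in reversed(seq))):
        for i in range(len(oriented)):
            rot = oriented[i:] + oriented[:i]
            if best is None or rot < best:
                best = rot
    return best


def canonical_state(chromosomes: Iterable[tuple[str, Sequence[tuple[str, int]]]]):
    chroms = []
    for kind, content in chromosomes:
        seq = tuple(content)
        if not seq:
            continue
        if kind == "L":
            chroms.append(("L", _canon_linear(seq)))
        else:
            chroms.append(("C", _canon_circular(seq)))
    return tuple(sorted(chroms))


def genome_state(g: Genome):
    """Canonical BFS state of a genome (markers anonymised to families)."""
    return canonical_state(
        (kind[0].upper(), [(g.families[m], s) for m, s in content])
        for kind, content in g.chromosomes()
    )


def _family_counts(state) -> dict[str, int]:
    out: dict[str, int] = {}
    for _, seq in state:
        for fam, _ in seq:
            out[fam] = out.get(fam, 0) + 1
    return out


def _neighbors(state, target_counts: dict[str, int], matched_counts: dict[str, int]):
    """All states one DCJ or one indel away from ``state``.

    Indels only touch markers that are singular under the (maximum)
    matching: a block is deletable iff it uses only copies beyond the
    matched count of its families, and insertions only introduce copies of
    families still deficient w.r.t. the target's counts.
    """
    out = set()
    chroms = list(state)
    counts = _family_counts(state)

    def deletable(block) -> bool:
        need: dict[str, int] = {}
        for fam, _ in block:
            need[fam] = need.get(fam, 0) + 1
        return all(
            counts.get(fam, 0) - k >= matched_counts.get(fam, 0)
            for fam, k in need.items()
        )

    # --- indels: deletions of contiguous segments of singular markers ----
    for ci, (kind, seq) in enumerate(chroms):
        others = chroms[:ci] + chroms[ci + 1 :]
        k = len(seq)
        if kind == "L":
            for i in range(k):
                for j in range(i + 1, k + 1):
                    if not deletable(seq[i:j]):
                        continue
                    rest = seq[:i] + seq[j:]
                    new = others + ([("L", rest)] if rest else [])
                    out.add(canonical_state(new))
        else:
            if deletable(seq):  # whole circular chromosome
                out.add(canonical_state(others))
            for i in range(k):
                for length in range(1, k):
                    rot = seq[i:] + seq[:i]
                    if not deletable(rot[:length]):
                        continue
                    out.add(canonical_state(others + [("C", rot[length:])]))

    # --- indels: insertions of deficient material ------------------------
    deficit: list[str] = []
    for fam, want in target_counts.items():
        deficit.extend([fam] * max(0, want - counts.get(fam, 0)))
    segments = set()
    for r in range(1, len(deficit) + 1):
        for combo in itertools.permutations(deficit, r):
            for signs in itertools.product((1, -1), repeat=r):
                segments.add(tuple(zip(combo, signs)))
    for seg in segments:
        out.add(canonical_state(chroms + [("L", seg)]))
        out.add(canonical_state(chroms + [("C", seg)]))
        for ci, (kind, seq) in enumerate(chroms):
            others = chroms[:ci] + chroms[ci + 1 :]
            k = len(seq)
            positions = range(k + 1) if kind == "L" else range(k)
            for pos in positions:
                new_seq = seq[:pos] + seg + seq[pos:]
                out.add(canonical_state(others + [(kind, new_seq)]))

    # --- DCJs -------------------------------------------------------------
    # operate on the adjacency graph of an arbitrary concrete labelling
    adjacencies, telo_of, fam_of = _state_graph(chroms)
    items = sorted(adjacencies)
    for (p, q) in itertools.combinations(items, 2):
        (a, b), (c, d) = p, q
        for (u1, v1), (u2, v2) in (((a, c), (b, d)), ((a, d), (b, c))):
            new_adj = set(items)
            new_adj.discard(p)
            new_adj.discard(q)
            for u, v in ((u1, v1), (u2, v2)):
                if u in telo_of and v in telo_of:
                    continue  # telomere-telomere join: both ends vanish
                new_adj.add(frozenset((u, v)) if u != v else None)
            new_adj.discard(None)
            out.add(_graph_to_state(new_adj, telo_of, fam_of))
    # single cut creating two telomeres (fission into/out of linear pieces)
    for p in items:
        a, b = sorted(p, key=repr)
        if a in telo_of or b in telo_of:
            continue
        new_adj = set(items)
        new_adj.discard(p)
        new_adj.add(frozenset((a, ("T", a))))
        new_adj.add(frozenset((b, ("T", b))))
        telo2 = dict(telo_of)
        telo2[("T", a)] = True
        telo2[("T", b)] = True
        out.add(_graph_to_state(new_adj, telo2, fam_of))

    out.discard(canonical_state(chroms))
    return out


def _state_graph(chroms):
    """Concrete adjacency-set representation of a chromosome list."""
    adjacencies = set()
    telo_of: dict = {}
    fam_of: dict[int, str] = {}
    mid = 0
    for kind, seq in chroms:
        ends = []
        for fam, sign in seq:
            fam_of[mid] = fam
            tail, head = (mid, "t"), (mid, "h")
            first, last = (tail, head) if sign > 0 else (head, tail)
            ends.append(first)
            ends.append(last)
            mid += 1
        inner = ends[1:-1]
        for i in range(0, len(inner), 2):
            adjacencies.add(frozenset((inner[i], inner[i + 1])))
        if kind == "L":
            t1, t2 = ("T", ("l", mid, 0)), ("T", ("l", mid, 1))
            telo_of[t1] = telo_of[t2] = True
            adjacencies.add(frozenset((t1, ends[0])))
            adjacencies.add(frozenset((t2, ends[-1])))
        else:
            if len(seq) == 1:
                adjacencies.add(frozenset(ends))
            else:
                adjacencies.add(frozenset((ends[-1], ends[0])))
    return adjacencies, telo_of, fam_of


def _graph_to_state(adjacencies, telo_of, fam_of):
    partner: dict = {}
    for e in adjacencies:
        e = sorted(e, key=repr)
        if len(e) == 1:  # self-loop adjacency: one-marker circle
            u = v = e[0]
        else:
            u, v = e
        partner[u] = v
        partner[v] = u
    chroms = []
    seen_m: set[int] = set()
    seen_t: set = set()

    def other_side(x):
        return (x[0], "h" if x[1] == "t" else "t")

    for t in sorted((x for x in partner if x in telo_of), key=repr):
        if t in seen_t:
            continue
        seen_t.add(t)
        content = []
        cur = t
        while True:
            nxt = partner[cur]
            if nxt in telo_of:
                seen_t.add(nxt)
                break
            mid, side = nxt
            content.append((fam_of[mid], 1 if side == "t" else -1))
            seen_m.add(mid)
            cur = other_side(nxt)
        chroms.append(("L", tuple(content)))
    for mid in sorted(fam_of):
        if mid in seen_m or (mid, "t") not in partner:
            continue
        seen_m.add(mid)
        content = [(fam_of[mid], 1)]
        cur = (mid, "h")
        while True:
            nxt = partner[cur]
            if nxt[0] == mid:
                break
            content.append((fam_of[nxt[0]], 1 if nxt[1] == "t" else -1))
            seen_m.add(nxt[0])
            cur = other_side(nxt)
        chroms.append(("C", tuple(content)))
    return canonical_state(chroms)


def _bfs(start, goal, max_ops: int, state_budget: int) -> Optional[int]:
    """Bidirectional BFS between two states; None if beyond ``max_ops``."""
    if start == goal:
        return 0
    ca, cb = _family_counts(start), _family_counts(goal)
    matched = {
        fam: min(ca.get(fam, 0), cb.get(fam, 0)) for fam in set(ca) | set(cb)
    }
    targets = (cb, ca)
    fronts = [{start: 0}, {goal: 0}]
    frontiers = [{start}, {goal}]
    depths = [0, 0]
    explored = 0
    while depths[0] + depths[1] < max_ops:
        side = 0 if len(frontiers[0]) <= len(frontiers[1]) else 1
        new_frontier = set()
        for st in frontiers[side]:
            for nb in _neighbors(st, targets[side], matched):
                if nb in fronts[side]:
                    continue
                explored += 1
                if explored > state_budget:
                    raise BudgetExceededError("BFS oracle state budget exceeded")
                fronts[side][nb] = depths[side] + 1
                new_frontier.add(nb)
        depths[side] += 1
        frontiers[side] = new_frontier
        meet = new_frontier & set(fronts[1 - side])
        if meet:
            return min(fronts[side][m] + fronts[1 - side][m] for m in meet)
        if not new_frontier:
            break
    return None


def _relabeled_states(genome_a: Genome, genome_b: Genome, matching):
    """States of both genomes under a fixed resolved matching.

    Matched pairs share a private label; unmatched markers get a
    family+genome label, so indel moves can only ever touch markers that
    are singular under this matching.
    """
    label: dict[tuple[str, str], str] = {}
    for i, (ma, mb) in enumerate(matching):
        label[("A", ma)] = label[("B", mb)] = f"p{i}"
    states = []
    for tag, g in (("A", genome_a), ("B", genome_b)):
        chroms = []
        for kind, content in g.chromosomes():
            seq = [
                (
                    label.get((tag, m), f"{g.families[m]}.{tag.lower()}"),
                    s,
                )
                for m, s in content
            ]
            chroms.append((kind[0].upper(), seq))
        states.append(canonical_state(chroms))
    return states


def bfs_operation_oracle(
    genome_a: Genome,
    genome_b: Genome,
    max_ops: int = 4,
    state_budget: int = 400_000,
    matching_budget: int = 10_000,
) -> int:
    """Minimum number of DCJ/indel operations turning A into B, by search.

    Implements the maximum matching model operationally: for every maximum
    matching of the family homology, a bidirectional breadth-first search
    counts the fewest DCJ and indel moves that turn A into B with the
    matching held fixed (matched markers are conserved; indels only touch
    markers singular under the matching); the minimum over matchings is
    returned.  Genomes are compared up to marker renaming.  Only for tiny
    instances; raises :class:`BudgetExceededError` when no scenario with at
    most ``max_ops`` operations is certified or a search budget is hit.
    """
    best: Optional[int] = None
    for matching in iter_maximum_matchings(
        genome_a, genome_b, budget=matching_budget
    ):
        start, goal = _relabeled_states(genome_a, genome_b, matching)
        d = _bfs(start, goal, max_ops, state_budget)
        if d is not None and (best is None or d < best):
            best = d
            if best == 0:
                break
    if best is None:
        raise BudgetExceededError(
            f"no scenario with at most {max_ops} operations found"
        )
    return best
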