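"""Genome graphs, degenerate genomes, phylogenies and on-disk formats.

A genome is modelled as a graph on marker extremities and telomeres: marker
edges pair the tail and head of each marker, adjacency edges pair neighbouring
extremities.  In a proper genome the adjacency edges form a perfect matching
on extremities plus telomeres, so connected components are exactly linear
chromosomes (paths between two telomeres) and circular chromosomes (cycles).
A *degenerate* genome drops the matching requirement on adjacencies: an
extremity may sit in zero, one or many candidate adjacencies.  Degenerate
genomes encode uncertainty about ancestral gene orders.

Markers carry a *family* label; two markers are homologous iff their family
labels coincide.  Marker identifiers are unique within a genome; cross-genome
ambiguity is resolved by tagging vertices with their genome wherever two
genomes meet (see :mod:`spplin.cfmrd`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional

TAIL = "t"
HEAD = "h"
TELO = "o"


class Extremity(NamedTuple):
    """One end of a marker (side ``t``/``h``) or a telomere (side ``o``)."""

    marker: str
    side: str

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.marker}^{self.side}"

    @property
    def is_telomere(self) -> bool:
        return self.side == TELO

    def sibling(self) -> "Extremity":
        """The other extremity of the same marker."""
        if self.side == TELO:
            raise ValueError("telomeres have no sibling extremity")
        return Extremity(self.marker, HEAD if self.side == TAIL else TAIL)


#: An adjacency is an unordered pair of extremities, stored sorted.
Adjacency = tuple[Extremity, Extremity]


def adjacency(u: Extremity, v: Extremity) -> Adjacency:
    """Canonical (order-insensitive) key for the adjacency ``{u, v}``."""
    return (u, v) if u <= v else (v, u)


class GenomeError(ValueError):
    """Raised when a genome violates its structural invariants."""


class ParseError(ValueError):
    """Raised on malformed input files; mentions the offending line."""


class DegenerateGenome:
    """A set of markers plus an arbitrary set of candidate adjacencies.

    Parameters
    ----------
    name:
        Genome label (phylogeny node name).
    families:
        Mapping ``marker id -> family label``.
    adjacencies:
        Iterable of extremity pairs.  Telomere--telomere pairs are rejected.
    telomeres:
        Telomeric extremities.  Telomeres mentioned in ``adjacencies`` are
        added automatically.
    """

    def __init__(
        self,
        name: str,
        families: dict[str, str],
        adjacencies: Iterable[tuple[Extremity, Extremity]] = (),
        telomeres: Iterable[Extremity] = (),
    ) -> None:
        self.name = name
        self.families = dict(families)
        self.telomeres: set[Extremity] = set(telomeres)
        self.adjacencies: set[Adjacency] = set()
        for u, v in adjacencies:
            self.add_adjacency(u, v)
        for t in self.telomeres:
            if not t.is_telomere:
                raise GenomeError(f"{t} registered as telomere but has side {t.side}")

    # -- construction -----------------------------------------------------
    def add_adjacency(self, u: Extremity, v: Extremity) -> Adjacency:
        if u.is_telomere and v.is_telomere:
            raise GenomeError(f"adjacency {u}-{v} joins two telomeres")
        if u == v:
            raise GenomeError(f"adjacency {u}-{v} is a loop")
        for w in (u, v):
            if w.is_telomere:
                self.telomeres.add(w)
            elif w.marker not in self.families:
                raise GenomeError(f"adjacency endpoint {w} references unknown marker")
        adj = adjacency(u, v)
        self.adjacencies.add(adj)
        return adj

    # -- derived sets ------------------------------------------------------
    def extremities(self) -> list[Extremity]:
        """All marker extremities E(D), sorted."""
        out = []
        for m in self.families:
            out.append(Extremity(m, TAIL))
            out.append(Extremity(m, HEAD))
        return sorted(out)

    def vertices(self) -> list[Extremity]:
        return sorted(self.extremities() + sorted(self.telomeres))

    def marker_edges(self) -> list[tuple[Extremity, Extremity]]:
        return [
            (Extremity(m, TAIL), Extremity(m, HEAD)) for m in sorted(self.families)
        ]

    def degree(self, v: Extremity) -> int:
        return sum(1 for a in self.adjacencies if v in a)

    def family_members(self) -> dict[str, list[str]]:
        """Family label -> sorted marker ids of that family in this genome."""
        out: dict[str, list[str]] = {}
        for m, f in self.families.items():
            out.setdefault(f, []).append(m)
        for ms in out.values():
            ms.sort()
        return out

    @property
    def is_degenerate(self) -> bool:
        """True unless the adjacencies form a perfect matching on E u T."""
        try:
            self._check_matching()
        except GenomeError:
            return True
        return False

    def _check_matching(self) -> None:
        deg: dict[Extremity, int] = {v: 0 for v in self.extremities()}
        for t in self.telomeres:
            deg[t] = 0
        for u, v in self.adjacencies:
            deg[u] += 1
            deg[v] += 1
        for v, d in deg.items():
            if d != 1:
                raise GenomeError(
                    f"extremity {v} of genome {self.name} lies in {d} adjacencies"
                )

    def copy(self) -> "DegenerateGenome":
        return DegenerateGenome(
            self.name, self.families, self.adjacencies, self.telomeres
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<{type(self).__name__} {self.name}: {len(self.families)} markers, "
            f"{len(self.adjacencies)} adjacencies, {len(self.telomeres)} telomeres>"
        )


class Genome(DegenerateGenome):
    """A proper genome: adjacencies are a perfect matching on E u T.

    Connected components of the genome graph are simple paths (linear
    chromosomes, both ends telomeric) or simple cycles (circular
    chromosomes); this is validated on construction.
    """

    def __init__(self, *args, **kwargs) -> None:
        super().__init__(*args, **kwargs)
        self.validate()

    def validate(self) -> None:
        self._check_matching()
        # Matching on E u T together with the marker perfect matching already
        # implies path/cycle components; verify telomere bookkeeping anyway.
        n_lin = sum(1 for a in self.adjacencies for w in a if w.is_telomere)
        if n_lin != len(self.telomeres):
            raise GenomeError(
                f"genome {self.name}: {len(self.telomeres)} telomeres but "
                f"{n_lin} telomeric adjacency endpoints"
            )

    # -- chromosome traversal ---------------------------------------------
    def chromosomes(self) -> list[tuple[str, list[tuple[str, int]]]]:
        """Decompose into chromosomes.

        Returns a list of ``(kind, content)`` with ``kind`` ``"linear"`` or
        ``"circular"`` and ``content`` a list of ``(marker id, sign)`` read
        along the chromosome.
        """
        partner: dict[Extremity, Extremity] = {}
        for u, v in self.adjacencies:
            partner[u] = v
            partner[v] = u
        seen: set[str] = set()
        out: list[tuple[str, list[tuple[str, int]]]] = []

        def walk(
            start: Extremity, start_marker: Optional[str]
        ) -> tuple[str, list[tuple[str, int]], Optional[Extremity]]:
            content: list[tuple[str, int]] = []
            cur = start
            while True:
                nxt = partner[cur]
                if nxt.is_telomere:
                    return "linear", content, nxt
                if start_marker is not None and nxt.marker == start_marker:
                    return "circular", content, None
                # entering marker nxt.marker through extremity nxt
                sign = 1 if nxt.side == TAIL else -1
                content.append((nxt.marker, sign))
                seen.add(nxt.marker)
                cur = nxt.sibling()

        # linear chromosomes: start at telomeres
        done_telo: set[Extremity] = set()
        for t in sorted(self.telomeres):
            if t in done_telo:
                continue
            kind, content, end = walk(t, None)
            out.append((kind, content))
            done_telo.add(t)
            if end is not None:
                done_telo.add(end)
        # circular chromosomes: remaining markers
        for m in sorted(self.families):
            if m in seen:
                continue
            seen.add(m)
            _, rest, _ = walk(Extremity(m, HEAD), m)
            out.append(("circular", [(m, 1)] + rest))
        return out

    def copy(self) -> "Genome":
        return Genome(self.name, self.families, self.adjacencies, self.telomeres)


# ---------------------------------------------------------------------------
# adjacency weights
# ---------------------------------------------------------------------------


class AdjacencyWeights:
    """Order-insensitive weights for candidate adjacencies."""

    def __init__(self, default: float = 0.0) -> None:
        self.default = default
        self._w: dict[Adjacency, float] = {}

    def set(self, u: Extremity, v: Extremity, weight: float) -> None:
        self._w[adjacency(u, v)] = weight

    def get(self, u: Extremity, v: Extremity | None = None) -> float:
        adj = u if v is None else adjacency(u, v)
        return self._w.get(adj, self.default)

    def items(self) -> Iterator[tuple[Adjacency, float]]:
        return iter(self._w.items())

    def copy(self) -> "AdjacencyWeights":
        out = AdjacencyWeights(self.default)
        out._w = dict(self._w)
        return out


# ---------------------------------------------------------------------------
# family bounds
# ---------------------------------------------------------------------------


@dataclass
class FamilyBounds:
    """Per-genome, per-family bounds (L, H) on ancestral marker counts.

    Unspecified families default to ``L = H = `` the number of candidate
    copies, i.e. every candidate marker of the family must occur.
    """

    bounds: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def set(self, genome: str, family: str, low: int, high: int) -> None:
        if not 0 <= low <= high:
            raise ValueError(f"invalid bounds ({low}, {high}) for {genome}/{family}")
        self.bounds[(genome, family)] = (low, high)

    def get(self, genome: DegenerateGenome, family: str) -> tuple[int, int]:
        n = len(genome.family_members().get(family, []))
        low, high = self.bounds.get((genome.name, family), (n, n))
        if high > n:
            raise ValueError(
                f"bounds for {genome.name}/{family} exceed the {n} candidate copies"
            )
        return low, high


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted tree with uniquely named nodes bound to (degenerate) genomes."""

    def __init__(
        self,
        edges: list[tuple[str, str]],
        root: str,
        branch_lengths: Optional[dict[tuple[str, str], float]] = None,
    ) -> None:
        self.edges = list(edges)
        self.root = root
        self.branch_lengths = dict(branch_lengths or {})
        self.genomes: dict[str, DegenerateGenome] = {}
        children: dict[str, list[str]] = {}
        parents: dict[str, str] = {}
        names = {root}
        for p, c in edges:
            children.setdefault(p, []).append(c)
            if c in parents:
                raise ValueError(f"node {c} has two parents")
            parents[c] = p
            names.add(p)
            names.add(c)
        self.children = children
        self.parents = parents
        self.nodes = sorted(names)
        self.leaves = sorted(n for n in names if n not in children)
        self.internal = sorted(n for n in names if n in children)

    def bind(self, genome: DegenerateGenome) -> None:
        if genome.name not in set(self.nodes):
            raise ValueError(f"no tree node named {genome.name}")
        self.genomes[genome.name] = genome

    def genome(self, name: str) -> DegenerateGenome:
        try:
            return self.genomes[name]
        except KeyError:
            raise ValueError(f"node {name} carries no genome") from None

    def validate_bindings(self) -> None:
        for n in self.nodes:
            g = self.genome(n)
            if n in self.leaves and g.is_degenerate:
                raise GenomeError(f"leaf {n} carries a degenerate genome")

    def path_edges(self, a: str, b: str) -> list[tuple[str, str]]:
        """Tree edges on the unique path between nodes ``a`` and ``b``."""

        def ancestors(x: str) -> list[str]:
            out = [x]
            while x in self.parents:
                x = self.parents[x]
                out.append(x)
            return out

        anc_a, anc_b = ancestors(a), ancestors(b)
        common = next(x for x in anc_a if x in set(anc_b))
        path = anc_a[: anc_a.index(common)] + anc_b[: anc_b.index(common)]
        edges = set()
        for x in path:
            edges.add((self.parents[x], x))
        return sorted(edges)


# ---------------------------------------------------------------------------
# UniMoG-style genome files
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"^[+-]?[^|)\s]+$")


def parse_unimog(text: str) -> list[Genome]:
    """Parse genomes written as signed marker sequences.

    Format: ``>name`` headers start a genome; chromosomes are whitespace
    separated signed family names terminated by ``|`` (linear) or ``)``
    (circular).  The k-th occurrence of a family name *across the whole
    file* becomes marker ``family_k``, so homologous copies get distinct,
    stable identifiers.
    """
    genomes: list[Genome] = []
    occurrence: dict[str, int] = {}

    name: Optional[str] = None
    families: dict[str, str] = {}
    adjacencies: list[tuple[Extremity, Extremity]] = []
    telomeres: list[Extremity] = []
    chrom: list[tuple[str, int]] = []
    n_telo = 0
    seen_names: set[str] = set()

    def telomere() -> Extremity:
        nonlocal n_telo
        n_telo += 1
        return Extremity(f"t{n_telo}", TELO)

    def flush_chromosome(kind: str, lineno: int) -> None:
        nonlocal chrom
        if not chrom:
            raise ParseError(f"line {lineno}: empty chromosome")
        ends: list[Extremity] = []
        for fam, sign in chrom:
            occurrence[fam] = occurrence.get(fam, 0) + 1
            mid = f"{fam}_{occurrence[fam]}"
            families[mid] = fam
            first = Extremity(mid, TAIL if sign > 0 else HEAD)
            last = Extremity(mid, HEAD if sign > 0 else TAIL)
            ends.append(first)
            ends.append(last)
        inner = ends[1:-1]
        for i in range(0, len(inner), 2):
            adjacencies.append((inner[i], inner[i + 1]))
        if kind == "linear":
            for e in (ends[0], ends[-1]):
                t = telomere()
                telomeres.append(t)
                adjacencies.append((t, e))
        else:
            adjacencies.append((ends[-1], ends[0]))
        chrom = []

    def flush_genome(lineno: int) -> None:
        nonlocal families, adjacencies, telomeres, n_telo
        if name is None:
            return
        if chrom:
            raise ParseError(
                f"line {lineno}: chromosome of genome {name} lacks a "
                "terminator ('|' or ')')"
            )
        genomes.append(Genome(name, families, adjacencies, telomeres))
        families, adjacencies, telomeres, n_telo = {}, [], [], 0

    lineno = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush_genome(lineno)
            name = line[1:].strip()
            if not name:
                raise ParseError(f"line {lineno}: empty genome name")
            if name in seen_names:
                raise ParseError(f"line {lineno}: duplicate genome name {name!r}")
            seen_names.add(name)
            continue
        if name is None:
            raise ParseError(f"line {lineno}: marker data before any '>' header")
        for tok in line.split():
            if tok == "|":
                flush_chromosome("linear", lineno)
            elif tok == ")":
                flush_chromosome("circular", lineno)
            elif _TOKEN.match(tok):
                sign = -1 if tok.startswith("-") else 1
                fam = tok.lstrip("+-")
                if not fam:
                    raise ParseError(f"line {lineno}: bad marker token {tok!r}")
                chrom.append((fam, sign))
            else:
                raise ParseError(f"line {lineno}: bad token {tok!r}")
    flush_genome(lineno)
    if not genomes:
        raise ParseError("no genomes found")
    return genomes


def write_unimog(genomes: Iterable[Genome]) -> str:
    """Serialize genomes; inverse of :func:`parse_unimog` up to copy renaming."""
    lines: list[str] = []
    for g in genomes:
        lines.append(f">{g.name}")
        for kind, content in g.chromosomes():
            toks = [
                (fam if sign > 0 else f"-{fam}")
                for fam, sign in ((g.families[m], s) for m, s in content)
            ]
            toks.append("|" if kind == "linear" else ")")
            lines.append(" ".join(toks))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# candidate-adjacency tables
# ---------------------------------------------------------------------------


def parse_adjacency_table(
    text: str, default_weight: float = 0.0
) -> tuple[dict[str, DegenerateGenome], AdjacencyWeights]:
    """Parse a TSV of candidate ancestral adjacencies.

    Columns: ``genome  marker1  side1  marker2  side2  [weight]`` with sides
    in ``{t, h, o}``; side ``o`` denotes a telomere (a fresh telomeric
    extremity is created per row).  ``#`` starts a comment; a header line is
    recognised by a non-side token in column 3.  Marker families are taken
    as the marker name up to a final ``_copy`` suffix.
    """
    weights = AdjacencyWeights(default_weight)
    rows: dict[str, list[tuple[Extremity, Extremity, float]]] = {}
    fams: dict[str, dict[str, str]] = {}
    n_telo: dict[str, int] = {}

    def family_of(marker: str) -> str:
        base, _, copy = marker.rpartition("_")
        if base and copy.isdigit():
            return base
        return marker

    first_data = True
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) not in (5, 6, 7):
            raise ParseError(f"line {lineno}: expected 5-7 columns, got {len(parts)}")
        gname, m1, s1, m2, s2 = parts[:5]
        if first_data:
            first_data = False
            if s1 not in (TAIL, HEAD, TELO) and s2 not in (TAIL, HEAD, TELO):
                continue  # header
        for s in (s1, s2):
            if s not in (TAIL, HEAD, TELO):
                raise ParseError(f"line {lineno}: unknown side code {s!r}")
        if s1 == TELO and s2 == TELO:
            raise ParseError(f"line {lineno}: adjacency joins two telomeres")
        w = default_weight
        if len(parts) >= 6:
            try:
                w = float(parts[5])
            except ValueError:
                raise ParseError(f"line {lineno}: bad weight {parts[5]!r}") from None
        rows.setdefault(gname, [])
        fams.setdefault(gname, {})
        exts = []
        for m, s in ((m1, s1), (m2, s2)):
            if s == TELO:
                n_telo[gname] = n_telo.get(gname, 0) + 1
                exts.append(Extremity(f"t{n_telo[gname]}", TELO))
            else:
                fams[gname][m] = family_of(m)
                exts.append(Extremity(m, s))
        rows[gname].append((exts[0], exts[1], w))

    out: dict[str, DegenerateGenome] = {}
    for gname, entries in rows.items():
        d = DegenerateGenome(gname, fams[gname])
        for u, v, w in entries:
            adj = d.add_adjacency(u, v)
            weights._w[adj] = w
        out[gname] = d
    return out, weights


def write_adjacency_table(
    genomes: Iterable[DegenerateGenome], weights: Optional[AdjacencyWeights] = None
) -> str:
    lines = ["#genome\tmarker1\tside1\tmarker2\tside2\tweight"]
    for g in genomes:
        for u, v in sorted(g.adjacencies):
            w = weights.get(u, v) if weights is not None else 0.0
            lines.append(
                f"{g.name}\t{u.marker}\t{u.side}\t{v.marker}\t{v.side}\t{w:g}"
            )
    return "\n".join(lines) + "\n"


def parse_family_bounds(text: str) -> FamilyBounds:
    """Parse a TSV ``genome  family  low  high`` of copy-number bounds."""
    fb = FamilyBounds()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"line {lineno}: expected 4 columns")
        g, f, lo, hi = parts
        try:
            fb.set(g, f, int(lo), int(hi))
        except ValueError as e:
            raise ParseError(f"line {lineno}: {e}") from None
    return fb


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick tree whose internal nodes are all labeled."""
    import dendropy

    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=False,
        suppress_leaf_node_taxa=False,
    )
    # drop redundant unlabeled unary wrappers such as "((A,B)F)Root;"
    tree.suppress_unifurcations()

    def label(node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        if node.label:
            return node.label
        raise ParseError("unlabeled internal node in Newick tree")

    edges: list[tuple[str, str]] = []
    lengths: dict[tuple[str, str], float] = {}
    root = tree.seed_node
    # collapse a redundant unifurcation at the root (e.g. "((...)X)Root;")
    for node in tree.preorder_node_iter():
        p = node.parent_node
        if p is None:
            continue
        e = (label(p), label(node))
        edges.append(e)
        if node.edge.length is not None:
            lengths[e] = float(node.edge.length)
    names = [label(n) for n in tree.preorder_node_iter()]
    if len(set(names)) != len(names):
        raise ParseError("duplicate node labels in Newick tree")
    return Phylogeny(edges, root=label(root), branch_lengths=lengths)
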