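"""Polynomial-size ILP for the weighted small parsimony linearization problem.

Given a phylogeny whose nodes carry (degenerate) genomes, the ILP
simultaneously picks a linearization of every node's candidate adjacency set
(*global level*) and a DCJ-indel-optimal decomposition of the comparison
diagram (CFMRD) of every tree edge (*local level*), minimising

    sum over tree edges E of ( alpha * f_E  -  (1 - alpha) * w_E )

where ``f_E`` is the DCJ-indel distance of the branch under the maximum
matching model and ``w_E`` the total weight of the adjacencies selected at
the branch's two endpoint genomes.

The local level assembles the distance formula

    f = n - c + ceil((p_ab + max(p_Aa,p_aB) + max(p_Ab,p_Bb) - p_AB)/2) + s

from component reports: cycles and AB-paths are claimed through a
rank/potential mechanism (a component may report at most once, at its
minimum-rank vertex), path classes involving indel ends are forced through
a genome-side label ``l`` that must flip somewhere along every mixed path,
and circular singletons are either enumerated explicitly or counted through
an orientation/potential gadget of constant size per vertex -- keeping the
whole program linear in the total size of all comparison diagrams.

Vertex ranks place telomeres of both genomes before marker extremities
(T(A), T(B), E(A), E(B)): the minimum-rank vertex of a cycle is then always
an A-extremity and that of a telomere path a telomere, which pins each
component's report to a vertex class that cannot misreport.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .cfmrd import (
    CFMRD,
    ComponentCensus,
    Vertex,
    build_cfmrd,
    classify_components,
    distance_resolved,
)
from .genomes import (
    HEAD,
    TAIL,
    Adjacency,
    AdjacencyWeights,
    DegenerateGenome,
    Extremity,
    FamilyBounds,
    Genome,
    Phylogeny,
)
from .milp import Model, Variable


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass
class EdgeContext:
    """Bookkeeping of the local level of one tree edge."""

    index: int
    parent: str
    child: str
    cfmrd: CFMRD
    pair_vars: dict[tuple[str, str], Variable] = field(default_factory=dict)
    self_vars: dict[Vertex, Variable] = field(default_factory=dict)
    y: dict[Vertex, Variable] = field(default_factory=dict)
    z: dict[Vertex, Variable] = field(default_factory=dict)
    l: dict[Vertex, Variable] = field(default_factory=dict)
    reports: dict[str, dict[Vertex, Variable]] = field(default_factory=dict)
    f_var: Optional[Variable] = None
    w_var: Optional[Variable] = None
    counters: dict[str, Variable] = field(default_factory=dict)
    singleton_mode: str = "none"
    singleton_candidates: list[tuple[Variable, list[Variable]]] = field(
        default_factory=list
    )
    gadget_vars: dict[str, dict] = field(default_factory=dict)


@dataclass
class SppModel:
    """The assembled ILP plus the mappings needed to decode a solution."""

    model: Model
    phylogeny: Phylogeny
    alpha: float
    weights: AdjacencyWeights
    bounds: FamilyBounds
    g_vars: dict[str, dict[Extremity, Variable]] = field(default_factory=dict)
    adj_vars: dict[str, dict[Adjacency, Variable]] = field(default_factory=dict)
    edges: list[EdgeContext] = field(default_factory=list)
    extra_constraints: list[str] = field(default_factory=list)
    beta_emulation: Optional[float] = None


@dataclass
class Solution:
    """Decoded result: one proper genome per node, one distance per branch."""

    linearizations: dict[str, Genome]
    distances: dict[tuple[str, str], int]
    objective: float
    status: str
    gap: Optional[float]
    censuses: dict[tuple[str, str], ComponentCensus] = field(default_factory=dict)
    assignment: Optional[dict[str, float]] = None


# ---------------------------------------------------------------------------
# global level
# ---------------------------------------------------------------------------


def emit_global(spp: SppModel) -> None:
    """Presence variables, copy-number bounds and the one-adjacency-per-
    extremity rule for every node of the phylogeny."""
    m = spp.model
    for node in spp.phylogeny.nodes:
        genome = spp.phylogeny.genome(node)
        g: dict[Extremity, Variable] = {}
        a: dict[Adjacency, Variable] = {}
        spp.g_vars[node] = g
        spp.adj_vars[node] = a
        for v in genome.vertices():
            g[v] = m.binary(f"g|{node}|{v.marker}|{v.side}")
        for adj in sorted(genome.adjacencies):
            u, w = adj
            a[adj] = m.binary(f"a|{node}|{u.marker}.{u.side}|{w.marker}.{w.side}")
        # head present iff tail present; copy-number bounds per family
        members = genome.family_members()
        for fam, ms in sorted(members.items()):
            low, high = spp.bounds.get(genome, fam)
            if low == high == len(ms):
                for mk in ms:
                    m.fix(g[Extremity(mk, TAIL)], 1)
                    m.fix(g[Extremity(mk, HEAD)], 1)
            else:
                m.add_constr(
                    f"copy_bounds|{node}|{fam}",
                    {g[Extremity(mk, TAIL)]: 1 for mk in ms},
                    low,
                    high,
                )
            for mk in ms:
                t, h = g[Extremity(mk, TAIL)], g[Extremity(mk, HEAD)]
                if not (t.lb == t.ub and h.lb == h.ub):
                    m.add_constr(f"marker_whole|{node}|{mk}", {t: 1, h: -1}, 0, 0)
        # every present extremity/telomere sits in exactly one adjacency
        incident: dict[Extremity, list[Variable]] = {v: [] for v in g}
        for adj, var in a.items():
            incident[adj[0]].append(var)
            incident[adj[1]].append(var)
        for v in genome.vertices():
            terms = {var: 1.0 for var in incident[v]}
            terms[g[v]] = terms.get(g[v], 0.0) - 1.0
            m.add_constr(f"one_adjacency|{node}|{v.marker}.{v.side}", terms, 0, 0)
        if node in spp.phylogeny.leaves:
            # leaves are fixed genomes: presolve the forced selection
            for var in a.values():
                m.fix(var, 1)
            for var in g.values():
                m.fix(var, 1)


# ---------------------------------------------------------------------------
# local level
# ---------------------------------------------------------------------------


def _adj_var(spp: SppModel, ctx: EdgeContext, u: Vertex, v: Vertex) -> Variable:
    """Global selection variable behind an adjacency edge of the CFMRD
    (selection inheritance realised by variable identity)."""
    node = ctx.parent if u[0] == "A" else ctx.child
    key = (u[1], v[1]) if u[1] <= v[1] else (v[1], u[1])
    return spp.adj_vars[node][key]


def _g_var(spp: SppModel, ctx: EdgeContext, v: Vertex) -> Variable:
    node = ctx.parent if v[0] == "A" else ctx.child
    return spp.g_vars[node][v[1]]


def _dropped_self_sides(spp: SppModel, ctx: EdgeContext) -> dict[str, set[str]]:
    """Per family, the genome sides whose self edges are removed because the
    copy-number bounds determine which side is overrepresented."""
    ga = spp.phylogeny.genome(ctx.parent)
    gb = spp.phylogeny.genome(ctx.child)
    fams_a = ga.family_members()
    fams_b = gb.family_members()
    dropped: dict[str, set[str]] = {}
    for fam in set(fams_a) & set(fams_b):
        low_a, high_a = spp.bounds.get(ga, fam)
        low_b, high_b = spp.bounds.get(gb, fam)
        drop: set[str] = set()
        if low_a >= high_b:
            drop.add("B")
        if low_b >= high_a:
            drop.add("A")
        if drop:
            dropped[fam] = drop
    return dropped


def emit_local(spp: SppModel, ctx: EdgeContext) -> None:
    """Decomposition variables and component-reporting constraints for the
    comparison diagram of one tree edge."""
    m = spp.model
    R = ctx.cfmrd
    k = ctx.index
    ranks = R.ranks
    ga = R.genome_a
    gb = R.genome_b
    genome_of = {"A": ga, "B": gb}

    dropped = _dropped_self_sides(spp, ctx)
    kept_self = [
        (tag, mk)
        for tag, mk in R.self_markers
        if tag not in dropped.get(genome_of[tag].families[mk], set())
    ]

    # --- selection variables -------------------------------------------
    for ma, mb in R.ext_pairs:
        ctx.pair_vars[(ma, mb)] = m.binary(f"x|{k}|pair|{ma}|{mb}")
    for tag, mk in kept_self:
        ctx.self_vars[(tag, mk)] = m.binary(f"x|{k}|self|{tag}|{mk}")

    # coverage: each present extremity is matched or uses its self edge;
    # the tail/head sibling edges of a marker pairing share one variable,
    # so one constraint per marker covers both extremities (sibling
    # consistency holds structurally)
    pairs_of: dict[Vertex, list[Variable]] = {}
    for (ma, mb), var in ctx.pair_vars.items():
        pairs_of.setdefault(("A", ma), []).append(var)
        pairs_of.setdefault(("B", mb), []).append(var)
    for tag, g in (("A", ga), ("B", gb)):
        for mk in sorted(g.families):
            terms: dict[Variable, float] = {}
            for var in pairs_of.get((tag, mk), []):
                terms[var] = 1.0
            sv = ctx.self_vars.get((tag, mk))
            if sv is not None:
                terms[sv] = 1.0
            gv = _g_var(spp, ctx, (tag, Extremity(mk, TAIL)))
            terms[gv] = terms.get(gv, 0.0) - 1.0
            m.add_constr(f"cover|{k}|{tag}|{mk}", terms, 0, 0)

    # per family, self edges may rest in only one of the two genomes
    fams_self: dict[str, dict[str, list[Variable]]] = {}
    for (tag, mk), var in ctx.self_vars.items():
        fam = genome_of[tag].families[mk]
        fams_self.setdefault(fam, {}).setdefault(tag, []).append(var)
    for fam, sides in sorted(fams_self.items()):
        if len(sides) < 2:
            continue
        b = m.binary(f"b|{k}|{fam}")
        for var in sides["A"]:
            m.add_constr(f"self_side_a|{k}|{fam}|{var.name}", {var: 1, b: -1}, ub=0)
        for var in sides["B"]:
            m.add_constr(f"self_side_b|{k}|{fam}|{var.name}", {var: 1, b: 1}, ub=1)

    # --- per-vertex variables -------------------------------------------
    vname = {v: f"{v[0]}|{v[1].marker}|{v[1].side}" for v in R.vertices}
    for v in R.vertices:
        ctx.y[v] = m.add_var(f"y|{k}|{vname[v]}", 0, ranks[v], True)
        ctx.z[v] = m.binary(f"z|{k}|{vname[v]}")
        lv = m.binary(f"l|{k}|{vname[v]}")
        ctx.l[v] = lv
        if v[1].is_telomere:
            m.fix(lv, 0 if v[0] == "A" else 1)
        # only vertices of the linearized genomes may claim components
        m.add_constr(f"claim_present|{k}|{vname[v]}", {ctx.z[v]: 1, _g_var(spp, ctx, v): -1}, ub=0)
        # a claim requires the potential to reach the vertex's own rank
        m.add_constr(
            f"claim_rank|{k}|{vname[v]}", {ctx.z[v]: ranks[v], ctx.y[v]: -1}, ub=0
        )

    # --- report variables -----------------------------------------------
    reports: dict[str, dict[Vertex, Variable]] = {
        key: {} for key in ("c", "ab", "Aa", "Ab", "AB", "aB", "Bb")
    }
    ctx.reports = reports
    for v in R.vertices:
        tag, ext = v
        if ext.is_telomere:
            if tag == "A":
                for key in ("Aa", "Ab", "AB"):
                    reports[key][v] = m.binary(f"r{key}|{k}|{vname[v]}")
                # an AB claim follows the cycle-claim mechanism
                m.add_constr(
                    f"claim_AB|{k}|{vname[v]}",
                    {reports["AB"][v]: 1, ctx.z[v]: -1},
                    ub=0,
                )
            else:
                for key in ("aB", "Bb"):
                    reports[key][v] = m.binary(f"r{key}|{k}|{vname[v]}")
            # a telomere whose component potential collapsed to zero
            # terminates an indel-ended path and must report it
            keys = ("Ab", "Aa") if tag == "A" else ("aB", "Bb")
            m.add_constr(
                f"telo_report|{k}|{vname[v]}",
                {ctx.y[v]: 1, reports[keys[0]][v]: 1, reports[keys[1]][v]: 1},
                lb=1,
            )
            # conversely, reporting forces the potential to zero
            for key in keys:
                m.add_constr(
                    f"report_zero_{key}|{k}|{vname[v]}",
                    {ctx.y[v]: 1, reports[key][v]: ranks[v]},
                    ub=ranks[v],
                )
        elif tag == "A":
            reports["c"][v] = m.binary(f"rc|{k}|{vname[v]}")
            m.add_constr(
                f"claim_cycle|{k}|{vname[v]}", {reports["c"][v]: 1, ctx.z[v]: -1}, ub=0
            )
            if (tag, ext.marker) in ctx.self_vars:
                reports["ab"][v] = m.binary(f"rab|{k}|{vname[v]}")
                # only an extremity resting on its own self edge may
                # open an ab path
                m.add_constr(
                    f"ab_stop|{k}|{vname[v]}",
                    {reports["ab"][v]: 1, ctx.self_vars[(tag, ext.marker)]: -1},
                    ub=0,
                )

    # --- Shao-Lin-Moret style potential propagation -----------------------
    def potential(u: Vertex, v: Vertex, x: Variable, name: str) -> None:
        # y_u <= y_v + rank(u) * (1 - x), emitted for both orientations
        m.add_constr(
            f"pot|{k}|{name}",
            {ctx.y[u]: 1, ctx.y[v]: -1, x: ranks[u]},
            ub=ranks[u],
        )

    for i, (u, v) in enumerate(R.adj_edges):
        x = _adj_var(spp, ctx, u, v)
        potential(u, v, x, f"adj{i}a")
        potential(v, u, x, f"adj{i}b")
    for ma, mb in R.ext_pairs:
        x = ctx.pair_vars[(ma, mb)]
        for side in (TAIL, HEAD):
            u: Vertex = ("A", Extremity(ma, side))
            v: Vertex = ("B", Extremity(mb, side))
            potential(u, v, x, f"ext{ma}.{mb}.{side}a")
            potential(v, u, x, f"ext{ma}.{mb}.{side}b")
    for (tag, mk), x in ctx.self_vars.items():
        for side in (TAIL, HEAD):
            u = (tag, Extremity(mk, side))
            # y_u <= rank(u) * (1 - x): a selected self edge kills the claim
            m.add_constr(
                f"pot|{k}|self{tag}.{mk}.{side}",
                {ctx.y[u]: 1, x: ranks[u]},
                ub=ranks[u],
            )

    # --- genome-side labels and path reporting ----------------------------
    for (tag, mk), x in ctx.self_vars.items():
        for side in (TAIL, HEAD):
            lv = ctx.l[(tag, Extremity(mk, side))]
            if tag == "A":  # an A-side indel end lies on the a side
                m.add_constr(f"label_stop|{k}|{tag}.{mk}.{side}", {lv: 1, x: 1}, ub=1)
            else:  # ... and a B-side indel end on the b side
                m.add_constr(f"label_stop|{k}|{tag}.{mk}.{side}", {x: 1, lv: -1}, ub=0)
    for ma, mb in R.ext_pairs:  # labels agree across matched markers
        x = ctx.pair_vars[(ma, mb)]
        for side in (TAIL, HEAD):
            lu = ctx.l[("A", Extremity(ma, side))]
            lv = ctx.l[("B", Extremity(mb, side))]
            nm = f"label_ext|{k}|{ma}.{mb}.{side}"
            m.add_constr(nm + "a", {lu: 1, lv: -1, x: 1}, ub=1)
            m.add_constr(nm + "b", {lv: 1, lu: -1, x: 1}, ub=1)
    for i, (u, v) in enumerate(R.adj_edges):
        x = _adj_var(spp, ctx, u, v)
        tag = u[0]
        u_t, v_t = u[1].is_telomere, v[1].is_telomere
        if not u_t and not v_t:
            # the label may only flip across an adjacency next to an indel
            # end, paying the ab report of the lower-side endpoint
            for p, q in ((u, v), (v, u)):
                terms = {ctx.l[p]: 1.0, ctx.l[q]: -1.0, x: 1.0}
                rab = ctx.reports["ab"].get(q)
                if rab is not None:
                    terms[rab] = -1.0
                m.add_constr(f"label_adj|{k}|{i}|{vname[p]}", terms, ub=1)
        else:
            t, e = (u, v) if u_t else (v, u)
            if tag == "A":
                # a b-side neighbour of an A-telomere ends an AB or Ab
                # path there
                terms = {
                    ctx.l[e]: 1.0,
                    reports["AB"][t]: -1.0,
                    reports["Ab"][t]: -1.0,
                    x: 1.0,
                }
                m.add_constr(f"label_teloA|{k}|{i}", terms, ub=1)
                # claim guards match the neighbour's side
                m.add_constr(
                    f"guard_AB|{k}|{i}",
                    {reports["AB"][t]: 1, ctx.l[e]: -1, x: 1},
                    ub=1,
                )
                m.add_constr(
                    f"guard_Ab|{k}|{i}",
                    {reports["Ab"][t]: 1, ctx.l[e]: -1, x: 1},
                    ub=1,
                )
                m.add_constr(
                    f"guard_Aa|{k}|{i}",
                    {reports["Aa"][t]: 1, ctx.l[e]: 1, x: 1},
                    ub=2,
                )
            else:
                # an a-side neighbour of a B-telomere ends an aB path
                terms = {x: 1.0, ctx.l[e]: -1.0, reports["aB"][t]: -1.0}
                m.add_constr(f"label_teloB|{k}|{i}", terms, ub=0)
                m.add_constr(
                    f"guard_aB|{k}|{i}",
                    {reports["aB"][t]: 1, ctx.l[e]: 1, x: 1},
                    ub=2,
                )
                m.add_constr(
                    f"guard_Bb|{k}|{i}",
                    {reports["Bb"][t]: 1, ctx.l[e]: -1, x: 1},
                    ub=1,
                )


def emit_circular_singletons(spp: SppModel, ctx: EdgeContext, mode: str = "auto") -> None:
    """Count cycles of alternating adjacency and self edges.

    ``enumerate`` adds one indicator per candidate singleton; ``count``
    installs the orientation/potential gadget; ``auto`` enumerates while the
    number of candidates stays within twice the number of self edges and
    falls back to the gadget beyond that threshold.
    """
    if mode not in ("auto", "enumerate", "count"):
        raise ValueError("mode must be auto, enumerate or count")
    m = spp.model
    k = ctx.index
    n_self = len(ctx.self_vars)

    if n_self == 0:
        ctx.singleton_mode = "none"
        ctx.counters["s"] = m.add_var(f"s|{k}", 0, 0, True)
        return

    s_terms: dict[Variable, float] = {}
    threshold = 2 * n_self
    candidates = None
    if mode in ("auto", "enumerate"):
        cap = threshold if mode == "auto" else 10_000
        candidates = _enumerate_singleton_candidates(spp, ctx, cap=cap)
        if candidates is None and mode == "enumerate":
            raise RuntimeError(
                "explicit enumeration requested but candidate count exceeds "
                "the safety cap"
            )

    if candidates is not None:
        ctx.singleton_mode = "enumerate"
        for idx, cyc in enumerate(candidates):
            ind = m.binary(f"rs|{k}|cand{idx}")
            terms: dict[Variable, float] = {ind: -1.0}
            for var in cyc:
                terms[var] = terms.get(var, 0.0) + 1.0
            m.add_constr(f"cand|{k}|{idx}", terms, ub=len(cyc) - 1)
            s_terms[ind] = 1.0
            ctx.singleton_candidates.append((ind, cyc))
    else:
        ctx.singleton_mode = "count"
        _emit_singleton_gadget(spp, ctx, s_terms)

    s_var = m.add_var(f"s|{k}", 0, float("inf"), True)
    ctx.counters["s"] = s_var
    terms = dict(s_terms)
    terms[s_var] = terms.get(s_var, 0.0) - 1.0
    m.add_constr(f"sdef|{k}", terms, 0, 0)


def _self_adjacency_edges(ctx: EdgeContext):
    """Adjacency edges joining extremities of two self-capable markers of
    the same genome (the only adjacencies a circular singleton can use)."""
    out = []
    vs = {
        (tag, Extremity(mk, side))
        for (tag, mk) in ctx.self_vars
        for side in (TAIL, HEAD)
    }
    for u, v in ctx.cfmrd.adj_edges:
        if u in vs and v in vs:
            out.append((u, v))
    return out, vs


def _enumerate_singleton_candidates(
    spp: SppModel, ctx: EdgeContext, cap: int
) -> Optional[list[list[Variable]]]:
    """All cycles alternating candidate adjacencies and self edges, as lists
    of their selection variables; ``None`` when more than ``cap`` exist.

    A candidate visits each of its markers once, entering through one
    extremity and leaving -- via the marker's self edge -- through the
    other.  Cycles are enumerated from their minimum-rank extremity.
    """
    adj_edges, _ = _self_adjacency_edges(ctx)
    ranks = ctx.cfmrd.ranks
    nbrs: dict[Vertex, list[tuple[Vertex, tuple[Vertex, Vertex]]]] = {}
    for u, v in adj_edges:
        nbrs.setdefault(u, []).append((v, (u, v)))
        nbrs.setdefault(v, []).append((u, (u, v)))

    def sibling(v: Vertex) -> Vertex:
        return (v[0], v[1].sibling())

    found: list[tuple[list[tuple[Vertex, Vertex]], set[Vertex]]] = []
    seen: set[frozenset] = set()
    overflow = False

    def walk(start, exit_, edges, markers):
        nonlocal overflow
        if overflow:
            return
        for nxt, e in nbrs.get(exit_, []):
            if e in edges:
                continue
            if nxt == start:
                key = frozenset(edges + [e])
                if key not in seen:
                    seen.add(key)
                    found.append((edges + [e], set(markers)))
                    if len(found) > cap:
                        overflow = True
                        return
                continue
            tm = (nxt[0], nxt[1].marker)
            if tm in markers:
                continue
            if min(ranks[nxt], ranks[sibling(nxt)]) < ranks[start]:
                continue  # canonical: start at the minimum-rank extremity
            walk(start, sibling(nxt), edges + [e], markers | {tm})

    for start in sorted(nbrs, key=lambda v: ranks[v]):
        if ranks[sibling(start)] < ranks[start]:
            continue  # its sibling is the canonical start
        walk(start, sibling(start), [], {(start[0], start[1].marker)})
        if overflow:
            return None

    out: list[list[Variable]] = []
    for edges, markers in found:
        vars_ = [_adj_var(spp, ctx, u, v) for u, v in edges]
        vars_ += [ctx.self_vars[mk] for mk in sorted(markers)]
        out.append(vars_)
    return out


def _emit_singleton_gadget(
    spp: SppModel, ctx: EdgeContext, s_terms: dict[Variable, float]
) -> None:
    """Orientation/potential counting of circular singletons.

    A selected edge flips the orientation bit ``d``; the potential ``w``
    must increase along the orientation across every selected adjacency and
    stays level across selected self edges, so every closed alternating
    cycle must pay a report ``r^s`` somewhere.  The level constraint is
    conditioned on the self edge being selected, otherwise a matched
    one-marker circular chromosome would be forced to report.
    """
    m = spp.model
    k = ctx.index
    adj_edges, vs = _self_adjacency_edges(ctx)
    K = len(ctx.self_vars) + 1
    big = K + 2
    d: dict[Vertex, Variable] = {}
    w: dict[Vertex, Variable] = {}
    rs: dict[Vertex, Variable] = {}
    ctx.gadget_vars = {"d": d, "w": w, "rs": rs}
    for v in sorted(vs, key=lambda v: ctx.cfmrd.ranks[v]):
        nm = f"{v[0]}|{v[1].marker}|{v[1].side}"
        d[v] = m.binary(f"d|{k}|{nm}")
        w[v] = m.add_var(f"wv|{k}|{nm}", 0, K, True)
        rs[v] = m.binary(f"rs|{k}|{nm}")
        s_terms[rs[v]] = 1.0
    edges_with_vars = [
        (u, v, _adj_var(spp, ctx, u, v)) for u, v in adj_edges
    ] + [
        (
            (tag, Extremity(mk, TAIL)),
            (tag, Extremity(mk, HEAD)),
            var,
        )
        for (tag, mk), var in ctx.self_vars.items()
    ]
    for i, (u, v, x) in enumerate(edges_with_vars):
        # selected edges flip the orientation
        m.add_constr(f"flip_a|{k}|{i}", {d[u]: 1, d[v]: 1, x: 1}, ub=2)
        m.add_constr(f"flip_b|{k}|{i}", {d[u]: 1, d[v]: 1, x: -1}, lb=0)
    for i, ((tag, mk), x) in enumerate(sorted(ctx.self_vars.items())):
        u = (tag, Extremity(mk, TAIL))
        v = (tag, Extremity(mk, HEAD))
        # the potential is level across a *selected* self edge
        m.add_constr(f"level_a|{k}|{i}", {w[u]: 1, w[v]: -1, x: big}, ub=big)
        m.add_constr(f"level_b|{k}|{i}", {w[v]: 1, w[u]: -1, x: big}, ub=big)
    for i, (u, v) in enumerate(adj_edges):
        x = _adj_var(spp, ctx, u, v)
        for p, q in ((u, v), (v, u)):
            # w_q >= w_p + d_q - d_p unless unselected or reported
            m.add_constr(
                f"rise|{k}|{i}|{1 if p == u else 2}",
                {
                    w[p]: 1,
                    w[q]: -1,
                    d[q]: 1,
                    d[p]: -1,
                    x: big,
                    rs[p]: -big,
                    rs[q]: -big,
                },
                ub=big,
            )


def emit_distance_assembly(spp: SppModel, ctx: EdgeContext) -> None:
    """Counters, linearised maxima/ceiling and the distance of one branch."""
    m = spp.model
    k = ctx.index
    inf = float("inf")

    def counter(name: str, terms: dict[Variable, float]) -> Variable:
        var = m.add_var(f"{name}|{k}", 0, inf, True)
        t = dict(terms)
        t[var] = t.get(var, 0.0) - 1.0
        m.add_constr(f"{name}def|{k}", t, 0, 0)
        ctx.counters[name] = var
        return var

    n = counter("n", {v: 1.0 for v in ctx.pair_vars.values()})
    c = counter("c", {v: 1.0 for v in ctx.reports["c"].values()})
    p = {}
    for key in ("ab", "Aa", "aB", "Ab", "Bb", "AB"):
        p[key] = counter(f"p{key}", {v: 1.0 for v in ctx.reports[key].values()})
    pmaxa = m.add_var(f"pmaxa|{k}", 0, inf, True)
    pmaxb = m.add_var(f"pmaxb|{k}", 0, inf, True)
    ctx.counters["pmaxa"] = pmaxa
    ctx.counters["pmaxb"] = pmaxb
    m.add_constr(f"pmaxa1|{k}", {pmaxa: 1, p["Aa"]: -1}, lb=0)
    m.add_constr(f"pmaxa2|{k}", {pmaxa: 1, p["aB"]: -1}, lb=0)
    m.add_constr(f"pmaxb1|{k}", {pmaxb: 1, p["Ab"]: -1}, lb=0)
    m.add_constr(f"pmaxb2|{k}", {pmaxb: 1, p["Bb"]: -1}, lb=0)
    q = m.add_var(f"q|{k}", -inf, inf, True)
    ctx.counters["q"] = q
    # 2q >= p_ab + max-a + max-b - p_AB   (ceiling, tight under minimisation)
    m.add_constr(
        f"qdef|{k}",
        {p["ab"]: 1, pmaxa: 1, pmaxb: 1, p["AB"]: -1, q: -2},
        ub=0,
    )
    f = m.add_var(f"f|{k}", 0, inf, True)
    ctx.f_var = f
    s = ctx.counters["s"]
    m.add_constr(f"fdef|{k}", {f: 1, n: -1, c: 1, q: -1, s: -1}, 0, 0)


def emit_objective(
    spp: SppModel,
    alpha: Optional[float] = None,
    beta_emulation: Optional[float] = None,
) -> None:
    """Problem objective: minimise  sum_E alpha*f_E - (1-alpha)*w_E.

    ``beta_emulation`` reduces the weight of every telomeric adjacency by
    the given amount before assembly, reproducing the explicit telomere
    penalty of the predecessor formulation (its defaults alpha'=1/2,
    beta'=1/4 correspond to alpha=2/3 and a reduction of 1 here).
    """
    if alpha is not None:
        spp.alpha = alpha
    spp.beta_emulation = beta_emulation
    if not 0.0 <= spp.alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    m = spp.model
    for ctx in spp.edges:
        # w_E: total selected adjacency weight at the branch endpoints
        terms: dict[Variable, float] = {}
        for node in (ctx.parent, ctx.child):
            for adj, var in spp.adj_vars[node].items():
                wt = spp.weights.get(adj)
                if beta_emulation is not None and (
                    adj[0].is_telomere or adj[1].is_telomere
                ):
                    wt -= beta_emulation
                if wt:
                    terms[var] = terms.get(var, 0.0) + wt
        w_var = m.add_var(f"w|{ctx.index}", -float("inf"), float("inf"), False)
        ctx.w_var = w_var
        t = dict(terms)
        t[w_var] = t.get(w_var, 0.0) - 1.0
        m.add_constr(f"wdef|{ctx.index}", t, 0, 0)
        m.add_objective_term(ctx.f_var, spp.alpha)
        m.add_objective_term(w_var, -(1.0 - spp.alpha))


# ---------------------------------------------------------------------------
# assembly, solving, decoding
# ---------------------------------------------------------------------------


def build_spp_model(
    phylogeny: Phylogeny,
    weights: Optional[AdjacencyWeights] = None,
    bounds: Optional[FamilyBounds] = None,
    alpha: float = 1.0,
    beta_emulation: Optional[float] = None,
    singleton_mode: str = "auto",
) -> SppModel:
    """Assemble the full ILP for a phylogeny of (degenerate) genomes."""
    phylogeny.validate_bindings()
    spp = SppModel(
        model=Model("spp", "min"),
        phylogeny=phylogeny,
        alpha=alpha,
        weights=weights if weights is not None else AdjacencyWeights(),
        bounds=bounds if bounds is not None else FamilyBounds(),
    )
    emit_global(spp)
    for idx, (parent, child) in enumerate(sorted(phylogeny.edges)):
        cfmrd = build_cfmrd(
            phylogeny.genome(parent), phylogeny.genome(child), self_edges="all"
        )
        ctx = EdgeContext(idx, parent, child, cfmrd)
        spp.edges.append(ctx)
        emit_local(spp, ctx)
        emit_circular_singletons(spp, ctx, mode=singleton_mode)
        emit_distance_assembly(spp, ctx)
    emit_objective(spp, alpha=alpha, beta_emulation=beta_emulation)
    return spp


def solve(
    spp: SppModel,
    time_limit: Optional[float] = None,
    threads: int = 1,
    seed: int = 0,
    warm_start: Optional[dict[str, float]] = None,
    mip_gap: float = 0.0,
    verbose: bool = False,
) -> Solution:
    """Solve the assembled model and decode the result.

    The HiGHS backend used here runs single-threaded and deterministically;
    ``threads`` and ``seed`` are accepted for interface stability.  A warm
    start (a full assignment, e.g. from preprocessing) is validated and used
    as incumbent fallback when the solver run is cut off before finding a
    solution of its own.
    """
    del threads, seed
    if warm_start is not None:
        bad = spp.model.check_assignment(warm_start)
        if bad:
            raise ValueError(f"warm start infeasible: {bad[:5]}")
    res = spp.model.solve(time_limit=time_limit, mip_gap=mip_gap, verbose=verbose)
    assignment = res.assignment
    status = res.status
    if assignment is None and warm_start is not None:
        assignment = {k: float(v) for k, v in warm_start.items()}
        status = f"{status}+warm_start"
    if assignment is None:
        raise RuntimeError(f"no solution available (solver status: {res.status})")
    return decode(spp, assignment, status=status, gap=res.gap)


def decode(
    spp: SppModel,
    assignment: dict[str, float],
    status: str = "optimal",
    gap: Optional[float] = None,
) -> Solution:
    """Reconstitute genomes and distances from a variable assignment.

    Every decoded genome is validated against the genome invariants and the
    objective is recomputed independently from the decoded selections; any
    discrepancy with the solver's variable values raises.
    """
    linearizations: dict[str, Genome] = {}
    for node in spp.phylogeny.nodes:
        genome = spp.phylogeny.genome(node)
        present = {
            v: round(assignment[var.name]) for v, var in spp.g_vars[node].items()
        }
        selected = [
            adj
            for adj, var in spp.adj_vars[node].items()
            if round(assignment[var.name]) == 1
        ]
        fams = {
            mk: fam
            for mk, fam in genome.families.items()
            if present[Extremity(mk, TAIL)] == 1
        }
        telomeres = {t for adj in selected for t in adj if t.is_telomere}
        linearizations[node] = Genome(node, fams, selected, telomeres)

    distances: dict[tuple[str, str], int] = {}
    censuses: dict[tuple[str, str], ComponentCensus] = {}
    objective = 0.0
    for ctx in spp.edges:
        # recompute the branch distance from the decoded decomposition
        la = linearizations[ctx.parent]
        lb = linearizations[ctx.child]
        vertices = [("A", v) for v in la.vertices()] + [
            ("B", v) for v in lb.vertices()
        ]
        adj = [(("A", u), ("A", v)) for u, v in la.adjacencies] + [
            (("B", u), ("B", v)) for u, v in lb.adjacencies
        ]
        ext = []
        for (ma, mb), var in ctx.pair_vars.items():
            if round(assignment[var.name]) == 1:
                for side in (TAIL, HEAD):
                    ext.append(
                        (("A", Extremity(ma, side)), ("B", Extremity(mb, side)))
                    )
        selfp = []
        for (tag, mk), var in ctx.self_vars.items():
            if round(assignment[var.name]) == 1:
                selfp.append(
                    (
                        (tag, Extremity(mk, TAIL)),
                        (tag, Extremity(mk, HEAD)),
                    )
                )
        cens = classify_components(vertices, adj, ext, selfp)
        d = distance_resolved(cens)
        f_val = round(assignment[ctx.f_var.name])
        if f_val < d:
            raise AssertionError(
                f"edge {ctx.parent}->{ctx.child}: solver distance {f_val} "
                f"below census distance {d} (internal inconsistency)"
            )
        if status == "optimal" and spp.alpha > 0 and f_val != d:
            raise AssertionError(
                f"edge {ctx.parent}->{ctx.child}: optimal solver distance "
                f"{f_val} != census distance {d} (internal inconsistency)"
            )
        distances[(ctx.parent, ctx.child)] = d
        censuses[(ctx.parent, ctx.child)] = cens
        w_val = assignment[ctx.w_var.name] if ctx.w_var is not None else 0.0
        objective += spp.alpha * d - (1.0 - spp.alpha) * w_val
    model_obj = spp.model.objective_value(assignment)
    if status == "optimal" and spp.alpha > 0 and abs(model_obj - objective) > 1e-6:
        raise AssertionError(
            f"objective mismatch: recomputed {objective} vs model {model_obj}"
        )
    return Solution(
        linearizations=linearizations,
        distances=distances,
        objective=objective,
        status=status,
        gap=gap,
        censuses=censuses,
        assignment=assignment,
    )


# ---------------------------------------------------------------------------
# convenience: pairwise distance through the ILP
# ---------------------------------------------------------------------------


def pairwise_distance_ilp(
    genome_a: Genome,
    genome_b: Genome,
    time_limit: Optional[float] = None,
    singleton_mode: str = "auto",
) -> int:
    """DCJ-indel distance of two proper genomes via the two-node ILP."""
    na, nb = genome_a.name, genome_b.name
    if na == nb:
        na, nb = f"{na}#A", f"{nb}#B"
    phylo = Phylogeny([(na, nb)], root=na)
    ga = Genome(na, genome_a.families, genome_a.adjacencies, genome_a.telomeres)
    gb = Genome(nb, genome_b.families, genome_b.adjacencies, genome_b.telomeres)
    phylo.bind(ga)
    phylo.bind(gb)
    spp = build_spp_model(phylo, alpha=1.0, singleton_mode=singleton_mode)
    sol = solve(spp, time_limit=time_limit)
    if not sol.status.startswith("optimal"):
        raise RuntimeError(f"solver did not prove optimality: {sol.status}")
    return round(sol.objective)
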