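"""Optional solution-space tightening: warm starts and leaf-pair bounds.

Both features default to off: on most instances the time spent computing
them exceeds what they save the solver.  They remain useful when any
incumbent at all is needed quickly (the warm start is a certified feasible
solution) or when pairwise leaf distances were computed anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .genomes import Extremity, Genome, HEAD, TAIL
from .ilp_model import SppModel, pairwise_distance_ilp
from .linearize import try_linearize


@dataclass
class WarmStart:
    """A certified-feasible assignment of the full ILP."""

    assignment: dict[str, float]
    objective: float
    linearizations: dict[str, Genome] = field(default_factory=dict)


class NotLinearizableError(ValueError):
    """A node's candidate set admits no linearization; augment it first."""


# ---------------------------------------------------------------------------
# initial solution
# ---------------------------------------------------------------------------


def initial_solution(spp: SppModel) -> WarmStart:
    """Greedy feasible solution: linearize every ancestor by weight-aware
    maximum matching, then decompose every branch diagram by fixing short
    alternating cycles first.

    The resulting objective is an upper bound on the optimum; the returned
    assignment satisfies every constraint of the assembled model.  Only
    copy-number bounds that admit keeping every candidate marker are
    supported.
    """
    phylo = spp.phylogeny
    for node in phylo.nodes:
        g = phylo.genome(node)
        for fam, ms in g.family_members().items():
            _, high = spp.bounds.get(g, fam)
            if high < len(ms):
                raise ValueError(
                    "initial_solution supports only bounds that admit keeping "
                    f"all candidate markers (node {node}, family {fam})"
                )

    assignment: dict[str, float] = {}
    linearizations: dict[str, Genome] = {}

    # -- global level: one linearization per node -------------------------
    for node in phylo.nodes:
        genome = phylo.genome(node)
        if node in phylo.leaves:
            lin = Genome(node, genome.families, genome.adjacencies, genome.telomeres)
        else:
            res = try_linearize(genome, spp.weights)
            if not res.feasible:
                raise NotLinearizableError(
                    f"candidate set of node {node} is not linearizable; "
                    "augment it (local guarantees or safer mode) first"
                )
            lin = res.linearization
        linearizations[node] = lin
        for v, var in spp.g_vars[node].items():
            if v.is_telomere:
                assignment[var.name] = 1 if v in lin.telomeres else 0
            else:
                assignment[var.name] = 1
        for adj, var in spp.adj_vars[node].items():
            assignment[var.name] = 1 if adj in lin.adjacencies else 0

    # -- local level: one decomposition per branch ------------------------
    for ctx in spp.edges:
        la, lb = linearizations[ctx.parent], linearizations[ctx.child]
        matching = _greedy_matching(la, lb, max_cycle_edges=8)
        _assign_edge(spp, ctx, la, lb, matching, assignment)

    bad = spp.model.check_assignment(assignment)
    if bad:  # pragma: no cover - internal consistency trap
        raise AssertionError(f"warm start violates the model: {bad[:5]}")
    return WarmStart(
        assignment=assignment,
        objective=spp.model.objective_value(assignment),
        linearizations=linearizations,
    )


def _greedy_matching(
    la: Genome, lb: Genome, max_cycle_edges: int = 8
) -> list[tuple[str, str]]:
    """Maximum matching per family, preferring pairings that close short
    alternating cycles in the comparison diagram (shortest first)."""
    fams_a = la.family_members()
    fams_b = lb.family_members()

    adj: dict[tuple[str, Extremity], tuple[str, Extremity]] = {}
    for tag, g in (("A", la), ("B", lb)):
        for u, v in g.adjacencies:
            adj[(tag, u)] = (tag, v)
            adj[(tag, v)] = (tag, u)

    partners: dict[tuple[str, str], list[str]] = {}
    for fam in set(fams_a) & set(fams_b):
        for ma in fams_a[fam]:
            partners[("A", ma)] = fams_b[fam]
        for mb in fams_b[fam]:
            partners[("B", mb)] = fams_a[fam]

    cycles: list[tuple[int, frozenset]] = []
    seen: set[frozenset] = set()

    def other_tag(tag: str) -> str:
        return "B" if tag == "A" else "A"

    def walk(start, cur, pairs, steps):
        # ``cur``: vertex just reached; continue through its adjacency edge,
        # then branch over the extremity edges of the adjacent extremity
        if steps >= max_cycle_edges // 2:
            return
        nxt = adj.get(cur)
        if nxt is None or nxt[1].is_telomere:
            return
        tag, ext = nxt
        for pm in partners.get((tag, ext.marker), []):
            key = (ext.marker, pm) if tag == "A" else (pm, ext.marker)
            if any(
                k != key and (k[0] == key[0] or k[1] == key[1]) for k in pairs
            ):
                continue  # conflicting pairing cannot lie on one cycle
            landing = (other_tag(tag), Extremity(pm, ext.side))
            if landing == start:
                fs = frozenset(pairs | {key})
                if fs not in seen:
                    seen.add(fs)
                    cycles.append((steps + 1, fs))
                continue
            walk(start, landing, pairs | {key}, steps + 1)

    for ext in la.extremities():
        walk(("A", ext), ("A", ext), frozenset(), 0)

    cycles.sort(key=lambda c: (c[0], sorted(c[1])))
    matched_a: dict[str, str] = {}
    matched_b: dict[str, str] = {}

    def compatible(pairs) -> bool:
        pa, pb = {}, {}
        for ma, mb in pairs:
            if pa.get(ma, mb) != mb or pb.get(mb, ma) != ma:
                return False
            pa[ma], pb[mb] = mb, ma
        return all(
            matched_a.get(ma, mb) == mb and matched_b.get(mb, ma) == ma
            for ma, mb in pairs
        )

    for _, pairs in cycles:
        if compatible(pairs):
            for ma, mb in pairs:
                matched_a[ma] = mb
                matched_b[mb] = ma
    # complete to a maximum matching, family by family
    for fam in sorted(set(fams_a) & set(fams_b)):
        free_a = [m for m in fams_a[fam] if m not in matched_a]
        free_b = [m for m in fams_b[fam] if m not in matched_b]
        for ma, mb in zip(free_a, free_b):
            matched_a[ma] = mb
            matched_b[mb] = ma
    return sorted(matched_a.items())


def _is_self_pair(u, v) -> bool:
    return (
        u[0] == v[0]
        and not u[1].is_telomere
        and not v[1].is_telomere
        and u[1].marker == v[1].marker
        and u[1].side != v[1].side
    )


_PATH_KEY = {
    frozenset(("a", "b")): "ab",
    frozenset(("A", "a")): "Aa",
    frozenset(("a", "B")): "aB",
    frozenset(("A", "b")): "Ab",
    frozenset(("B", "b")): "Bb",
    frozenset(("A", "B")): "AB",
}


def _assign_edge(spp, ctx, la, lb, matching, assignment) -> None:
    """Fill in every local variable of one branch for a given matching."""
    ranks = ctx.cfmrd.ranks
    matched_a = {ma for ma, _ in matching}
    matched_b = {mb for _, mb in matching}
    mset = set(matching)

    for (ma, mb), var in ctx.pair_vars.items():
        assignment[var.name] = 1 if (ma, mb) in mset else 0
    selfed: set = set()
    for (tag, mk), var in ctx.self_vars.items():
        on = (tag == "A" and mk not in matched_a) or (
            tag == "B" and mk not in matched_b
        )
        assignment[var.name] = 1 if on else 0
        if on:
            selfed.add((tag, mk))
    # b_f points to the side whose surplus rests on self edges
    for fam in {
        (la if tag == "A" else lb).families[mk] for tag, mk in ctx.self_vars
    }:
        name = f"b|{ctx.index}|{fam}"
        if spp.model.has_var(name):
            use_a = any(
                tag == "A" and la.families[mk] == fam for tag, mk in selfed
            )
            assignment[name] = 1 if use_a else 0

    # selected edges of the decomposition
    sel_adj = []
    for tag, g in (("A", la), ("B", lb)):
        for u, v in g.adjacencies:
            sel_adj.append(((tag, u), (tag, v)))
    sel_ext = []
    for ma, mb in matching:
        for side in (TAIL, HEAD):
            sel_ext.append((("A", Extremity(ma, side)), ("B", Extremity(mb, side))))
    stop_edges = [
        ((tag, Extremity(mk, TAIL)), (tag, Extremity(mk, HEAD)))
        for tag, mk in sorted(selfed)
    ]
    stops = {v for e in stop_edges for v in e}

    # defaults: vertices outside any component keep the escape values
    for v in ctx.cfmrd.vertices:
        assignment[ctx.y[v].name] = ranks[v]
        assignment[ctx.z[v].name] = 0
        assignment[ctx.l[v].name] = 1 if (v[1].is_telomere and v[0] == "B") else 0
    for reps in ctx.reports.values():
        for var in reps.values():
            assignment[var.name] = 0

    # sub-components over adjacency + extremity edges (self edges ignored,
    # exactly as in the component census)
    nbr_sub: dict = {}
    for u, v in sel_adj + sel_ext:
        nbr_sub.setdefault(u, []).append(v)
        nbr_sub.setdefault(v, []).append(u)

    n_cycles = 0
    counts = {k: 0 for k in ("ab", "Aa", "aB", "Ab", "Bb", "AB")}
    seen: set = set()
    for v0 in sorted(nbr_sub, key=lambda v: ranks[v]):
        if v0 in seen:
            continue
        comp = [v0]
        seen.add(v0)
        stack = [v0]
        while stack:
            x = stack.pop()
            for y in nbr_sub[x]:
                if y not in seen:
                    seen.add(y)
                    comp.append(y)
                    stack.append(y)
        ends = [v for v in comp if len(nbr_sub[v]) == 1]
        has_stop = any(v in stops for v in comp)
        yval = 0 if has_stop else min(ranks[v] for v in comp)
        for v in comp:
            assignment[ctx.y[v].name] = yval
        if not ends:  # proper cycle
            vmin = min(comp, key=lambda v: ranks[v])
            assignment[ctx.z[vmin].name] = 1
            assignment[ctx.reports["c"][vmin].name] = 1
            n_cycles += 1
            for v in comp:
                if not v[1].is_telomere and v not in stops:
                    assignment[ctx.l[v].name] = 0
            continue
        labels = {v: (v[0] if v[1].is_telomere else v[0].lower()) for v in ends}
        key = _PATH_KEY.get(frozenset(labels.values()))
        lval = 1 if key in ("ab", "Ab", "Bb", "AB") or set(labels.values()) in (
            {"B"},
            {"b"},
        ) else 0
        for v in comp:
            if v[1].is_telomere or v in stops:
                continue  # fixed by side
            assignment[ctx.l[v].name] = lval
        for v in comp:
            if v in stops:
                assignment[ctx.l[v].name] = 1 if v[0] == "B" else 0
        if key is None:
            continue  # AA/BB/aa/bb: coefficient zero, nothing to report
        counts[key] += 1
        if key == "ab":
            stop_end = next(v for v in ends if v in stops and v[0] == "A")
            assignment[ctx.reports["ab"][stop_end].name] = 1
        elif key == "AB":
            t = next(v for v in ends if v[0] == "A" and v[1].is_telomere)
            assignment[ctx.z[t].name] = 1
            assignment[ctx.reports["AB"][t].name] = 1
        else:
            t = next(v for v in ends if v[1].is_telomere)
            assignment[ctx.reports[key][t].name] = 1

    n_singletons = _assign_singletons(
        spp, ctx, sel_adj, stop_edges, stops, assignment
    )

    # counters
    q = math.ceil(
        (
            counts["ab"]
            + max(counts["Aa"], counts["aB"])
            + max(counts["Ab"], counts["Bb"])
            - counts["AB"]
        )
        / 2
    )
    cnt = ctx.counters
    assignment[cnt["n"].name] = len(matching)
    assignment[cnt["c"].name] = n_cycles
    for key in ("ab", "Aa", "aB", "Ab", "Bb", "AB"):
        assignment[cnt[f"p{key}"].name] = counts[key]
    assignment[cnt["pmaxa"].name] = max(counts["Aa"], counts["aB"])
    assignment[cnt["pmaxb"].name] = max(counts["Ab"], counts["Bb"])
    assignment[cnt["q"].name] = q
    assignment[cnt["s"].name] = n_singletons
    assignment[ctx.f_var.name] = len(matching) - n_cycles + q + n_singletons
    # w_E from the emitted definition (includes telomere-weight emulation)
    wval = 0.0
    for node in (ctx.parent, ctx.child):
        for adj_, var in spp.adj_vars[node].items():
            if assignment[var.name]:
                wt = spp.weights.get(adj_)
                if spp.beta_emulation is not None and (
                    adj_[0].is_telomere or adj_[1].is_telomere
                ):
                    wt -= spp.beta_emulation
                wval += wt
    assignment[ctx.w_var.name] = wval


def _assign_singletons(spp, ctx, sel_adj, stop_edges, stops, assignment) -> int:
    """Set the circular-singleton variables; returns the singleton count.

    Circular singletons are the closed chains of the graph made of selected
    self edges plus selected adjacencies joining two resting markers.
    """
    gnbr: dict = {}
    singleton_edges = [
        (u, v) for u, v in sel_adj if u in stops and v in stops
    ] + stop_edges
    for u, v in singleton_edges:
        gnbr.setdefault(u, []).append(v)
        gnbr.setdefault(v, []).append(u)
    count = 0
    singleton_heads = []
    visited: set = set()
    ranks = ctx.cfmrd.ranks
    for v0 in sorted(gnbr, key=lambda v: ranks[v]):
        if v0 in visited:
            continue
        comp = {v0}
        stack = [v0]
        while stack:
            x = stack.pop()
            for y in gnbr[x]:
                if y not in comp:
                    comp.add(y)
                    stack.append(y)
        visited |= comp
        if all(len(gnbr[v]) == 2 for v in comp):
            count += 1
            singleton_heads.append(min(comp, key=lambda v: ranks[v]))

    if ctx.singleton_mode == "enumerate":
        recount = 0
        for ind, cyc in ctx.singleton_candidates:
            on = all(assignment[v.name] >= 0.5 for v in cyc)
            assignment[ind.name] = 1 if on else 0
            recount += int(on)
        assert recount == count, "candidate enumeration out of sync"
        return count
    if ctx.singleton_mode != "count":
        return count

    # orientation/potential gadget: alternate d along each chain and closed
    # cycle, let the potential follow the orientation, report once per cycle
    d, w, rs = ctx.gadget_vars["d"], ctx.gadget_vars["w"], ctx.gadget_vars["rs"]
    for var in list(d.values()) + list(w.values()) + list(rs.values()):
        assignment[var.name] = 0
    # the gadget graph also contains selected adjacencies between *matched*
    # gadget vertices: include them in the chain decomposition
    gv = set(d)
    chain_edges = [
        (u, v) for u, v in sel_adj if u in gv and v in gv
    ] + stop_edges
    cnbr: dict = {}
    for u, v in chain_edges:
        cnbr.setdefault(u, []).append(v)
        cnbr.setdefault(v, []).append(u)
    visited = set()
    heads = set(singleton_heads)
    for v0 in sorted(cnbr, key=lambda v: ranks[v]):
        if v0 in visited:
            continue
        comp = {v0}
        stack = [v0]
        while stack:
            x = stack.pop()
            for y in cnbr[x]:
                if y not in comp:
                    comp.add(y)
                    stack.append(y)
        visited |= comp
        endpoints = sorted(
            (v for v in comp if len(cnbr[v]) == 1), key=lambda v: ranks[v]
        )
        if endpoints:
            head, cycle = endpoints[0], False
        else:
            head = min(comp, key=lambda v: ranks[v])
            cycle = True
            assignment[rs[head].name] = 1
        order = [head]
        prev: Optional[tuple] = None
        cur = head
        if cycle:
            # leave through the self edge first so the wrap-around lands on
            # the reported vertex's adjacency edge
            nxt = next(x for x in cnbr[cur] if _is_self_pair(cur, x))
            order.append(nxt)
            prev, cur = cur, nxt
        while True:
            nxts = [x for x in cnbr[cur] if x != prev]
            if not nxts or nxts[0] == head:
                break
            order.append(nxts[0])
            prev, cur = cur, nxts[0]
        dval = 1
        for v in order:
            assignment[d[v].name] = dval
            dval = 1 - dval
        levels = [0]
        for i in range(1, len(order)):
            u, v = order[i - 1], order[i]
            if _is_self_pair(u, v):
                levels.append(levels[-1])
            else:
                levels.append(levels[-1] + (1 if assignment[d[v].name] else -1))
        shift = -min(levels)
        for v, lev in zip(order, levels):
            assignment[w[v].name] = lev + shift
    return count


# ---------------------------------------------------------------------------
# leaf-pair lower bounds
# ---------------------------------------------------------------------------


def leaf_pair_lower_bounds(
    spp: SppModel,
    distances: Optional[dict[tuple[str, str], int]] = None,
    time_limit: Optional[float] = None,
) -> dict[tuple[str, str], int]:
    """Add, for every pair of leaves, the constraint that the distances
    along the connecting tree path sum to at least the pairwise DCJ-indel
    distance of the two leaf genomes.

    Any chain of intermediate genomes transforming one leaf genome into the
    other needs at least as many operations as a direct transformation, so
    the bound never cuts off an optimum.  Pairwise distances are computed
    with the two-node ILP unless supplied.
    """
    phylo = spp.phylogeny
    f_of = {(ctx.parent, ctx.child): ctx.f_var for ctx in spp.edges}
    out: dict[tuple[str, str], int] = {}
    leaves = list(phylo.leaves)
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            if distances is not None and (a, b) in distances:
                dist = distances[(a, b)]
            else:
                dist = pairwise_distance_ilp(
                    phylo.genome(a), phylo.genome(b), time_limit=time_limit
                )
            out[(a, b)] = dist
            if dist > 0:
                terms = {f_of[e]: 1.0 for e in phylo.path_edges(a, b)}
                name = f"leaf_bound|{a}|{b}"
                spp.model.add_constr(name, terms, lb=dist)
                spp.extra_constraints.append(name)
    return out
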