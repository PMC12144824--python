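"""Linearizability testing and telomere augmentation for degenerate genomes.

A degenerate genome is *linearizable* when a conflict-free subset of its
candidate adjacencies covers every marker extremity exactly once -- i.e. it
admits a proper genome as sub-selection.  Weighting each candidate adjacency
by the number of non-telomeric extremities it touches turns the question
into a maximum-weight matching problem: the genome is linearizable iff the
optimum weight equals the number of marker extremities, and the optimal
matching itself is a linearization.

Two augmentation strategies guarantee linearizability of noisy candidate
sets: a per-component one that only adds telomeres where a component cannot
be linearized locally, and a *safer* mode that offers a telomere to every
extremity so that no spurious candidate adjacency is ever forced into the
solution merely to keep the genome linearizable.
"""

from __future__ import annotations

import itertools

from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .genomes import (
    AdjacencyWeights,
    DegenerateGenome,
    Extremity,
    Genome,
    TELO,
)


def linearizability_weight(adj: tuple[Extremity, Extremity]) -> int:
    """Number of marker extremities incident to an adjacency (1 or 2)."""
    u, v = adj
    if u.is_telomere and v.is_telomere:
        raise ValueError("telomere-telomere adjacencies are not permitted")
    return 2 - int(u.is_telomere) - int(v.is_telomere)


@dataclass
class LinearizationResult:
    feasible: bool
    linearization: Optional[Genome]
    matching_weight: int


def try_linearize(
    degenerate: DegenerateGenome,
    weights: Optional[AdjacencyWeights] = None,
) -> LinearizationResult:
    """Find a linearization of ``degenerate`` via maximum-weight matching.

    The primary objective is extremity coverage (the linearizability
    criterion); when candidate ``weights`` are given they break ties among
    full-coverage solutions, preferring heavy candidate adjacencies.
    Infeasibility is reported in the result, not raised.
    """
    n_ext = len(degenerate.families) * 2
    graph = nx.Graph()
    graph.add_nodes_from(degenerate.vertices())
    if weights is not None:
        total = sum(abs(w) for _, w in weights.items()) + 1.0
    else:
        total = 1.0
    scale = 2.0 * total
    for u, v in degenerate.adjacencies:
        w = scale * linearizability_weight((u, v))
        if weights is not None:
            w += weights.get(u, v)
        graph.add_edge(u, v, weight=w)
    matching = nx.max_weight_matching(graph, maxcardinality=False)
    cover = sum(linearizability_weight((u, v)) for u, v in matching)
    if cover != n_ext:
        return LinearizationResult(False, None, cover)
    telomeres = {w for e in matching for w in e if w.is_telomere}
    genome = Genome(
        degenerate.name,
        degenerate.families,
        matching,
        telomeres,
    )
    return LinearizationResult(True, genome, cover)


def brute_force_linearizable(degenerate: DegenerateGenome) -> bool:
    """Exhaustive check over all adjacency subsets (test oracle, tiny only)."""
    n_ext = len(degenerate.families) * 2
    adjs = sorted(degenerate.adjacencies)
    if len(adjs) > 20:
        raise ValueError("brute-force subset search limited to 20 adjacencies")
    exts = set(degenerate.extremities())
    for r in range(len(adjs) + 1):
        for subset in itertools.combinations(adjs, r):
            deg: dict[Extremity, int] = {}
            for u, v in subset:
                deg[u] = deg.get(u, 0) + 1
                deg[v] = deg.get(v, 0) + 1
            if any(d > 1 for d in deg.values()):
                continue
            if all(deg.get(e, 0) == 1 for e in exts):
                return True
    return False


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _fresh_telomere(v: Extremity) -> Extremity:
    """Deterministic telomere name for augmenting extremity ``v``."""
    return Extremity(f"t_{v.marker}_{v.side}", TELO)


def _components(d: DegenerateGenome) -> list[list[Extremity]]:
    graph = nx.Graph()
    graph.add_nodes_from(d.vertices())
    graph.add_edges_from(d.adjacencies)
    graph.add_edges_from(d.marker_edges())
    return [sorted(c) for c in nx.connected_components(graph)]


def _locally_linearizable(d: DegenerateGenome, comp: list[Extremity]) -> bool:
    """Even-sized components that are simple paths, simple cycles, or whose
    adjacencies form a complete graph are accepted as locally linearizable,
    provided their adjacency edges contain a perfect matching of the
    component (the matching is what actually certifies a local
    linearization)."""
    if len(comp) % 2 != 0:
        return False
    cset = set(comp)
    adj_edges = [e for e in d.adjacencies if e[0] in cset]
    edges = adj_edges + [e for e in d.marker_edges() if e[0] in cset]
    deg: dict[Extremity, int] = {v: 0 for v in comp}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    n_edges = len(edges)
    degs = sorted(deg.values())
    shape_ok = False
    if degs and degs[-1] <= 2:
        if n_edges == len(comp) - 1 and degs[0] == 1 and degs[1] == 1:
            shape_ok = True  # simple path
        elif n_edges == len(comp) and degs[0] == 2:
            shape_ok = True  # simple cycle
    k = len(comp)
    if all(not v.is_telomere for v in comp) and len(adj_edges) == k * (k - 1) // 2:
        shape_ok = True  # fully connected on marker extremities
    if not shape_ok:
        return False
    graph = nx.Graph()
    graph.add_nodes_from(comp)
    graph.add_edges_from(adj_edges)
    matching = nx.max_weight_matching(graph, maxcardinality=True)
    return 2 * len(matching) == len(comp)


def augment_local_guarantees(degenerate: DegenerateGenome) -> DegenerateGenome:
    """Add telomeres only in components without a local linearization
    guarantee; every extremity of such a component gains a fresh telomere
    and telomeric adjacency."""
    out = degenerate.copy()
    for comp in _components(degenerate):
        if _locally_linearizable(degenerate, comp):
            continue
        for v in comp:
            if v.is_telomere:
                continue
            out.add_adjacency(v, _fresh_telomere(v))
    return out


def augment_safer(
    degenerate: DegenerateGenome,
    telomere_weight: float = 0.0,
) -> tuple[DegenerateGenome, AdjacencyWeights]:
    """Offer a telomere to *every* extremity (safer linearization mode).

    Returns the augmented genome together with the weight delta assigning
    ``telomere_weight`` to each added telomeric adjacency.  Idempotent:
    extremities that already carry an augmentation telomere gain nothing.
    """
    out = degenerate.copy()
    delta = AdjacencyWeights()
    for v in sorted(degenerate.extremities()):
        t = _fresh_telomere(v)
        if (min(v, t), max(v, t)) in out.adjacencies:
            continue
        adj = out.add_adjacency(v, t)
        delta._w[adj] = telomere_weight
    return out, delta


def is_augmentation_telomere(t: Extremity) -> bool:
    return t.is_telomere and t.marker.startswith("t_")
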