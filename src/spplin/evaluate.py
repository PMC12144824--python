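"""Scoring of reconstructed ancestral genomes against simulated truth."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genomes import DegenerateGenome
from .ilp_model import Solution
from .linearize import is_augmentation_telomere
from .simulate import GroundTruth


def _canonical_keys(genome: DegenerateGenome):
    """Adjacency keys insensitive to orientation and to telomere identity.

    Returns (non-telomeric keys, telomeric keys, augmentation-telomeric
    keys); telomeric adjacencies are keyed by their marker extremity only.
    """
    keys = set()
    telo = set()
    telo_aug = set()
    for u, v in genome.adjacencies:
        if u.is_telomere or v.is_telomere:
            t, e = (u, v) if u.is_telomere else (v, u)
            telo.add(("telo", e))
            if is_augmentation_telomere(t):
                telo_aug.add(("telo", e))
        else:
            keys.add((u, v) if u <= v else (v, u))
    return keys, telo, telo_aug


@dataclass
class NodeScore:
    precision: float
    recall: float
    f1: float
    n_recovered: int
    n_true: int
    n_hit: int
    empty_recovery: bool = False  # precision defined as 1 on the empty set


@dataclass
class ReconstructionScore:
    """Precision/recall/F1 of recovered ancestral adjacencies.

    ``per_node`` holds one entry per internal node; the headline
    ``precision``/``recall``/``f1`` are unweighted means over nodes, and the
    ``pooled_*`` variants aggregate hits over all nodes before dividing.
    """

    per_node: dict[str, NodeScore] = field(default_factory=dict)
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    pooled_precision: float = 0.0
    pooled_recall: float = 0.0
    pooled_f1: float = 0.0
    total_distance: int = 0
    objective: float = 0.0


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def score(
    solution: Solution,
    truth: GroundTruth,
    telomeres: str = "auto",
) -> ReconstructionScore:
    """Compare recovered internal-node adjacencies with the ground truth.

    Adjacency keys are orientation-insensitive; telomeric adjacencies are
    keyed by their marker extremity.  With ``telomeres="auto"`` (default),
    telomeric adjacencies that exist only because augmentation offered a
    telomere are excluded from the recovered set unless the true genome
    ends a chromosome at the same extremity; ``"include"`` scores every
    telomeric adjacency, ``"exclude"`` drops them from both sets.
    """
    if telomeres not in ("auto", "include", "exclude"):
        raise ValueError("telomeres must be auto, include or exclude")
    out = ReconstructionScore()
    hits = rec_total = true_total = 0
    for node in truth.phylogeny.internal:
        if node not in solution.linearizations:
            raise ValueError(f"solution carries no genome for node {node}")
        recovered = solution.linearizations[node]
        true = truth.phylogeny.genome(node)
        rec_keys, rec_telo, rec_aug = _canonical_keys(recovered)
        true_keys, true_telo, _ = _canonical_keys(true)
        if telomeres == "include":
            rec_keys |= rec_telo
            true_keys |= true_telo
        elif telomeres == "auto":
            rec_keys |= (rec_telo - rec_aug) | (rec_aug & true_telo)
            true_keys |= true_telo
        hit = len(rec_keys & true_keys)
        p = 1.0 if not rec_keys else hit / len(rec_keys)
        r = 0.0 if not true_keys else hit / len(true_keys)
        if not true_keys:
            r = 1.0
        out.per_node[node] = NodeScore(
            p, r, _f1(p, r), len(rec_keys), len(true_keys), hit, not rec_keys
        )
        hits += hit
        rec_total += len(rec_keys)
        true_total += len(true_keys)
    nodes = list(out.per_node.values())
    if nodes:
        out.precision = sum(s.precision for s in nodes) / len(nodes)
        out.recall = sum(s.recall for s in nodes) / len(nodes)
        out.f1 = sum(s.f1 for s in nodes) / len(nodes)
    out.pooled_precision = 1.0 if rec_total == 0 else hits / rec_total
    out.pooled_recall = 1.0 if true_total == 0 else hits / true_total
    out.pooled_f1 = _f1(out.pooled_precision, out.pooled_recall)
    out.total_distance = sum(solution.distances.values())
    out.objective = solution.objective
    return out


def run_log(solution: Solution) -> dict:
    """JSON-ready summary of a solver run."""
    return {
        "status": solution.status,
        "objective": solution.objective,
        "gap": solution.gap,
        "total_distance": sum(solution.distances.values()),
        "distances": {f"{p}->{c}": d for (p, c), d in sorted(solution.distances.items())},
    }
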