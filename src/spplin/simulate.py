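"""Ground-truth simulation: genome evolution along a phylogeny.

The simulator evolves a root genome of single-copy markers down a fixed tree
topology, applying a configured number of operations per branch drawn from
fixed rates: segmental (tandem-free) duplications and deletions/insertions
with Zipf-distributed lengths, and otherwise uniform random DCJs (two cuts,
random rejoin; occasional single cuts so chromosome counts can drift).
Candidate adjacency sets for the internal nodes are the true adjacencies
plus a configurable number of adversarial noise adjacencies.  Everything is
driven by one seeded RNG, so identical configurations reproduce identical
ground truths byte for byte.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .genomes import (
    HEAD,
    TAIL,
    TELO,
    DegenerateGenome,
    Extremity,
    Genome,
    Phylogeny,
    parse_newick,
)

#: the balanced four-leaf topology used throughout the evaluation protocol
DEFAULT_TOPOLOGY = "(((A:1.0,B:1.0)F:1.0),((C:1.0,D:1.0)G:1.0))Root;"


@dataclass
class SimulationConfig:
    """Evolution-protocol parameters.

    Defaults follow the linear-chromosome benchmark protocol: 100 single-copy
    markers at the root, 30 operations per branch at rates 0.4 duplication /
    0.2 deletion / 0.1 insertion (remainder DCJ), Zipf length parameters 6.0
    for duplications and 4.0 for indels (truncated at ``zipf_max``), and 30
    noise adjacencies per internal node.
    """

    tree: str = DEFAULT_TOPOLOGY
    markers: int = 100
    chromosomes: int = 2
    circular: bool = False
    ops_per_branch: int = 30
    dup_rate: float = 0.4
    del_rate: float = 0.2
    ins_rate: float = 0.1
    zipf_dup: float = 6.0
    zipf_indel: float = 4.0
    zipf_max: int = 20
    noise: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.markers < 1 or self.chromosomes < 1 or self.ops_per_branch < 0:
            raise ValueError("sizes must be positive")
        rates = (self.dup_rate, self.del_rate, self.ins_rate)
        if any(r < 0 or r > 1 for r in rates) or sum(rates) > 1:
            raise ValueError("rates must lie in [0,1] and sum to at most 1")


@dataclass
class GroundTruth:
    """Everything the simulator knows: true genomes, candidates, op log."""

    config: SimulationConfig
    phylogeny: Phylogeny  # bound to the true genomes
    candidates: dict[str, DegenerateGenome] = field(default_factory=dict)
    operations: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def true_adjacency_sets(self) -> dict[str, set]:
        return {
            n: set(self.phylogeny.genome(n).adjacencies)
            for n in self.phylogeny.internal
        }

    def spp_phylogeny(self) -> Phylogeny:
        """A phylogeny carrying leaf genomes and candidate ancestors."""
        phylo = Phylogeny(
            self.phylogeny.edges, self.phylogeny.root, self.phylogeny.branch_lengths
        )
        for leaf in self.phylogeny.leaves:
            phylo.bind(self.phylogeny.genome(leaf))
        for node in self.phylogeny.internal:
            phylo.bind(self.candidates[node])
        return phylo


# -- internal chromosome-list representation: [(kind, [(marker, sign)])] ----


def _chroms_to_genome(
    name: str, chroms: list[tuple[str, list[tuple[str, int]]]], families: dict[str, str]
) -> Genome:
    fams = {}
    adjacencies = []
    telomeres = []
    n_telo = 0
    for kind, content in chroms:
        if not content:
            continue
        ends: list[Extremity] = []
        for mid, sign in content:
            fams[mid] = families[mid]
            first = Extremity(mid, TAIL if sign > 0 else HEAD)
            last = Extremity(mid, HEAD if sign > 0 else TAIL)
            ends.append(first)
            ends.append(last)
        inner = ends[1:-1]
        for i in range(0, len(inner), 2):
            adjacencies.append((inner[i], inner[i + 1]))
        if kind == "linear":
            for e in (ends[0], ends[-1]):
                n_telo += 1
                t = Extremity(f"t{n_telo}", TELO)
                telomeres.append(t)
                adjacencies.append((t, e))
        else:
            adjacencies.append((ends[-1], ends[0]))
    return Genome(name, fams, adjacencies, telomeres)


class _Evolver:
    def __init__(self, config: SimulationConfig, rng: random.Random) -> None:
        self.cfg = config
        self.rng = rng
        self.families: dict[str, str] = {}
        self.copy_counter: dict[str, int] = {}
        self.n_insert_fams = 0

    def new_marker(self, family: str) -> str:
        self.copy_counter[family] = self.copy_counter.get(family, 0) + 1
        mid = f"{family}_{self.copy_counter[family]}"
        self.families[mid] = family
        return mid

    def root_genome(self) -> list[tuple[str, list[tuple[str, int]]]]:
        cfg = self.cfg
        ids = [self.new_marker(f"m{i+1}") for i in range(cfg.markers)]
        kind = "circular" if cfg.circular else "linear"
        chroms = []
        per = max(1, cfg.markers // cfg.chromosomes)
        for i in range(cfg.chromosomes):
            part = ids[i * per : (i + 1) * per] if i < cfg.chromosomes - 1 else ids[
                (cfg.chromosomes - 1) * per :
            ]
            if part:
                chroms.append((kind, [(m, 1) for m in part]))
        return chroms

    def _zipf(self, a: float) -> int:
        weights = [k ** (-a) for k in range(1, self.cfg.zipf_max + 1)]
        return self.rng.choices(range(1, self.cfg.zipf_max + 1), weights=weights)[0]

    # -- operations -----------------------------------------------------
    def _segment(self, chroms, length):
        """Random (chromosome index, start, actual length) of a contiguous
        segment; None when the genome is empty."""
        sizes = [len(c[1]) for c in chroms]
        total = sum(sizes)
        if total == 0:
            return None
        weights = [s / total for s in sizes]
        ci = self.rng.choices(range(len(chroms)), weights=weights)[0]
        kind, seq = chroms[ci]
        k = len(seq)
        cap = k if kind == "linear" else k - 1
        if cap == 0:
            if kind == "circular":
                return (ci, 0, k)  # whole circular chromosome
            return (ci, 0, 1)
        length = min(length, cap)
        start = self.rng.randrange(k)
        if kind == "linear":
            start = self.rng.randrange(k - length + 1)
        return (ci, start, length)

    @staticmethod
    def _cut(seq, kind, start, length):
        if kind == "linear" or start + length <= len(seq):
            return seq[start : start + length], seq[:start] + seq[start + length :]
        wrap = start + length - len(seq)
        return seq[start:] + seq[:wrap], seq[wrap:start]

    def duplicate(self, chroms) -> Optional[str]:
        pick = self._segment(chroms, self._zipf(self.cfg.zipf_dup))
        if pick is None:
            return None
        ci, start, length = pick
        kind, seq = chroms[ci]
        if length >= len(seq) and kind == "circular":
            length = max(1, len(seq) - 1)
        segment = (
            seq[start : start + length]
            if start + length <= len(seq)
            else seq[start:] + seq[: start + length - len(seq)]
        )
        copy = [(self.new_marker(self.families[m]), s) for m, s in segment]
        # tandem-free: never paste directly behind the template
        for _ in range(20):
            ti = self.rng.randrange(len(chroms))
            tkind, tseq = chroms[ti]
            pos = self.rng.randrange(len(tseq) + (1 if tkind == "linear" else 0))
            if ti == ci and start <= pos <= start + length:
                continue
            chroms[ti] = (tkind, tseq[:pos] + copy + tseq[pos:])
            return f"dup {len(segment)}"
        return None

    def delete(self, chroms) -> Optional[str]:
        pick = self._segment(chroms, self._zipf(self.cfg.zipf_indel))
        if pick is None:
            return None
        ci, start, length = pick
        kind, seq = chroms[ci]
        _, rest = self._cut(seq, kind, start, length)
        if rest:
            chroms[ci] = (kind, rest)
        else:
            del chroms[ci]
        return f"del {length}"

    def insert(self, chroms) -> Optional[str]:
        length = self._zipf(self.cfg.zipf_indel)
        self.n_insert_fams += 1
        fam = f"x{self.n_insert_fams}"
        block = [
            (self.new_marker(f"{fam}.{j}" if length > 1 else fam), 1)
            for j in range(length)
        ]
        if not chroms:
            chroms.append(("linear", block))
            return f"ins {length}"
        ti = self.rng.randrange(len(chroms))
        tkind, tseq = chroms[ti]
        pos = self.rng.randrange(len(tseq) + (1 if tkind == "linear" else 0))
        chroms[ti] = (tkind, tseq[:pos] + block + tseq[pos:])
        return f"ins {length}"

    def dcj(self, chroms) -> Optional[str]:
        """Uniform random DCJ on the adjacency graph representation."""
        genome = _chroms_to_genome("tmp", chroms, self.families)
        adjs = sorted(genome.adjacencies)
        if not adjs:
            return None
        rng = self.rng
        single_cut = rng.random() < 0.1 and any(
            not u.is_telomere and not v.is_telomere for u, v in adjs
        )
        new_adj = set(adjs)
        if single_cut or len(adjs) < 2:
            cuttable = [
                a for a in adjs if not a[0].is_telomere and not a[1].is_telomere
            ]
            if not cuttable:
                return None
            u, v = cuttable[rng.randrange(len(cuttable))]
            new_adj.discard((u, v) if u <= v else (v, u))
            new_adj.add((u, Extremity(f"tn1_{u.marker}{u.side}", TELO)))
            new_adj.add((v, Extremity(f"tn2_{v.marker}{v.side}", TELO)))
            kind = "cut"
        else:
            i, j = rng.sample(range(len(adjs)), 2)
            (a, b), (c, d) = adjs[i], adjs[j]
            if rng.random() < 0.5:
                joins = ((a, c), (b, d))
            else:
                joins = ((a, d), (b, c))
            for e in (adjs[i], adjs[j]):
                new_adj.discard(e)
            for u, v in joins:
                if u.is_telomere and v.is_telomere:
                    continue  # the two loose telomeres vanish
                new_adj.add((u, v) if u <= v else (v, u))
            kind = "dcj"
        telomeres = {w for e in new_adj for w in e if w.is_telomere}
        g = Genome("tmp", genome.families, new_adj, telomeres)
        chroms[:] = [
            (k, content) for k, content in g.chromosomes()
        ]
        return kind

    def branch(self, chroms) -> list[str]:
        cfg = self.cfg
        log: list[str] = []
        ops = 0
        attempts = 0
        while ops < cfg.ops_per_branch:
            attempts += 1
            if attempts > 50 * (cfg.ops_per_branch + 1):
                raise RuntimeError("too many inapplicable operations; giving up")
            r = self.rng.random()
            if r < cfg.dup_rate:
                res = self.duplicate(chroms)
            elif r < cfg.dup_rate + cfg.del_rate:
                res = self.delete(chroms)
            elif r < cfg.dup_rate + cfg.del_rate + cfg.ins_rate:
                res = self.insert(chroms)
            else:
                res = self.dcj(chroms)
            if res is not None:
                log.append(res)
                ops += 1
        return log


def evolve(config: SimulationConfig) -> GroundTruth:
    """Simulate genomes at every node of the configured topology."""
    config.validate()
    rng = random.Random(config.seed)
    phylo = parse_newick(config.tree)
    ev = _Evolver(config, rng)
    chroms_at: dict[str, list] = {phylo.root: ev.root_genome()}
    truth = GroundTruth(config=config, phylogeny=phylo)

    def copy_chroms(chroms):
        return [(k, list(seq)) for k, seq in chroms]

    for parent, child in _preorder_edges(phylo):
        chroms = copy_chroms(chroms_at[parent])
        truth.operations[(parent, child)] = ev.branch(chroms)
        chroms_at[child] = chroms
    for node in phylo.nodes:
        phylo.bind(_chroms_to_genome(node, chroms_at[node], ev.families))
    for node in phylo.internal:
        g = phylo.genome(node)
        truth.candidates[node] = DegenerateGenome(
            node, g.families, g.adjacencies, g.telomeres
        )
    return truth


def _preorder_edges(phylo: Phylogeny):
    out = []
    stack = [phylo.root]
    while stack:
        node = stack.pop()
        for child in sorted(phylo.children.get(node, []), reverse=True):
            out.append((node, child))
            stack.append(child)
    return out


def add_noise(truth: GroundTruth, k: Optional[int] = None, seed: Optional[int] = None) -> None:
    """Add ``k`` adversarial candidate adjacencies per internal node.

    Noise adjacencies join random marker extremity pairs that are not true
    adjacencies (and are not already candidates); true candidates are kept.
    """
    if k is None:
        k = truth.config.noise
    rng = random.Random(truth.config.seed + 7919 if seed is None else seed)
    for node in truth.phylogeny.internal:
        cand = truth.candidates[node]
        exts = cand.extremities()
        possible = len(exts) * (len(exts) - 1) // 2 - len(
            [a for a in cand.adjacencies if not a[0].is_telomere and not a[1].is_telomere]
        )
        if k > possible:
            raise ValueError(
                f"cannot draw {k} noise adjacencies at {node}: only {possible} "
                "non-true extremity pairs exist"
            )
        added = 0
        while added < k:
            u, v = rng.sample(exts, 2)
            key = (u, v) if u <= v else (v, u)
            if key in cand.adjacencies:
                continue
            cand.add_adjacency(u, v)
            added += 1


def simulate(config: SimulationConfig) -> GroundTruth:
    """Evolve genomes and add the configured noise in one call."""
    truth = evolve(config)
    if truth.config.noise:
        add_noise(truth)
    return truth


def random_genome(
    rng: random.Random,
    name: str,
    families: list[str],
    circular_prob: float = 0.3,
    max_chromosomes: int = 2,
) -> Genome:
    """A uniform random arrangement of the given family multiset into one or
    two chromosomes with random orientations (tiny-instance test helper)."""
    ev = _Evolver(SimulationConfig(), rng)
    seq = [(ev.new_marker(f), rng.choice((1, -1))) for f in families]
    rng.shuffle(seq)
    chroms = []
    if seq:
        n_chrom = rng.randint(1, min(max_chromosomes, len(seq)))
        cuts = sorted(rng.sample(range(1, len(seq)), n_chrom - 1)) if n_chrom > 1 else []
        prev = 0
        for cut in cuts + [len(seq)]:
            kind = "circular" if rng.random() < circular_prob else "linear"
            chroms.append((kind, seq[prev:cut]))
            prev = cut
    return _chroms_to_genome(name, chroms, ev.families)


# ---------------------------------------------------------------------------
# the five-marker illustration pair
# ---------------------------------------------------------------------------


def worked_example():
    """The canonical five-marker genome pair with its two homologies.

    Returns ``(genome_a, genome_b, families, matching)`` where ``families``
    is the unresolved homology (equal family labels) and ``matching`` the
    resolved refinement {1_1~1_3, 1_2~1_4, 2_1~2_2, 3_1~3_2} that leaves
    markers 4_1 and 5_1 singular.
    """
    from .genomes import parse_unimog

    genome_a, genome_b = parse_unimog(">A\n1 1 2 4 -3 |\n>B\n1 1 2 5 3 |")
    families = {
        "1": ["1_1", "1_2", "1_3", "1_4"],
        "2": ["2_1", "2_2"],
        "3": ["3_1", "3_2"],
        "4": ["4_1"],
        "5": ["5_1"],
    }
    matching = [("1_1", "1_3"), ("1_2", "1_4"), ("2_1", "2_2"), ("3_1", "3_2")]
    return genome_a, genome_b, families, matching
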