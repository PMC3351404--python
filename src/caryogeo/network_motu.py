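"""Statistical-parsimony haplotype networks, loop resolution and nesting.

The network connects haplotypes in increasing mutational distance while
the distance stays within a probabilistic parsimony limit; ties within a
distance class may create cycles ("loops") that are broken by an ordered
criterion cascade (haplotype frequency, interior-vs-tip topology,
geographic proximity, lexicographic). The acyclic network is then nested
into 1-step, 2-step, ... clades working inward from the tips, and MOTUs
(molecular operational taxonomic units) are read off a chosen nesting
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .errors import CaryogeoError
from .seq_data import (
    Alignment,
    HaplotypeIndex,
    great_circle_km,
    pairwise_differences,
)

__all__ = [
    "parsimony_connection_limit", "parsimony_probability",
    "build_parsimony_network", "resolve_loops", "ParsimonyNetwork",
    "build_nesting_design", "NestingDesign", "assign_motus",
]


# ---------------------------------------------------------------------------
# Connection limit
# ---------------------------------------------------------------------------

def parsimony_probability(j: int, length: int) -> float:
    """Probability that j observed differences over ``length`` sites arose
    without superimposed change.

    Per-site change counts are modelled as Poisson; a site differs between
    two haplotypes iff its count is odd. The divergence parameter is
    moment-matched from the observed proportion (j/length), and the
    parsimony probability is the conditional probability that every
    differing site changed exactly once and every identical site not at
    all.
    """
    if j < 0 or length <= 0:
        raise ValueError("need j >= 0 and length > 0")
    if j == 0:
        return 1.0
    q = 2.0 * j / length
    if q >= 1.0:
        return 0.0
    lam = -0.5 * math.log1p(-q)
    # P(X=1 | X odd) = lam / sinh(lam); P(X=0 | X even) = 1 / cosh(lam)
    log_p = j * (math.log(lam) - math.log(math.sinh(lam))) \
        - (length - j) * math.log(math.cosh(lam))
    return math.exp(log_p)


def parsimony_connection_limit(length: int, confidence: float = 0.95) -> int:
    """Largest step count whose parsimonious-connection probability
    exceeds ``confidence``. Single steps are always connectable."""
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    if length <= 0:
        raise ValueError("length must be positive")
    j = 1
    while j + 1 <= length // 2 and parsimony_probability(j + 1, length) > confidence:
        j += 1
    return j


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

@dataclass
class ParsimonyNetwork:
    """Haplotype graph; edges carry the mutational step count.

    ``graph`` is haplotype-level (edge attribute ``steps``); ``expanded()``
    inserts ``steps - 1`` zero-frequency intermediate nodes per multi-step
    edge so that every edge spans exactly one mutation.
    """

    graph: nx.Graph
    counts: Mapping[str, int]
    localities: Mapping[str, frozenset]
    removed_edges: tuple = field(default_factory=tuple)

    def components(self) -> list[frozenset]:
        return [frozenset(c) for c in nx.connected_components(self.graph)]

    def expanded(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.graph.nodes:
            g.add_node(node, kind="haplotype", count=self.counts.get(node, 0))
        k = 0
        for u, v, data in sorted(self.graph.edges(data=True)):
            steps = data.get("steps", 1)
            prev = u
            for _ in range(steps - 1):
                k += 1
                mid = f"_mv{k}"
                g.add_node(mid, kind="inferred", count=0)
                g.add_edge(prev, mid)
                prev = mid
            g.add_edge(prev, v)
        return g


def build_parsimony_network(index: HaplotypeIndex, max_steps: int,
                            aln: Alignment | None = None) -> ParsimonyNetwork:
    """Connect haplotypes in increasing distance order up to ``max_steps``.

    Distance classes are processed in ascending order; within a class,
    every pair whose endpoints lay in different components *at the start
    of the class* is connected (this is what introduces loops among
    equally parsimonious alternatives). Pairs beyond ``max_steps`` stay
    unconnected, so divergent haplotype groups form separate networks.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    hap_aln = aln if aln is not None else index.alignment()
    hap_aln = hap_aln.subset(index.labels)
    diff, _ = pairwise_differences(hap_aln)
    labels = list(hap_aln.ids)
    g = nx.Graph()
    for h in index.haplotypes:
        g.add_node(h.label)
    pairs_by_d: dict[int, list[tuple[str, str]]] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d = int(diff[i, j])
            if 1 <= d <= max_steps:
                pairs_by_d.setdefault(d, []).append((labels[i], labels[j]))
    for d in sorted(pairs_by_d):
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                comp_of[node] = ci
        for u, v in sorted(pairs_by_d[d]):
            if comp_of[u] != comp_of[v]:
                g.add_edge(u, v, steps=d)
    return ParsimonyNetwork(graph=g, counts=dict(zip(index.labels, index.counts)),
                            localities=index.locality_sets())


def _edge_removal_key(g: nx.Graph, u: str, v: str,
                      counts: Mapping[str, int],
                      localities: Mapping[str, frozenset],
                      coords: Mapping[str, tuple[float, float]] | None):
    steps = g.edges[u, v].get("steps", 1)
    freq_key = tuple(sorted((counts.get(u, 0), counts.get(v, 0))))
    interior = sum(1 for x in (u, v) if g.degree(x) > 2)
    if coords:
        locs_u = [coords[c] for c in localities.get(u, ()) if c in coords]
        locs_v = [coords[c] for c in localities.get(v, ()) if c in coords]
        if locs_u and locs_v:
            geo = min(great_circle_km(a, b) for a in locs_u for b in locs_v)
        else:
            geo = 0.0
    else:
        geo = 0.0
    # remove the edge with: most mutational steps (longest ambiguous
    # connection), then lowest endpoint frequencies, fewest interior
    # endpoints, largest geographic separation, smallest label
    return (-steps, freq_key, interior, -geo, tuple(sorted((u, v))))


def resolve_loops(net: ParsimonyNetwork,
                  coords: Mapping[str, tuple[float, float]] | None = None
                  ) -> ParsimonyNetwork:
    """Break every cycle by removing one edge per cycle.

    The longest connection in the cycle (most mutational steps) is
    removed first — alternative connections of unequal length are not
    equally parsimonious. Among equal-length alternatives the criterion
    cascade is (first decisive wins): (1) retain connections to
    higher-frequency haplotypes, (2) retain connections to interior
    (degree > 2) haplotypes, (3) retain geographically closer pairs when
    ``coords`` (locality code -> (lat, lon)) is given, (4) remove the
    lexicographically smallest edge. Idempotent on acyclic input; every
    removal is logged.
    """
    g = net.graph.copy()
    removed = list(net.removed_edges)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        keyed = sorted(
            (_edge_removal_key(g, u, v, net.counts, net.localities, coords),
             (u, v))
            for u, v, *_ in [(e[0], e[1]) for e in cycle]
        )
        key, (u, v) = keyed[0]
        tie = len(keyed) > 1 and keyed[1][0][:4] == key[:4]
        g.remove_edge(u, v)
        removed.append({"edge": tuple(sorted((u, v))),
                        "cycle": [tuple(sorted((e[0], e[1]))) for e in cycle],
                        "tie_broken_lexicographically": tie})
    return ParsimonyNetwork(graph=g, counts=net.counts,
                            localities=net.localities,
                            removed_edges=tuple(removed))


# ---------------------------------------------------------------------------
# Nesting design and MOTUs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NestingDesign:
    """Hierarchical clades over network nodes (intermediates included).

    ``levels[k]`` is a partition of all nodes into k-step clades; level 0
    is the trivial singleton partition. Every level-k clade is a union of
    level-(k-1) clades.
    """

    levels: tuple[tuple[frozenset, ...], ...]
    counts: Mapping[str, int]
    haplotype_labels: frozenset

    @property
    def max_level(self) -> int:
        return len(self.levels) - 1

    def clades(self, level: int) -> tuple[frozenset, ...]:
        if not (0 <= level <= self.max_level):
            raise ValueError(f"level {level} outside design (max {self.max_level})")
        return self.levels[level]


def _nest_once(g: nx.Graph) -> list[set]:
    """One nesting pass: group nodes into clades working inward from tips."""
    remaining = set(g.nodes)
    clades: list[set] = []
    while remaining:
        sub = g.subgraph(remaining)
        isolated = sorted(n for n in remaining if sub.degree(n) == 0)
        for n in isolated:
            clades.append({n})
            remaining.discard(n)
        if not remaining:
            break
        sub = g.subgraph(remaining)
        tips = sorted(n for n in remaining if sub.degree(n) == 1)
        if not tips:
            # residual cycle; should not occur on resolved networks
            clades.append(set(remaining))
            break
        centers: dict = {}
        paired: set = set()
        for t in tips:
            if t in paired:
                continue
            nb = sorted(sub.neighbors(t))[0]
            if nb in tips:
                # two adjacent tips (an isolated 2-chain): one clade
                center = min(t, nb)
                centers.setdefault(center, set()).update({t, nb})
                paired.update({t, nb})
            else:
                centers.setdefault(nb, set()).add(t)
                paired.add(t)
        for center, members in sorted(centers.items()):
            clade = set(members) | {center}
            clade &= remaining  # guard against double assignment
            if clade:
                clades.append(clade)
                remaining -= clade
    return clades


def build_nesting_design(net: ParsimonyNetwork, max_level: int
                         ) -> NestingDesign:
    """Nest the (acyclic, loop-resolved) network into hierarchical clades.

    Works on the intermediate-expanded unit-step graph so that clade
    boundaries respect mutational steps. Leftover interior nodes that no
    tip pass reaches form their own singleton clades at that level and
    merge at the next one.
    """
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    base = net.expanded()
    try:
        nx.find_cycle(base)
        raise CaryogeoError("nesting requires a loop-resolved (acyclic) network")
    except nx.NetworkXNoCycle:
        pass
    levels: list[tuple[frozenset, ...]] = [
        tuple(sorted((frozenset({n}) for n in base.nodes), key=sorted))
    ]
    current = levels[0]
    for _ in range(max_level):
        # clade graph: nodes = current clades, edges where members touch
        cg = nx.Graph()
        node_clade = {}
        for clade in current:
            cg.add_node(clade)
            for n in clade:
                node_clade[n] = clade
        for u, v in base.edges:
            cu, cv = node_clade[u], node_clade[v]
            if cu != cv:
                cg.add_edge(cu, cv)
        grouped = _nest_once(cg)
        new_level = tuple(sorted(
            (frozenset().union(*group) for group in grouped), key=sorted))
        levels.append(new_level)
        current = new_level
    return NestingDesign(levels=tuple(levels), counts=dict(net.counts),
                         haplotype_labels=frozenset(net.counts))


def assign_motus(design: NestingDesign, level: int,
                 prefix: str = "MOTU") -> dict[str, str]:
    """Map haplotype label -> MOTU label from the clades at ``level``.

    MOTUs are numbered by decreasing total haplotype frequency (ties by
    smallest member label); clades containing only inferred intermediates
    are dropped. Disconnected networks never share a clade, so they are
    distinct MOTUs at every level.
    """
    clades = design.clades(level)
    keep = []
    for clade in clades:
        haps = sorted(clade & design.haplotype_labels)
        if haps:
            total = sum(design.counts.get(h, 0) for h in haps)
            keep.append((-total, haps[0], haps))
    keep.sort()
    out: dict[str, str] = {}
    for i, (_, _, haps) in enumerate(keep, start=1):
        for h in haps:
            out[h] = f"{prefix}{i}"
    return out
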