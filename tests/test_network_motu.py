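import itertools
import math

import networkx as nx
import numpy as np
import pytest

from caryogeo.network_motu import (
    assign_motus,
    build_nesting_design,
    build_parsimony_network,
    parsimony_connection_limit,
    parsimony_probability,
    resolve_loops,
)
from caryogeo.seq_data import Alignment, HaplotypeIndex, Haplotype, collapse_haplotypes

from _oracles import min_spanning_weight


def index_from_seqs(seqs: dict[str, str], counts: dict[str, int] | None = None,
                    locs: dict[str, frozenset] | None = None) -> HaplotypeIndex:
    haps = []
    for label, seq in seqs.items():
        c = (counts or {}).get(label, 1)
        occ = {next(iter(locs[label])): c} if locs and label in locs else {"L": c}
        haps.append(Haplotype(label=label, sequence=seq, count=c,
                              occurrences=occ))
    return HaplotypeIndex(haplotypes=tuple(haps))


class TestConnectionLimit:
    def test_single_step_always_connectable(self):
        for length in (10, 100, 590):
            assert parsimony_connection_limit(length, 0.95) >= 1

    def test_probability_decreases_with_steps(self):
        probs = [parsimony_probability(j, 590) for j in range(1, 15)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_higher_confidence_tightens_limit(self):
        assert (parsimony_connection_limit(590, 0.99)
                <= parsimony_connection_limit(590, 0.95))

    def test_longer_sequences_loosen_limit(self):
        assert (parsimony_connection_limit(1200, 0.95)
                >= parsimony_connection_limit(300, 0.95))

    def test_independent_transcription_of_probability_model(self):
        # oracle: same probability model written directly
        for j, m in [(1, 590), (5, 590), (9, 590), (3, 100)]:
            lam = -0.5 * math.log(1 - 2 * j / m)
            p = (lam / math.sinh(lam)) ** j * (1 / math.cosh(lam)) ** (m - j)
            assert math.isclose(parsimony_probability(j, m), p, rel_tol=1e-12)

    def test_bad_confidence(self):
        with pytest.raises(ValueError):
            parsimony_connection_limit(590, 1.5)


class TestNetworkConstruction:
    def test_single_edge(self):
        idx = index_from_seqs({"A": "AAAA", "B": "AAAT"})
        net = build_parsimony_network(idx, max_steps=5)
        assert set(net.graph.edges) == {("A", "B")}

    def test_chain_no_redundant_edge(self):
        # A-B=1, B-C=1, A-C=2: the 2-step pair is already connected
        idx = index_from_seqs({"A": "AAAA", "B": "AAAT", "C": "AATT"})
        net = build_parsimony_network(idx, max_steps=5)
        assert set(net.graph.edges) == {("A", "B"), ("B", "C")}

    def test_beyond_limit_stays_disconnected(self):
        idx = index_from_seqs({"A": "AAAAAA", "B": "TTTTTT"})
        net = build_parsimony_network(idx, max_steps=3)
        assert len(net.components()) == 2

    def test_intermediates_inserted(self):
        idx = index_from_seqs({"A": "AAAA", "B": "AATT"})
        net = build_parsimony_network(idx, max_steps=5)
        g = net.expanded()
        inferred = [n for n, d in g.nodes(data=True) if d["kind"] == "inferred"]
        assert len(inferred) == 1
        assert nx.shortest_path_length(g, "A", "B") == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_minimal_network_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        # distinct random haplotypes over a short region
        seqs = {}
        while len(seqs) < n:
            s = "".join("ACGT"[b] for b in rng.integers(0, 4, size=8))
            seqs.setdefault(f"H{len(seqs)+1}", s) if s not in seqs.values() else None
        idx = index_from_seqs(seqs)
        net = resolve_loops(build_parsimony_network(idx, max_steps=8))
        # oracle: exhaustive minimal spanning weight per component
        labels = sorted(seqs)
        dist = {}
        for a, b in itertools.combinations(labels, 2):
            dist[(a, b)] = sum(x != y for x, y in zip(seqs[a], seqs[b]))
        oracle = min_spanning_weight(labels, dist, max_steps=8)
        comps = {frozenset(c) for c in net.components()}
        assert comps == set(oracle)
        for comp in comps:
            w = sum(d["steps"] for u, v, d in net.graph.edges(data=True)
                    if u in comp)
            assert w == oracle[comp]
        # resolved network is acyclic
        with pytest.raises(nx.NetworkXNoCycle):
            nx.find_cycle(net.graph)


class TestLoopResolution:
    def _square(self, counts):
        # 4-cycle A-B-C-D-A, all edges one step
        seqs = {"A": "AAAA", "B": "AAAT", "C": "AATT", "D": "AATA"}
        idx = index_from_seqs(seqs, counts=counts)
        net = build_parsimony_network(idx, max_steps=4)
        assert len(nx.cycle_basis(net.graph)) == 1
        return net

    def test_low_frequency_edge_removed(self):
        net = self._square({"A": 10, "B": 1, "C": 1, "D": 1})
        resolved = resolve_loops(net)
        removed = resolved.removed_edges[0]["edge"]
        assert "A" not in removed  # high-frequency node keeps its links

    def test_acyclic_input_unchanged(self):
        idx = index_from_seqs({"A": "AAAA", "B": "AAAT", "C": "AATT"})
        net = build_parsimony_network(idx, max_steps=4)
        resolved = resolve_loops(net)
        assert set(resolved.graph.edges) == set(net.graph.edges)
        assert resolved.removed_edges == ()

    def test_idempotent(self):
        net = self._square({"A": 2, "B": 2, "C": 2, "D": 2})
        once = resolve_loops(net)
        twice = resolve_loops(once)
        assert set(once.graph.edges) == set(twice.graph.edges)

    def test_all_tied_removes_lexicographically_smallest(self):
        net = self._square({"A": 1, "B": 1, "C": 1, "D": 1})
        resolved = resolve_loops(net)
        rec = resolved.removed_edges[0]
        assert rec["edge"] == ("A", "B")
        assert rec["tie_broken_lexicographically"]


class TestNesting:
    def _design(self, seqs, max_level=3, counts=None):
        idx = index_from_seqs(seqs, counts=counts)
        net = resolve_loops(build_parsimony_network(idx, max_steps=10))
        return build_nesting_design(net, max_level=max_level)

    def test_star_one_clade(self):
        d = self._design({"C": "AAAA", "T1": "AAAT", "T2": "AAAG"},
                         max_level=1)
        assert d.clades(1) == (frozenset({"C", "T1", "T2"}),)

    def test_five_chain_level_structure(self):
        d = self._design({"A": "AAAAA", "B": "AAAAT", "C": "AAATT",
                          "D": "AATTT", "E": "ATTTT"}, max_level=2)
        lvl1 = set(d.clades(1))
        assert lvl1 == {frozenset({"A", "B"}), frozenset({"C"}),
                        frozenset({"D", "E"})}
        assert set(d.clades(2)) == {frozenset({"A", "B", "C", "D", "E"})}

    def test_single_haplotype(self):
        d = self._design({"A": "AAAA"}, max_level=3)
        for lvl in range(4):
            assert d.clades(lvl) == (frozenset({"A"}),)

    def test_levels_form_proper_hierarchy(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            n = int(rng.integers(4, 9))
            seqs = {}
            while len(seqs) < n:
                s = "".join("ACGT"[b] for b in rng.integers(0, 4, size=10))
                if s not in seqs.values():
                    seqs[f"H{len(seqs)+1}"] = s
            d = self._design(seqs, max_level=4)
            for k in range(1, d.max_level + 1):
                lower = d.clades(k - 1)
                for clade in d.clades(k):
                    parts = [c for c in lower if c <= clade]
                    assert frozenset().union(*parts) == clade

    def test_requires_acyclic(self):
        seqs = {"A": "AAAA", "B": "AAAT", "C": "AATT", "D": "AATA"}
        net = build_parsimony_network(index_from_seqs(seqs), max_steps=4)
        from caryogeo.errors import CaryogeoError
        with pytest.raises(CaryogeoError):
            build_nesting_design(net, max_level=2)


class TestMotus:
    def test_chain_level1_three_motus(self):
        idx = index_from_seqs({"A": "AAAAA", "B": "AAAAT", "C": "AAATT",
                               "D": "AATTT", "E": "ATTTT"},
                              counts={"A": 5, "B": 1, "C": 1, "D": 1, "E": 1})
        net = resolve_loops(build_parsimony_network(idx, max_steps=10))
        design = build_nesting_design(net, max_level=2)
        motus = assign_motus(design, 1)
        assert len(set(motus.values())) == 3
        # numbering follows decreasing total frequency
        assert motus["A"] == "MOTU1"

    def test_full_depth_single_motu(self):
        idx = index_from_seqs({"A": "AAAA", "B": "AAAT"})
        net = resolve_loops(build_parsimony_network(idx, max_steps=4))
        design = build_nesting_design(net, max_level=2)
        assert set(assign_motus(design, 2).values()) == {"MOTU1"}

    def test_disconnected_networks_distinct_motus(self):
        idx = index_from_seqs({"A": "AAAAAA", "B": "TTTTTT"})
        net = resolve_loops(build_parsimony_network(idx, max_steps=2))
        design = build_nesting_design(net, max_level=3)
        motus = assign_motus(design, 3)
        assert motus["A"] != motus["B"]

    def test_level_beyond_design_raises(self):
        idx = index_from_seqs({"A": "AAAA", "B": "AAAT"})
        net = resolve_loops(build_parsimony_network(idx, max_steps=4))
        design = build_nesting_design(net, max_level=1)
        with pytest.raises(ValueError):
            assign_motus(design, 5)
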