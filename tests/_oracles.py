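"""Independent oracle implementations used only by the tests.

Each oracle is written directly from the defining formulas or by
exhaustive enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math


# ---------------------------------------------------------------------------
# Tajima's D, transcribed formula by formula
# ---------------------------------------------------------------------------

def tajimas_d_oracle(seqs: list[str]) -> float:
    """D from raw sequences; complete-deletion sites; None when S = 0."""
    n = len(seqs)
    length = len(seqs[0])
    cols = [
        [s[j] for s in seqs]
        for j in range(length)
        if all(s[j] in "ACGT" for s in seqs)
    ]
    S = sum(1 for col in cols if len(set(col)) > 1)
    if S == 0:
        return None
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(1 for col in cols if col[i] != col[j])
    kbar = total / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i / i for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (kbar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


# ---------------------------------------------------------------------------
# Nucleotide diversity by brute-force double loop
# ---------------------------------------------------------------------------

def pi_oracle(seqs: list[str]) -> float:
    """Mean per-pair per-site difference proportion, pairwise deletion."""
    n = len(seqs)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            diff = valid = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in "ACGT" and b in "ACGT":
                    valid += 1
                    if a != b:
                        diff += 1
            if valid:
                vals.append(diff / valid)
    return sum(vals) / len(vals)


# ---------------------------------------------------------------------------
# MPR root states by exhaustive internal-labeling enumeration
# ---------------------------------------------------------------------------
# Trees are nested tuples: a leaf is a string label, an internal node a
# tuple of child subtrees.

def _internal_nodes(tree) -> list:
    if isinstance(tree, str):
        return []
    out = [tree]
    for child in tree:
        out.extend(_internal_nodes(child))
    return out


def mpr_root_states(tree, tip_states: dict[str, frozenset],
                    states: list[str]) -> frozenset:
    """Root states attaining the minimal number of state changes.

    Tips pick the cheapest member of their state set given the parent
    state; internal labelings are enumerated exhaustively.
    """
    internals = _internal_nodes(tree)

    def cost(node, parent_state, assignment):
        if isinstance(node, str):
            return 0 if parent_state in tip_states[node] else 1
        own = assignment[id(node)]
        c = 0 if parent_state is None or own == parent_state else 1
        return c + sum(cost(ch, own, assignment) for ch in node)

    best = math.inf
    winners: dict[str, float] = {}
    for combo in itertools.product(states, repeat=len(internals)):
        assignment = {id(node): st for node, st in zip(internals, combo)}
        c = cost(tree, None, assignment)
        root_state = combo[0]
        winners[root_state] = min(winners.get(root_state, math.inf), c)
        best = min(best, c)
    return frozenset(s for s, c in winners.items() if c == best)


def all_rooted_topologies(labels: tuple[str, ...]):
    """All rooted binary tree shapes over the given labeled tips."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    # split: first goes left; enumerate subsets of rest joining it
    for r in range(len(rest)):
        for left_rest in itertools.combinations(rest, r):
            right = tuple(x for x in rest if x not in left_rest)
            if not right:
                continue
            for lt in all_rooted_topologies((first,) + left_rest):
                for rt in all_rooted_topologies(right):
                    yield (lt, rt)


def tree_to_newick(tree) -> str:
    if isinstance(tree, str):
        return tree
    return "(" + ",".join(tree_to_newick(c) for c in tree) + ")"


# ---------------------------------------------------------------------------
# Minimal spanning network by exhaustive spanning-tree search
# ---------------------------------------------------------------------------

def min_spanning_weight(nodes: list[str],
                        dist: dict[tuple[str, str], int],
                        max_steps: int) -> dict[frozenset, int]:
    """Per connected component: minimal spanning-tree weight.

    Components are defined by distances <= max_steps; within each, all
    spanning trees are enumerated (edge subsets of size n-1 that connect
    all nodes) and the minimal total weight returned.
    """
    edges = [(a, b) for (a, b) in dist if dist[(a, b)] <= max_steps]
    # components via repeated traversal
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    comps = []
    for n in nodes:
        if n in seen:
            continue
        stack, comp = [n], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(comp)
    out = {}
    for comp in comps:
        if len(comp) == 1:
            out[frozenset(comp)] = 0
            continue
        comp_edges = [e for e in edges if e[0] in comp and e[1] in comp]
        best = math.inf
        for subset in itertools.combinations(comp_edges, len(comp) - 1):
            reach = {next(iter(comp))}
            grew = True
            while grew:
                grew = False
                for a, b in subset:
                    if (a in reach) != (b in reach):
                        reach |= {a, b}
                        grew = True
            if reach == comp:
                best = min(best, sum(dist[e] for e in subset))
        out[frozenset(comp)] = best
    return out
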