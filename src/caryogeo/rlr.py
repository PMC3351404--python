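"""Refugium localization reconstruction (RLR) and Bayes-factor utilities.

RLR infers the ancestral locality of a lineage's most recent common
ancestor. Each sampling locality (optionally pooled with adjacent ones)
is a discrete character assigned to the tips of a sample of rooted
coalescent genealogies; a parsimonious dispersal model (rare colonization,
island-style movement, negligible secondary gene flow) lets the dispersal
history be traced backward along each genealogy by Fitch parsimony. When
a genealogy's root state set contains n equally parsimonious characters,
each receives weight w = 1/n; the relative probability score of a
character is the sum of its weights across trees divided by the number of
trees, reported on a 0-100 percent scale.

The module also provides the harmonic-mean marginal-likelihood estimator
and the Bayes-factor comparison (decimal-log scale, Jeffreys grades)
used to choose between demographic models for tree sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.special import logsumexp

from .errors import TreeError
from .seq_data import LocalityTable

__all__ = [
    "TreeSample", "read_tree_sample", "pool_localities",
    "fitch_root_states", "RootStateWeights", "rps_scores", "RPSResult",
    "harmonic_mean_log_ml", "bayes_factor", "BFResult",
]


@dataclass(frozen=True)
class TreeSample:
    """Rooted genealogies plus the tip -> character-set map."""

    trees: tuple
    tip_states: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("empty tree sample")
        for label, states in self.tip_states.items():
            if not states:
                raise TreeError(f"tip {label!r} has an empty character set")

    def __len__(self) -> int:
        return len(self.trees)


def _is_rooted(tree: dendropy.Tree) -> bool:
    if tree.is_rooted:
        return True
    # a bifurcating seed node on an un-flagged newick is accepted as rooted
    return len(tree.seed_node.child_nodes()) == 2


def read_tree_sample(path: str | Path,
                     tip_states: Mapping[str, Sequence[str]] | None = None,
                     burnin_fraction: float = 0.0,
                     subsample: int | None = None,
                     seed: int = 0,
                     schema: str | None = None) -> TreeSample:
    """Read rooted trees (Newick or NEXUS), drop burn-in, subsample.

    The first ``burnin_fraction`` of trees is discarded; ``subsample``
    trees are then drawn uniformly without replacement (original order
    preserved) with the given seed. Unrooted trees are rejected.
    ``tip_states`` maps tip labels to character (locality) sets; if
    omitted, each tip is its own single-state character.
    """
    path = Path(path)
    if schema is None:
        schema = "nexus" if path.suffix.lower() in (".nex", ".nexus", ".trees") \
            else "newick"
    trees = dendropy.TreeList.get(path=str(path), schema=schema,
                                  preserve_underscores=True)
    if not trees:
        raise TreeError(f"no trees in {path}")
    for i, t in enumerate(trees):
        if not _is_rooted(t):
            raise TreeError(f"tree {i} in {path} is not rooted")
    if not (0.0 <= burnin_fraction < 1.0):
        raise TreeError("burnin_fraction must be in [0, 1)")
    start = int(len(trees) * burnin_fraction)
    kept = list(trees[start:])
    if subsample is not None:
        if subsample > len(kept):
            raise TreeError(
                f"requested {subsample} trees but only {len(kept)} remain "
                "after burn-in")
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(kept), size=subsample, replace=False))
        kept = [kept[i] for i in idx]
    labels = {leaf.taxon.label for t in kept for leaf in t.leaf_node_iter()}
    if tip_states is None:
        states = {lab: frozenset({lab}) for lab in labels}
    else:
        missing = labels - set(tip_states)
        if missing:
            raise TreeError(f"tips without character states: {sorted(missing)}")
        states = {lab: frozenset(tip_states[lab]) for lab in labels}
    return TreeSample(trees=tuple(kept), tip_states=states)


def pool_localities(pooling: Mapping[str, str],
                    table: LocalityTable | None = None,
                    codes: Sequence[str] | None = None) -> dict[str, str]:
    """Relabel locality codes to pooled characters.

    Every code carrying data must appear in ``pooling`` (identity entries
    allowed); with ``table`` given, occupied codes are checked. Codes not
    in the map raise; use an identity map for unpooled analyses.
    """
    if table is not None:
        codes = [r.code for r in table if r.n]
    if codes is None:
        raise ValueError("need a LocalityTable or an explicit code list")
    missing = [c for c in codes if c not in pooling]
    if missing:
        raise TreeError(f"locality codes absent from pooling map: {missing}")
    return {c: pooling[c] for c in codes}


def read_pooling_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: locality code -> pooled character."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code, char = line.split("\t")[:2]
            out[code.strip()] = char.strip()
    return out


@dataclass(frozen=True)
class RootStateWeights:
    states: frozenset
    n: int
    weight: float  # 1/n per state

    def __post_init__(self) -> None:
        if self.n != len(self.states) or self.n == 0:
            raise TreeError("inconsistent root state set")


def fitch_root_states(tree: dendropy.Tree,
                      tip_states: Mapping[str, frozenset]) -> RootStateWeights:
    """Generalized Fitch bottom-up pass; returns the root state set.

    Binary nodes take the intersection of child sets when non-empty, else
    the union. Multifurcations generalize this: the states attaining the
    maximum number of child-set occurrences are kept. Tips may carry
    multi-state sets (haplotypes observed at several pooled localities).
    """
    sets: dict = {}
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if not children:
            label = node.taxon.label if node.taxon else None
            if label is None or label not in tip_states:
                raise TreeError(f"tip without character states: {label!r}")
            s = frozenset(tip_states[label])
            if not s:
                raise TreeError(f"tip {label!r} has an empty character set")
            sets[node] = s
        else:
            counts: dict = {}
            for ch in children:
                for st in sets[ch]:
                    counts[st] = counts.get(st, 0) + 1
            top = max(counts.values())
            sets[node] = frozenset(s for s, c in counts.items() if c == top)
    root_set = sets[tree.seed_node]
    return RootStateWeights(states=root_set, n=len(root_set),
                            weight=1.0 / len(root_set))


@dataclass(frozen=True)
class RPSResult:
    """Per-character relative probability scores on a 0-100 scale."""

    scores: Mapping[str, float]
    n_trees: int

    def top(self) -> tuple[str, float]:
        best = max(self.scores.items(), key=lambda kv: (kv[1], kv[0]))
        return best


def rps_scores(sample: TreeSample,
               characters: Sequence[str] | None = None) -> RPSResult:
    """Relative probability score per character across the tree sample.

    RPS(c) = 100 * sum over trees of the root weight of c, divided by the
    number of trees. All characters are reported, zeros included; scores
    sum to 100.
    """
    all_chars = set()
    for s in sample.tip_states.values():
        all_chars |= s
    if characters is not None:
        all_chars |= set(characters)
    acc = {c: 0.0 for c in sorted(all_chars)}
    for tree in sample.trees:
        rw = fitch_root_states(tree, sample.tip_states)
        for st in rw.states:
            acc[st] += rw.weight
    n = len(sample.trees)
    return RPSResult(scores={c: 100.0 * v / n for c, v in acc.items()},
                     n_trees=n)


# ---------------------------------------------------------------------------
# Harmonic-mean marginal likelihood and Bayes factors
# ---------------------------------------------------------------------------

def harmonic_mean_log_ml(log_likelihoods: Sequence[float]) -> float:
    """Log marginal likelihood via the harmonic mean of likelihoods.

    Computed stably in log space: -(logsumexp(-l) - log N). Burn-in must
    be removed beforehand.
    """
    ll = np.asarray(log_likelihoods, dtype=float)
    if ll.size < 2:
        raise ValueError("need at least two likelihood samples")
    return float(-(logsumexp(-ll) - math.log(ll.size)))


@dataclass(frozen=True)
class BFResult:
    log_ml_a: float
    log_ml_b: float
    log10_bf: float
    call: str  # none | substantial | strong | decisive
    favored: str  # "A", "B" or "neither"


def bayes_factor(log_ml_a: float, log_ml_b: float,
                 labels: tuple[str, str] = ("A", "B")) -> BFResult:
    """Bayes factor on the decimal-log scale with Jeffreys grades.

    Natural-log marginal likelihoods in, log10 BF out; |log10 BF| in
    (1/2, 1] is substantial, (1, 2] strong, > 2 decisive evidence for the
    favored model.
    """
    for v in (log_ml_a, log_ml_b):
        if not math.isfinite(v):
            raise ValueError("marginal-likelihood estimates must be finite")
    log10_bf = (log_ml_a - log_ml_b) / math.log(10.0)
    mag = abs(log10_bf)
    if mag > 2.0:
        call = "decisive"
    elif mag > 1.0:
        call = "strong"
    elif mag > 0.5:
        call = "substantial"
    else:
        call = "none"
    favored = "neither" if log10_bf == 0 else (labels[0] if log10_bf > 0
                                               else labels[1])
    return BFResult(log_ml_a=log_ml_a, log_ml_b=log_ml_b,
                    log10_bf=log10_bf, call=call, favored=favored)
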