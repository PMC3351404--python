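"""Haplotype and nucleotide diversity summaries.

Haplotype diversity uses the unbiased estimator
``H = n/(n-1) * (1 - sum p_i^2)`` with haplotype frequencies
``p_i = c_i / n``. Nucleotide diversity (pi) is the mean over all pairs of
the per-site proportion of differences under pairwise deletion, i.e. each
pair contributes ``diff_ij / valid_ij`` computed over its own complete
sites. Samples of size one carry not-calculable markers (NaN), never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import NotCalculable
from .seq_data import Alignment, HaplotypeIndex, LocalityTable, pairwise_differences


@dataclass(frozen=True)
class DiversityStats:
    n: int
    k: int
    H: float  # NaN when not calculable
    pi: float  # NaN when not calculable

    def formatted(self) -> dict[str, str]:
        fmt = lambda x: "n/a" if math.isnan(x) else f"{x:.4f}"
        return {"n": str(self.n), "k": str(self.k),
                "H": fmt(self.H), "pi": fmt(self.pi)}


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Unbiased haplotype (gene) diversity from haplotype counts."""
    if any(c <= 0 for c in counts):
        raise ValueError("haplotype counts must be positive")
    n = sum(counts)
    if n < 2:
        raise NotCalculable("haplotype diversity needs n >= 2")
    p2 = sum((c / n) ** 2 for c in counts)
    return n / (n - 1) * (1.0 - p2)


def nucleotide_diversity(aln: Alignment) -> float:
    """Mean per-site pairwise difference proportion (pairwise deletion)."""
    if aln.n < 2:
        raise NotCalculable("nucleotide diversity needs n >= 2")
    diff, valid = pairwise_differences(aln)
    iu = np.triu_indices(aln.n, k=1)
    d, v = diff[iu], valid[iu]
    comparable = v > 0
    if not comparable.any():
        raise NotCalculable("all pairs incomparable under pairwise deletion")
    return float((d[comparable] / v[comparable]).mean())


def alignment_diversity(aln: Alignment) -> DiversityStats:
    """n, distinct-haplotype count, H and pi for one alignment."""
    k = len(set(aln.sequences))
    if aln.n < 2:
        return DiversityStats(n=aln.n, k=k, H=float("nan"), pi=float("nan"))
    counts = [aln.sequences.count(s) for s in dict.fromkeys(aln.sequences)]
    return DiversityStats(n=aln.n, k=k, H=haplotype_diversity(counts),
                          pi=nucleotide_diversity(aln))


def per_locality_summary(index: HaplotypeIndex, table: LocalityTable
                         ) -> pd.DataFrame:
    """Per-locality n, H and pi from haplotype occurrences.

    Pi is computed over the multiset of specimen sequences present at the
    locality (each haplotype repeated by its local count). Localities with
    a single specimen yield NaN markers, matching the n/a convention.
    """
    known = set(table.codes)
    per_loc: dict[str, list[tuple[str, int]]] = {}
    for h in index.haplotypes:
        for code, c in h.occurrences.items():
            if code not in known:
                from .errors import MappingError
                raise MappingError(f"occurrence at unknown locality code {code!r}")
            per_loc.setdefault(code, []).append((h.label, c))
    rows = []
    for code in table.codes:
        if code not in per_loc:
            continue
        haps = per_loc[code]
        n = sum(c for _, c in haps)
        if n < 2:
            rows.append({"code": code, "n": n, "H": float("nan"), "pi": float("nan")})
            continue
        H = haplotype_diversity([c for _, c in haps])
        ids, seqs = [], []
        for label, c in haps:
            seq = index.by_label(label).sequence
            for j in range(c):
                ids.append(f"{label}_{code}_{j}")
                seqs.append(seq)
        local = Alignment(ids=tuple(ids), sequences=tuple(seqs),
                          length=len(seqs[0]))
        rows.append({"code": code, "n": n, "H": H,
                     "pi": nucleotide_diversity(local)})
    return pd.DataFrame(rows, columns=["code", "n", "H", "pi"])


def dataset_summary(table: LocalityTable) -> dict:
    """Whole-table tallies: per-species totals, locality counts, sympatry.

    Sympatry fraction = share of occupied localities where every species in
    the table is present, rounded to a whole percent.
    """
    totals = {sp: 0 for sp in table.species}
    loc_counts = {sp: 0 for sp in table.species}
    per_loc_n: list[int] = []
    occupied = 0
    sympatric = 0
    for row in table:
        present = [sp for sp in table.species if sp in row.n]
        if not present:
            continue
        occupied += 1
        if len(present) == len(table.species):
            sympatric += 1
        for sp in present:
            totals[sp] += row.n[sp]
            loc_counts[sp] += 1
            per_loc_n.append(row.n[sp])
    return {
        "species": list(table.species),
        "total_specimens": sum(totals.values()),
        "totals": totals,
        "locality_counts": loc_counts,
        "n_localities": occupied,
        "min_n": min(per_loc_n) if per_loc_n else 0,
        "max_n": max(per_loc_n) if per_loc_n else 0,
        "mean_n": (sum(per_loc_n) / len(per_loc_n)) if per_loc_n else float("nan"),
        "sympatry_percent": round(100 * sympatric / occupied) if occupied else 0,
    }
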