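"""Neutrality and demographic-history statistics.

Implements the frequency-spectrum tests used to detect population
expansion in mtDNA samples:

* Tajima's D from segregating sites and mean pairwise differences
  (complete-deletion sites, so the observed statistic matches its
  gap-free simulation null).
* Fu's Fs via the Ewens sampling formula: with theta-hat = mean pairwise
  differences, S' = Pr(K >= k_obs | theta-hat, n) and Fs = ln(S'/(1-S')).
* Coalescent-simulation p-values for both statistics under a neutral
  constant-size null, conditioned on the observed number of segregating
  sites by default (mutations placed multinomially on the genealogy) or
  on theta-hat (Poisson placement).
* Mismatch distributions, the sudden-expansion expectation (Poisson smear
  of the equilibrium geometric; the infinite-growth simplification is the
  default), least-squares fitting of (tau, theta0), Harpending's
  raggedness index and its parametric-bootstrap p-value.
* McDonald-Kreitman 2x2 counts of synonymous/non-synonymous changes
  partitioned into within-species polymorphism and between-species fixed
  differences.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import AlignmentError, NotCalculable
from .seq_data import (
    Alignment,
    complete_deletion_columns,
    mean_pairwise_differences,
    segregating_sites,
    translate_codons,
)
from Bio.Data import CodonTable

__all__ = [
    "tajima_constants", "tajimas_d", "ewens_pmf", "fus_fs",
    "coalescent_null_pvalue", "NullTestResult", "neutrality_summary",
    "NeutralityResult", "mismatch_observed", "mismatch_expected",
    "fit_expansion", "raggedness_index", "raggedness_pvalue",
    "mk_counts", "MKCounts",
]


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 normalizing constants for a sample of n sequences."""
    if n < 2:
        raise ValueError("n must be >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _d_from_summaries(n: int, S: int, kbar: float) -> float:
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (kbar - S / c["a1"]) / math.sqrt(var)


def tajimas_d(aln: Alignment) -> tuple[float, dict[str, float]]:
    """Tajima's D with its components (n, S, k-bar and constants).

    S and k-bar are counted on complete-deletion sites. Monomorphic
    alignments (S = 0) are not calculable.
    """
    n = aln.n
    if n < 2:
        raise NotCalculable("Tajima's D needs n >= 2")
    S = segregating_sites(aln)
    if S == 0:
        raise NotCalculable("Tajima's D not calculable: no segregating sites")
    kbar = mean_pairwise_differences(aln, complete_deletion=True)
    comp = tajima_constants(n) | {"n": n, "S": S, "kbar": kbar}
    return _d_from_summaries(n, S, kbar), comp


# ---------------------------------------------------------------------------
# Ewens sampling formula and Fu's Fs
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _log_stirling_first_row(n: int) -> tuple[float, ...]:
    """log of unsigned Stirling numbers of the first kind c(n, k), k=0..n.

    Computed exactly with big integers via the coefficients of
    x(x+1)...(x+n-1), then logged; exact up to the float conversion.
    """
    coeffs = [1]  # polynomial in x, ascending powers; start with 1 (n=0)
    for m in range(n):
        new = [0] * (len(coeffs) + 1)
        for k, c in enumerate(coeffs):
            new[k] += c * m      # multiply by m
            new[k + 1] += c      # multiply by x
        coeffs = new
    return tuple(math.log(c) if c > 0 else -math.inf for c in coeffs)


def ewens_pmf(n: int, theta: float) -> np.ndarray:
    """Pr(K = k) for k = 1..n under the Ewens sampling formula.

    Pr(K = k) = c(n, k) theta^k / prod_{i=0}^{n-1}(theta + i), with c the
    unsigned Stirling numbers of the first kind. Returned as an array of
    length n (index 0 is k = 1).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    logs = _log_stirling_first_row(n)
    log_denom = sum(math.log(theta + i) for i in range(n))
    log_theta = math.log(theta)
    logp = np.array([logs[k] + k * log_theta - log_denom for k in range(1, n + 1)])
    p = np.exp(logp - logsumexp(logp))  # renormalize away float roundoff
    return p


def _fs_from_summaries(n: int, kbar: float, k_obs: int) -> float:
    if k_obs <= 1:
        raise NotCalculable("Fu's Fs not calculable: a single haplotype")
    if kbar <= 0:
        raise NotCalculable("Fu's Fs not calculable: theta-hat = 0")
    pmf = ewens_pmf(n, kbar)
    s_prime = float(pmf[k_obs - 1:].sum())
    if s_prime <= 0.0 or s_prime >= 1.0:
        raise NotCalculable("Fu's Fs not calculable: degenerate S'")
    return math.log(s_prime / (1.0 - s_prime))


def fus_fs(aln: Alignment) -> float:
    """Fu's Fs; haplotypes and k-bar counted on complete-deletion sites."""
    if aln.n < 2:
        raise NotCalculable("Fu's Fs needs n >= 2")
    m = complete_deletion_columns(aln)
    k_obs = len({row.tobytes() for row in m}) if m.size else 1
    kbar = mean_pairwise_differences(aln, complete_deletion=True)
    return _fs_from_summaries(aln.n, kbar, k_obs)


# ---------------------------------------------------------------------------
# Neutral coalescent null distributions
# ---------------------------------------------------------------------------

def _kingman_edges(n: int, rng: np.random.Generator,
                   start_time: float = 0.0) -> list[tuple[int, float]]:
    """Simulate a constant-size Kingman genealogy of n tips.

    Time is in coalescent units (a pair coalesces at rate 1). Returns the
    2n-2 edges as (tip bitmask, branch length). ``start_time`` delays the
    first coalescence, which models a sudden expansion with effectively
    infinite recent size: all n lineages survive the recent epoch.
    """
    masks = [1 << i for i in range(n)]
    births = [0.0] * n
    edges: list[tuple[int, float]] = []
    t = start_time
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        edges.append((masks[i], t - births[i]))
        edges.append((masks[j], t - births[j]))
        masks[i] = masks[i] | masks[j]
        births[i] = t
        del masks[j], births[j]
        k -= 1
    return edges


def _place_mutations(edges: list[tuple[int, float]], n: int,
                     rng: np.random.Generator,
                     S: int | None = None,
                     theta: float | None = None) -> tuple[float, int, int]:
    """Drop mutations on a genealogy; return (k-bar, S, haplotype count).

    Infinite-sites: every mutation is a new site. Either exactly ``S``
    mutations (multinomial over branch lengths) or Poisson with rate
    theta/2 per unit branch length.
    """
    lengths = np.array([e[1] for e in edges])
    if S is not None:
        counts = rng.multinomial(S, lengths / lengths.sum())
    else:
        counts = rng.poisson(theta / 2.0 * lengths)
    total = int(counts.sum())
    if total == 0:
        return 0.0, 0, 1
    kbar_sum = 0
    tip_sigs = [0] * n
    sig = 1
    for (mask, _), c in zip(edges, counts):
        if c == 0:
            continue
        b = mask.bit_count()
        kbar_sum += c * b * (n - b)
        m = mask
        while m:
            low = m & -m
            tip_sigs[low.bit_length() - 1] ^= sig
            m ^= low
        sig <<= 1
    kbar = 2.0 * kbar_sum / (n * (n - 1))
    return kbar, total, len(set(tip_sigs))


@dataclass(frozen=True)
class NullTestResult:
    stat: str
    observed: float
    p: float            # one-sided lower tail: Pr(sim <= observed)
    p_two_sided: float
    reps: int
    significant: bool   # at 0.05 for D, 0.02 for Fs (one-sided lower)


def coalescent_null_pvalue(aln: Alignment, stat: str = "D",
                           reps: int = 1000, seed: int = 0,
                           condition_on: str = "S") -> NullTestResult:
    """Simulation p-value for Tajima's D or Fu's Fs.

    Neutral constant-size coalescent genealogies are simulated and the
    statistic recomputed on each; by default the observed number of
    segregating sites is held fixed (``condition_on="S"``), otherwise
    mutations are Poisson with rate theta-hat (``condition_on="theta"``).
    The reported p is Pr(sim <= observed), the tail relevant for
    expansion; significance flags use 0.05 (D) and 0.02 (Fs).
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if stat not in ("D", "Fs"):
        raise ValueError("stat must be 'D' or 'Fs'")
    n = aln.n
    S_obs = segregating_sites(aln)
    kbar_obs = mean_pairwise_differences(aln, complete_deletion=True)
    if stat == "D":
        observed, _ = tajimas_d(aln)
    else:
        observed = fus_fs(aln)
    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(reps):
        edges = _kingman_edges(n, rng)
        if condition_on == "S":
            kbar, S, k = _place_mutations(edges, n, rng, S=S_obs)
        elif condition_on == "theta":
            kbar, S, k = _place_mutations(edges, n, rng, theta=kbar_obs)
        else:
            raise ValueError("condition_on must be 'S' or 'theta'")
        try:
            if stat == "D":
                if S == 0:
                    continue
                sims.append(_d_from_summaries(n, S, kbar))
            else:
                sims.append(_fs_from_summaries(n, kbar, k))
        except NotCalculable:
            continue
    sims_arr = np.array(sims)
    m = len(sims_arr)
    if m == 0:
        raise NotCalculable("no calculable simulated statistics")
    p_low = (int((sims_arr <= observed).sum()) + 1) / (m + 1)
    p_high = (int((sims_arr >= observed).sum()) + 1) / (m + 1)
    p_two = min(1.0, 2.0 * min(p_low, p_high))
    alpha = 0.05 if stat == "D" else 0.02
    return NullTestResult(stat=stat, observed=observed, p=p_low,
                          p_two_sided=p_two, reps=m,
                          significant=p_low <= alpha)


@dataclass(frozen=True)
class NeutralityResult:
    n: int
    S: int
    kbar: float
    D: float        # NaN when not calculable
    Fs: float       # NaN when not calculable
    pD: float       # NaN when not calculable
    pFs: float      # NaN when not calculable


def neutrality_summary(aln: Alignment, reps: int = 1000, seed: int = 0
                       ) -> NeutralityResult:
    """n, S, k-bar, D, Fs and their simulation p-values for one sample."""
    n = aln.n
    S = segregating_sites(aln)
    kbar = mean_pairwise_differences(aln, complete_deletion=True) if n >= 2 else 0.0
    nan = float("nan")
    D = Fs = pD = pFs = nan
    try:
        D, _ = tajimas_d(aln)
        pD = coalescent_null_pvalue(aln, "D", reps=reps, seed=seed).p
    except NotCalculable:
        pass
    try:
        Fs = fus_fs(aln)
        pFs = coalescent_null_pvalue(aln, "Fs", reps=reps, seed=seed + 1).p
    except NotCalculable:
        pass
    return NeutralityResult(n=n, S=S, kbar=kbar, D=D, Fs=Fs, pD=pD, pFs=pFs)


# ---------------------------------------------------------------------------
# Mismatch distribution and raggedness
# ---------------------------------------------------------------------------

def mismatch_observed(aln: Alignment) -> np.ndarray:
    """Relative frequencies of pairwise difference counts 0..d.

    Counts use complete-deletion sites so classes are integers.
    """
    if aln.n < 2:
        raise NotCalculable("mismatch distribution needs n >= 2")
    m = complete_deletion_columns(aln)
    n = aln.n
    counts: dict[int, int] = {}
    for i in range(n):
        if m.size:
            d = (m[i] != m[i + 1:]).sum(axis=1)
        else:
            d = np.zeros(n - i - 1, dtype=int)
        for val in d:
            counts[int(val)] = counts.get(int(val), 0) + 1
    dmax = max(counts)
    total = n * (n - 1) // 2
    return np.array([counts.get(i, 0) / total for i in range(dmax + 1)])


def _geometric_f(theta: float, d: int) -> np.ndarray:
    i = np.arange(d + 1)
    return theta**i / (theta + 1.0) ** (i + 1)


def mismatch_expected(model: str, params, d: int) -> np.ndarray:
    """Expected mismatch frequencies F_0..F_d.

    ``model="constant"``: F_i = theta^i / (theta+1)^(i+1) with
    ``params=theta``. ``model="sudden-expansion"``: ``params=(tau, theta0,
    theta1)`` (theta1 may be ``inf``): the class-j probability is the
    pre-expansion geometric smeared by a Poisson(tau) number of new
    mutations, plus the decaying contribution of the post-expansion
    equilibrium. tau=0 reduces exactly to the constant model at theta0.
    """
    if model == "constant":
        theta = float(params)
        if theta < 0:
            raise ValueError("theta must be non-negative")
        return _geometric_f(theta, d)
    if model != "sudden-expansion":
        raise ValueError(f"unknown model {model!r}")
    tau, theta0, theta1 = params
    if tau < 0 or theta0 < 0 or (not math.isinf(theta1) and theta1 <= theta0):
        raise ValueError("need tau >= 0, theta0 >= 0 and theta1 > theta0")
    f0 = _geometric_f(theta0, d)
    if math.isinf(theta1):
        decay = math.exp(-tau)
        f1 = np.zeros(d + 1)
    else:
        decay = math.exp(-tau * (theta1 + 1.0) / theta1)
        f1 = _geometric_f(theta1, d)
    out = np.empty(d + 1)
    # F_j = F1_j + decay * sum_i (tau^(j-i)/(j-i)!) (F0_i - F1_i); the decay
    # factor carries the exponential, so the smear weights are raw tau^k/k!
    log_tau = math.log(tau) if tau > 0 else -math.inf
    pois_raw = np.array([math.exp(k * log_tau - math.lgamma(k + 1))
                         if tau > 0 else (1.0 if k == 0 else 0.0)
                         for k in range(d + 1)])
    for j in range(d + 1):
        smear = sum(pois_raw[j - i] * (f0[i] - f1[i]) for i in range(j + 1))
        out[j] = f1[j] + decay * smear
    return out


def fit_expansion(x: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of (tau, theta0) of the sudden-expansion model.

    theta1 is taken as infinite (instantaneous large growth). A coarse
    grid seeds a Nelder-Mead refinement.
    """
    x = np.asarray(x, dtype=float)
    d = len(x) - 1
    mean_d = float(np.arange(d + 1) @ x)

    def sse(p):
        tau, th0 = p
        if tau < 0 or th0 < 0:
            return 1e9
        f = mismatch_expected("sudden-expansion", (tau, th0, math.inf), d)
        return float(((f - x) ** 2).sum())

    best = None
    for tau in np.linspace(0.0, max(2.0 * mean_d, 1.0), 9):
        for th0 in (0.01, 0.1, 0.5, 1.0, 2.0, max(0.05, mean_d)):
            val = sse((tau, th0))
            if best is None or val < best[0]:
                best = (val, (tau, th0))
    res = minimize(sse, x0=np.array(best[1]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    tau, th0 = res.x
    return max(0.0, float(tau)), max(0.0, float(th0))


def raggedness_index(x: Sequence[float]) -> float:
    """Harpending's raggedness: sum of squared successive differences.

    The class beyond the last observed one is taken as zero, so a
    single-class distribution (all pairs identical) scores 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty mismatch distribution")
    if not math.isclose(float(x.sum()), 1.0, abs_tol=1e-8):
        raise ValueError("mismatch frequencies must sum to 1")
    padded = np.concatenate([x, [0.0]])
    return float(((padded[1:] - padded[:-1]) ** 2).sum())


def _simulate_mismatch(n: int, tau: float, theta0: float,
                       rng: np.random.Generator) -> np.ndarray:
    """One parametric draw of a mismatch distribution under expansion.

    The recent epoch has effectively infinite size (no coalescence for a
    duration tau/theta0 in coalescent units of the ancestral population);
    mutations are Poisson at rate theta0/2 per unit branch length.
    """
    start = tau / theta0 if theta0 > 0 else 0.0
    edges = _kingman_edges(n, rng, start_time=start)
    lengths = np.array([e[1] for e in edges])
    counts = rng.poisson(theta0 / 2.0 * lengths)
    diff = np.zeros((n, n), dtype=np.int64)
    tips = np.arange(n)
    for (mask, _), c in zip(edges, counts):
        if c == 0:
            continue
        inside = np.array([(mask >> int(t)) & 1 for t in tips], dtype=bool)
        diff += c * np.logical_xor.outer(inside, ~inside)
    iu = np.triu_indices(n, k=1)
    d = diff[iu]
    dmax = int(d.max(initial=0))
    freq = np.bincount(d, minlength=dmax + 1).astype(float)
    return freq / freq.sum()


def raggedness_pvalue(aln: Alignment, reps: int = 1000, seed: int = 0
                      ) -> tuple[float, float, tuple[float, float]]:
    """(Hri, p, fitted (tau, theta0)) under the expansion model.

    p = Pr(simulated r >= observed r) over parametric coalescent
    bootstraps from the least-squares fit; a small p rejects the
    population-expansion model.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    x = mismatch_observed(aln)
    if len(x) < 2:
        raise NotCalculable("degenerate mismatch distribution")
    r_obs = raggedness_index(x)
    tau, th0 = fit_expansion(x)
    if th0 <= 0:
        th0 = 0.05  # degenerate fit guard: nearly star-shaped data
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(reps):
        r_sim = raggedness_index(_simulate_mismatch(aln.n, tau, th0, rng))
        if r_sim >= r_obs:
            count += 1
    p = (count + 1) / (reps + 1)
    return r_obs, p, (tau, th0)


# ---------------------------------------------------------------------------
# McDonald-Kreitman counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MKCounts:
    Ps: float
    Pn: float
    Ms: float
    Mn: float

    @property
    def neutrality_ratios(self) -> tuple[float, float]:
        """(Mn/Pn, Ms/Ps); NaN where the denominator is zero."""
        nan = float("nan")
        return (self.Mn / self.Pn if self.Pn else nan,
                self.Ms / self.Ps if self.Ps else nan)

    @property
    def positive_selection_indicated(self) -> bool:
        """Whether Mn/Pn exceeds Ms/Ps (cross-multiplied to handle zeros).

        Always False when there are no fixed non-synonymous differences.
        """
        return self.Mn > 0 and self.Mn * self.Ps > self.Ms * self.Pn


def _codon_aa(codon: str, table) -> str:
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def _pathway_changes(c1: str, c2: str, table) -> tuple[float, float]:
    """(synonymous, non-synonymous) changes between two codons.

    Averaged over all minimal single-step pathways; orderings passing
    through stop codons are excluded when a stop-free ordering exists.
    """
    sites = [i for i in range(3) if c1[i] != c2[i]]
    if not sites:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(sites):
        cur = c1
        steps = []
        has_stop = False
        for s in order:
            nxt = cur[:s] + c2[s] + cur[s + 1:]
            aa1, aa2 = _codon_aa(cur, table), _codon_aa(nxt, table)
            if aa2 == "*" and nxt != c2:
                has_stop = True
            steps.append(aa1 == aa2)
            cur = nxt
        paths.append((has_stop, steps))
    usable = [s for stop, s in paths if not stop] or [s for _, s in paths]
    syn = sum(sum(steps) for steps in usable) / len(usable)
    total = len(sites)
    return syn, total - syn


def _min_changes_within(codons: list[str], table) -> tuple[float, float]:
    """Polymorphic (syn, nonsyn) changes among a species' codons.

    A minimum spanning tree over Hamming distances gives the minimal set
    of changes; each edge is classified by pathway averaging.
    """
    uniq = sorted(set(codons))
    if len(uniq) <= 1:
        return 0.0, 0.0
    # Prim's MST on the small complete graph
    def ham(a, b):
        return sum(x != y for x, y in zip(a, b))
    in_tree = {uniq[0]}
    syn = nonsyn = 0.0
    while len(in_tree) < len(uniq):
        best = None
        for a in in_tree:
            for b in uniq:
                if b in in_tree:
                    continue
                d = ham(a, b)
                if best is None or d < best[0] or (d == best[0] and (a, b) < best[1:]):
                    best = (d, a, b)
        _, a, b = best
        s, ns = _pathway_changes(a, b, table)
        syn += s
        nonsyn += ns
        in_tree.add(b)
    return syn, nonsyn


def _majority_codon(codons: list[str]) -> str:
    counts: dict[str, int] = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
    return min(counts, key=lambda c: (-counts[c], c))


def detect_frame(aln: Alignment, code: int = 5) -> int:
    """Reading frame minimizing internal stop codons across sequences."""
    best = None
    for frame in (0, 1, 2):
        stops = sum(translate_codons(s, code, frame)[:-1].count("*")
                    for s in aln.sequences)
        if best is None or stops < best[0]:
            best = (stops, frame)
    return best[1]


def mk_counts(aln_a: Alignment, aln_b: Alignment, code: int = 5,
              frame: int | None = None) -> MKCounts:
    """McDonald-Kreitman 2x2 table for two species alignments.

    Polymorphic changes are minimal within-species codon changes (MST over
    observed codons, pathway-averaged syn/nonsyn). A codon site is a fixed
    difference when the two species share no nucleotide there; its
    syn/nonsyn class is the pathway-averaged change between the majority
    codons of the two species, restricted to fixed sites. Codons with
    missing data in a sequence skip that sequence only.
    """
    if aln_a.length != aln_b.length:
        raise AlignmentError("species alignments differ in length")
    table = CodonTable.unambiguous_dna_by_id[code]
    if frame is None:
        frame = detect_frame(aln_a, code)
    # frame sanity: warn when stops pervade
    n_codons = (aln_a.length - frame) // 3
    stops = sum(translate_codons(s, code, frame)[:-1].count("*")
                for s in aln_a.sequences + aln_b.sequences)
    total_cod = n_codons * (aln_a.n + aln_b.n)
    if total_cod and stops / total_cod > 0.5:
        warnings.warn("chosen reading frame yields internal stops in >50% "
                      "of codons", stacklevel=2)
    ps = pn = ms = mn = 0.0
    for ci in range(n_codons):
        lo = frame + 3 * ci
        cods_a = [s[lo:lo + 3] for s in aln_a.sequences]
        cods_b = [s[lo:lo + 3] for s in aln_b.sequences]
        cods_a = [c for c in cods_a if not set(c) - set("ACGT")]
        cods_b = [c for c in cods_b if not set(c) - set("ACGT")]
        if not cods_a or not cods_b:
            continue
        for cods in (cods_a, cods_b):
            s, ns = _min_changes_within(cods, table)
            ps += s
            pn += ns
        fixed_sites = [
            s for s in range(3)
            if not ({c[s] for c in cods_a} & {c[s] for c in cods_b})
        ]
        if fixed_sites:
            ca, cb = _majority_codon(cods_a), _majority_codon(cods_b)
            # classify only steps at fixed sites along minimal pathways
            s_frac, ns_frac = _fixed_site_changes(ca, cb, fixed_sites, table)
            ms += s_frac
            mn += ns_frac
    return MKCounts(Ps=ps, Pn=pn, Ms=ms, Mn=mn)


def _fixed_site_changes(c1: str, c2: str, fixed_sites: list[int], table
                        ) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) for the steps at fixed sites only."""
    sites = [i for i in range(3) if c1[i] != c2[i]]
    if not sites:
        return 0.0, 0.0
    acc_syn: list[float] = []
    acc_ns: list[float] = []
    for order in itertools.permutations(sites):
        cur = c1
        syn = ns = 0.0
        has_stop = False
        for s in order:
            nxt = cur[:s] + c2[s] + cur[s + 1:]
            if _codon_aa(nxt, table) == "*" and nxt != c2:
                has_stop = True
            if s in fixed_sites:
                if _codon_aa(cur, table) == _codon_aa(nxt, table):
                    syn += 1
                else:
                    ns += 1
            cur = nxt
        acc_syn.append((has_stop, syn))
        acc_ns.append((has_stop, ns))
    ok = [i for i, (stop, _) in enumerate(acc_syn) if not stop]
    idx = ok or list(range(len(acc_syn)))
    syn = sum(acc_syn[i][1] for i in idx) / len(idx)
    ns = sum(acc_ns[i][1] for i in idx) / len(idx)
    return syn, ns
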