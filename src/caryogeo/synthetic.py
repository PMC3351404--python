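"""Synthetic structured-coalescent data with a known refugial origin.

The generator emulates the sampling design the analysis pipeline expects:
multi-deme samples of short mtDNA-like haplotypes (590 bp by default),
star-like expanding lineages versus structured refugial ones, haplotypes
shared across localities, and posterior-like samples of rooted coalescent
trees whose true source deme is recorded for recovery tests.

Genealogies come from msprime's structured coalescent on a haploid-copy
timescale (population size N means a sample pair coalesces after N
generations on average). "Posterior-like" tree samples are independent
draws from the same scenario, not MCMC output: they exercise the
tree-sample contract of the RLR stage without phylogenetic inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import msprime
import numpy as np

from .errors import SimulationError
from .seq_data import Alignment, collapse_haplotypes, write_fasta_alignment

__all__ = [
    "SimScenario", "Genealogy", "make_scenario", "simulate_genealogy",
    "apply_mutations", "simulate_tree_sample", "export_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimScenario:
    """Deme structure, demographic events, mutation model and truth record."""

    demes: tuple[tuple[str, float], ...]           # (name, N_e in copies)
    migration: tuple[tuple[float, ...], ...]       # per-generation rates
    events: tuple[dict, ...]                       # time-ordered demographic events
    mutation_model: str                            # "infinite-sites" | "jc-finite"
    mutation_rate: float                           # per site per generation
    length: int                                    # sites
    sample_sizes: Mapping[str, int]
    seed: int
    source_deme: str | None                        # truth for recovery tests

    def __post_init__(self) -> None:
        if self.length <= 0 or self.mutation_rate < 0:
            raise SimulationError("need L > 0 and mutation rate >= 0")
        if any(n < 0 for n in self.sample_sizes.values()) \
                or sum(self.sample_sizes.values()) < 2:
            raise SimulationError("need total sample size >= 2")
        if any(size <= 0 for _, size in self.demes):
            raise SimulationError("deme sizes must be positive")
        for row in self.migration:
            if any(m < 0 for m in row):
                raise SimulationError("migration rates must be non-negative")

    @property
    def deme_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.demes)


@dataclass(frozen=True)
class Genealogy:
    """A single rooted genealogy with deme-labelled tips.

    ``tree_sequence`` retains the tskit object for mutation dropping;
    ``tip_demes`` maps tip label -> deme name.
    """

    tree_sequence: object
    tip_labels: tuple[str, ...]
    tip_demes: Mapping[str, str]

    def newick(self) -> str:
        t = self.tree_sequence.first()
        node_labels = {u: self.tip_labels[i]
                       for i, u in enumerate(self.tree_sequence.samples())}
        return t.as_newick(node_labels=node_labels)

    def dendropy_tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick(), schema="newick",
                                 rooting="default-rooted",
                                 preserve_underscores=True)

    def tip_states(self) -> dict[str, frozenset]:
        return {lab: frozenset({d}) for lab, d in self.tip_demes.items()}


def make_scenario(preset: str, strength: str = "strong", seed: int = 0,
                  length: int = 590) -> SimScenario:
    """Preset study designs.

    ``refugial-expansion``: a small refugial source deme seeds several
    young colony demes at a recent time; colonies are near-monophyletic,
    deep coalescence happens inside the source (the RLR truth), and D/Fs
    trend negative. ``sudden-growth``: one deme that grew suddenly from a
    small ancestral size — the star-like genealogy behind the mismatch
    expansion model (strongly negative D/Fs). ``island-constant``:
    symmetric migration at constant size. ``single-panmictic``: one deme,
    the null for type-I error calibration.
    """
    if strength not in ("weak", "strong"):
        raise ValueError("strength must be 'weak' or 'strong'")
    if preset == "refugial-expansion":
        n_col = 4
        strong = strength == "strong"
        src_size = 500.0 if strong else 2000.0
        col_size = 100.0 if strong else 500.0
        split = 300.0 if strong else 1500.0
        demes = (("SRC", src_size),) + tuple(
            (f"C{i+1}", col_size) for i in range(n_col))
        k = len(demes)
        migration = tuple(tuple(0.0 for _ in range(k)) for _ in range(k))
        events = (
            {"time": split, "type": "expansion-from-source",
             "source": "SRC", "colonies": [f"C{i+1}" for i in range(n_col)]},
        )
        samples = {"SRC": 15} | {f"C{i+1}": 10 for i in range(n_col)}
        rate = 6e-6
        return SimScenario(demes=demes, migration=migration, events=events,
                           mutation_model="infinite-sites",
                           mutation_rate=rate, length=length,
                           sample_sizes=samples, seed=seed,
                           source_deme="SRC")
    if preset == "sudden-growth":
        strong = strength == "strong"
        now = 50000.0 if strong else 5000.0
        anc = 50.0 if strong else 500.0
        t_exp = 300.0 if strong else 1000.0
        rate = 8.5e-6 if strong else 6e-6
        demes = (("POP", now),)
        events = ({"time": t_exp, "type": "size-change",
                   "deme": "POP", "size": anc},)
        return SimScenario(demes=demes, migration=((0.0,),), events=events,
                           mutation_model="infinite-sites",
                           mutation_rate=rate, length=length,
                           sample_sizes={"POP": 50}, seed=seed,
                           source_deme=None)
    if preset == "island-constant":
        k = 4
        size = 1000.0
        m = 1e-3 if strength == "strong" else 1e-4
        demes = tuple((f"D{i+1}", size) for i in range(k))
        migration = tuple(tuple(0.0 if i == j else m for j in range(k))
                          for i in range(k))
        samples = {f"D{i+1}": 10 for i in range(k)}
        rate = 5.0 / (2.0 * size * length)
        return SimScenario(demes=demes, migration=migration, events=(),
                           mutation_model="infinite-sites",
                           mutation_rate=rate, length=length,
                           sample_sizes=samples, seed=seed, source_deme=None)
    if preset == "single-panmictic":
        size = 1000.0
        demes = (("POP", size),)
        samples = {"POP": 50}
        rate = 5.0 / (2.0 * size * length)
        return SimScenario(demes=demes, migration=((0.0,),), events=(),
                           mutation_model="infinite-sites",
                           mutation_rate=rate, length=length,
                           sample_sizes=samples, seed=seed, source_deme=None)
    raise ValueError(f"unknown preset {preset!r}")


def _demography(scn: SimScenario) -> msprime.Demography:
    dem = msprime.Demography()
    names = scn.deme_names
    for name, size in scn.demes:
        dem.add_population(name=name, initial_size=size)
    for i, row in enumerate(scn.migration):
        for j, m in enumerate(row):
            if i != j and m > 0:
                dem.set_migration_rate(source=names[i], dest=names[j], rate=m)
    for ev in sorted(scn.events, key=lambda e: e["time"]):
        if ev["type"] == "expansion-from-source":
            for col in ev["colonies"]:
                dem.add_mass_migration(time=ev["time"], source=col,
                                       dest=ev["source"], proportion=1.0)
        elif ev["type"] == "size-change":
            dem.add_population_parameters_change(
                time=ev["time"], population=ev["deme"],
                initial_size=ev["size"])
        else:
            raise SimulationError(f"unknown event type {ev['type']!r}")
    dem.sort_events()
    return dem


def simulate_genealogy(scn: SimScenario, seed: int | None = None) -> Genealogy:
    """One structured-coalescent genealogy; reproducible under seed.

    Branch lengths are in generations on the haploid-copy timescale.
    Samples that cannot find a common ancestor (disconnected demes with
    zero migration and no joining event) trigger a guard error once a
    generous time cap is reached.
    """
    seed = scn.seed if seed is None else seed
    cap = 1000.0 * sum(size for _, size in scn.demes)
    try:
        ts = msprime.sim_ancestry(
            samples=[msprime.SampleSet(n, population=d, ploidy=1)
                     for d, n in scn.sample_sizes.items() if n > 0],
            demography=_demography(scn),
            sequence_length=scn.length,
            ploidy=1,
            end_time=cap,
            random_seed=_msprime_seed(seed),
        )
    except Exception as exc:  # msprime LibraryError on infinite waiting time
        raise SimulationError(
            "sample failed to coalesce; check that all demes are connected "
            f"by migration or demographic events ({exc})") from exc
    if ts.first().num_roots != 1:
        raise SimulationError(
            "sample failed to coalesce within the time cap; check that all "
            "demes are connected by migration or demographic events")
    labels = []
    tip_demes = {}
    counters: dict[str, int] = {}
    pops = {p.id: p.metadata.get("name", str(p.id)) for p in ts.populations()}
    for u in ts.samples():
        deme = pops[ts.node(u).population]
        counters[deme] = counters.get(deme, 0) + 1
        lab = f"{deme}_{counters[deme]}"
        labels.append(lab)
        tip_demes[lab] = deme
    return Genealogy(tree_sequence=ts, tip_labels=tuple(labels),
                     tip_demes=tip_demes)


def _msprime_seed(seed: int) -> int:
    # msprime requires seeds in [1, 2^32); fold arbitrary ints in
    return int(seed) % (2**32 - 1) + 1


def apply_mutations(gen: Genealogy, model: str, rate: float, length: int,
                    seed: int = 0) -> Alignment:
    """Drop mutations on a genealogy and return the tip alignment.

    ``infinite-sites``: every mutation hits a fresh site (error when more
    mutations arise than there are sites). ``jc-finite``: Jukes-Cantor on
    a discrete genome, multiple hits allowed. Unmutated columns carry a
    seeded random reference base.
    """
    rng = np.random.default_rng(seed)
    n = len(gen.tip_labels)
    ref = rng.integers(0, 4, size=length)
    seqs = np.tile(ref, (n, 1))
    ts = gen.tree_sequence
    if rate > 0:
        if model == "infinite-sites":
            mts = msprime.sim_mutations(
                ts, rate=rate, discrete_genome=False,
                random_seed=_msprime_seed(seed))
            if mts.num_sites > length:
                raise SimulationError(
                    f"infinite-sites model exhausted: {mts.num_sites} "
                    f"mutations for {length} sites")
            cols = rng.choice(length, size=mts.num_sites, replace=False)
        elif model == "jc-finite":
            mts = msprime.sim_mutations(
                ts, rate=rate, model=msprime.JC69(), discrete_genome=True,
                random_seed=_msprime_seed(seed))
            cols = None
        else:
            raise SimulationError(f"unknown mutation model {model!r}")
        base_idx = {b: i for i, b in enumerate("ACGT")}
        for k, var in enumerate(mts.variants()):
            col = int(cols[k]) if cols is not None else int(var.site.position)
            alleles = var.alleles
            if model == "infinite-sites":
                # re-map the binary split onto the reference base and a
                # distinct derived base at the chosen column
                anc = ref[col]
                derived = (anc + 1 + rng.integers(0, 3)) % 4
                anc_state = var.site.ancestral_state
                codes = np.where(np.array(alleles)[var.genotypes] == anc_state,
                                 anc, derived)
            else:
                codes = np.array([base_idx[alleles[g]] for g in var.genotypes])
            seqs[:, col] = codes
    records = [(lab, "".join(_BASES[row]))
               for lab, row in zip(gen.tip_labels, seqs)]
    return Alignment.from_records(records)


def simulate_alignment(scn: SimScenario, seed: int | None = None
                       ) -> tuple[Alignment, Genealogy]:
    """Genealogy + mutations in one call, seeded from the scenario."""
    seed = scn.seed if seed is None else seed
    gen = simulate_genealogy(scn, seed=seed)
    aln = apply_mutations(gen, scn.mutation_model, scn.mutation_rate,
                          scn.length, seed=seed + 1)
    return aln, gen


def simulate_tree_sample(scn: SimScenario, reps: int, seed: int | None = None
                         ) -> list[Genealogy]:
    """Independent genealogies standing in for a posterior tree sample."""
    if reps < 1:
        raise SimulationError("reps must be >= 1")
    seed = scn.seed if seed is None else seed
    return [simulate_genealogy(scn, seed=seed + 1000 * (r + 1))
            for r in range(reps)]


def export_fixture(scn: SimScenario, reps: int, outdir: str | Path,
                   species: str = "SIM") -> dict[str, Path]:
    """Write a complete pipeline input bundle for one scenario.

    Produces an aligned FASTA, a locality table in the wide TSV dialect,
    a Newick file of ``reps`` independent rooted genealogies, an identity
    pooling map and a truth JSON naming the source deme.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, gen = simulate_alignment(scn)
    fasta = outdir / "alignment.fasta"
    write_fasta_alignment(aln, fasta)

    index = collapse_haplotypes(aln, dict(gen.tip_demes))
    per_deme_haps: dict[str, list[str]] = {d: [] for d in scn.deme_names}
    for h in index.haplotypes:
        for deme in h.occurrences:
            per_deme_haps[deme].append(h.label)
    table = outdir / "localities.tsv"
    with open(table, "w") as fh:
        fh.write(f"code\tname\tlat\tlon\tN_{species}\thaplotypes_{species}\n")
        for i, (deme, _) in enumerate(scn.demes):
            n = scn.sample_sizes.get(deme, 0)
            n_cell = str(n) if n > 0 else ""
            haps = ",".join(sorted(per_deme_haps[deme],
                                   key=lambda h: int(h[1:])))
            fh.write(f"{deme}\tSimulated deme {deme}\t{44.0 + i:.2f}\t"
                     f"{8.0 + i:.2f}\t{n_cell}\t{haps}\n")

    trees_path = outdir / "trees.nwk"
    sample = simulate_tree_sample(scn, reps)
    with open(trees_path, "w") as fh:
        for g in sample:
            fh.write(g.newick() + "\n")

    pooling = outdir / "pooling.tsv"
    with open(pooling, "w") as fh:
        for deme in scn.deme_names:
            fh.write(f"{deme}\t{deme}\n")

    truth = outdir / "truth.json"
    with open(truth, "w") as fh:
        json.dump({"source_deme": scn.source_deme, "seed": scn.seed,
                   "preset_sample_sizes": dict(scn.sample_sizes)}, fh, indent=1)
    return {"fasta": fasta, "localities": table, "trees": trees_path,
            "pooling": pooling, "truth": truth}
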