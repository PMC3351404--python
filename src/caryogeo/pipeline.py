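"""End-to-end orchestration: from files to report bundle.

A run takes per-species inputs (alignment, specimen -> locality map or a
locality table), builds haplotype indices, networks and MOTUs, computes
the diversity and neutrality tables (whole dataset plus per MOTU), runs
the refugium localization reconstruction over a tree sample if one is
supplied, and writes deterministic TSV outputs with a header naming the
configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import diversity, network_motu, neutrality, rlr, seq_data
from .errors import CaryogeoError, NotCalculable

log = logging.getLogger("caryogeo")


@dataclass
class SpeciesConfig:
    label: str
    alignment: Path
    locality_of: Mapping[str, str]       # sequence id -> locality code
    motu_level: int = 2
    trees: Path | None = None            # optional rooted tree sample
    tree_burnin: float = 0.0
    tree_subsample: int | None = None


@dataclass
class RunConfig:
    species: list[SpeciesConfig]
    locality_table: Path
    outdir: Path
    pooling_map: Path | None = None
    confidence: float = 0.95
    neutrality_reps: int = 1000
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps({
            "species": [{"label": s.label, "alignment": str(s.alignment),
                         "motu_level": s.motu_level,
                         "trees": str(s.trees) if s.trees else None,
                         "burnin": s.tree_burnin,
                         "subsample": s.tree_subsample,
                         "n_ids": len(s.locality_of)}
                        for s in self.species],
            "locality_table": str(self.locality_table),
            "pooling_map": str(self.pooling_map) if self.pooling_map else None,
            "confidence": self.confidence,
            "neutrality_reps": self.neutrality_reps,
            "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# caryogeo run config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def run_full_analysis(cfg: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the report bundle.

    Outputs per run: a per-locality diversity table, a per-MOTU
    neutrality table, a MOTU assignment table, network edge lists, and
    (when a tree sample is supplied) an RPS table; plus a JSON run log
    with seeds and the config hash. Reruns with the same config are
    byte-identical.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    table = seq_data.read_locality_table(cfg.locality_table)
    outputs: dict[str, Path] = {}
    runlog: dict = {"config": cfg_hash, "seed": cfg.seed, "species": {}}

    for sp in cfg.species:
        tag = sp.label
        try:
            aln = seq_data.read_fasta_alignment(sp.alignment)
            index = seq_data.collapse_haplotypes(aln, sp.locality_of)
        except CaryogeoError as exc:
            raise CaryogeoError(f"[seq_data:{tag}] {exc}") from exc

        # diversity ---------------------------------------------------
        div = diversity.per_locality_summary(index, table)
        p = outdir / f"{tag}_diversity.tsv"
        _write_tsv(div, p, cfg_hash)
        outputs[f"{tag}_diversity"] = p

        # network + MOTUs ----------------------------------------------
        limit = network_motu.parsimony_connection_limit(aln.length,
                                                        cfg.confidence)
        net = network_motu.build_parsimony_network(index, max_steps=limit)
        net = network_motu.resolve_loops(net, coords=table.coordinates())
        design = network_motu.build_nesting_design(net,
                                                   max_level=sp.motu_level)
        motus = network_motu.assign_motus(design, sp.motu_level,
                                          prefix=f"{tag}_MOTU")
        rows = [{"haplotype": h, "motu": motus[h],
                 "count": index.by_label(h).count}
                for h in index.labels]
        p = outdir / f"{tag}_motus.tsv"
        _write_tsv(pd.DataFrame(rows), p, cfg_hash)
        outputs[f"{tag}_motus"] = p
        edges = pd.DataFrame(
            [{"a": u, "b": v, "steps": d.get("steps", 1)}
             for u, v, d in sorted(net.graph.edges(data=True))])
        p = outdir / f"{tag}_network_edges.tsv"
        _write_tsv(edges, p, cfg_hash)
        outputs[f"{tag}_network"] = p

        # neutrality: complete dataset plus per MOTU -------------------
        seq_of = dict(zip(aln.ids, aln.sequences))
        hap_of = {sid: next(h.label for h in index.haplotypes
                            if h.sequence == seq_of[sid]) for sid in aln.ids}
        units = {"complete": list(aln.ids)}
        for sid, hap in hap_of.items():
            units.setdefault(motus[hap], []).append(sid)
        neut_rows = []
        for i, (unit, ids) in enumerate(sorted(units.items(),
                                               key=lambda kv: (kv[0] != "complete", kv[0]))):
            sub = aln.subset(ids)
            res = neutrality.neutrality_summary(
                sub, reps=cfg.neutrality_reps, seed=cfg.seed + i)
            fmt = lambda x: "n. c." if isinstance(x, float) and math.isnan(x) else x
            neut_rows.append({
                "unit": unit, "N": res.n,
                "H": len({seq_of[x] for x in ids}),
                "S": res.S, "D": fmt(res.D), "Fs": fmt(res.Fs),
                "pD": fmt(res.pD), "pFs": fmt(res.pFs),
                "D_significant": (not math.isnan(res.pD)) and res.pD <= 0.05,
                "Fs_significant": (not math.isnan(res.pFs)) and res.pFs <= 0.02,
            })
        p = outdir / f"{tag}_neutrality.tsv"
        _write_tsv(pd.DataFrame(neut_rows), p, cfg_hash)
        outputs[f"{tag}_neutrality"] = p
        runlog["species"][tag] = {"n": aln.n, "haplotypes": len(index),
                                  "connection_limit": limit,
                                  "motu_level": sp.motu_level,
                                  "loops_removed": len(net.removed_edges)}

        # RLR ----------------------------------------------------------
        if sp.trees is not None:
            pooling = (rlr.read_pooling_map(cfg.pooling_map)
                       if cfg.pooling_map else
                       {c: c for c in table.codes})
            # tree tips may be haplotype labels or specimen ids; cover both
            tip_states = {}
            for hap, locs in index.locality_sets().items():
                tip_states[hap] = frozenset(pooling.get(c, c) for c in locs)
            for sid, code in sp.locality_of.items():
                tip_states[sid] = frozenset({pooling.get(code, code)})
            sample = rlr.read_tree_sample(
                sp.trees, tip_states=tip_states,
                burnin_fraction=sp.tree_burnin,
                subsample=sp.tree_subsample, seed=cfg.seed)
            scores = rlr.rps_scores(sample)
            df = pd.DataFrame(sorted(scores.scores.items(),
                                     key=lambda kv: (-kv[1], kv[0])),
                              columns=["character", "RPS"])
            p = outdir / f"{tag}_rps.tsv"
            _write_tsv(df, p, cfg_hash)
            outputs[f"{tag}_rps"] = p
            runlog["species"][tag]["rps_top"] = scores.top()[0]

    log_path = outdir / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump(runlog, fh, indent=1, sort_keys=True)
    outputs["run_log"] = log_path
    return outputs
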