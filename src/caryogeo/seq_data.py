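"""Alignments, locality metadata and haplotype collapsing.

This module holds the shared sequence machinery: reading aligned FASTA,
reading the locality table (one row per sampling site, one column block per
species), collapsing identical sequences into haplotypes with per-locality
occurrence counts, pairwise-deletion difference counting, and codon
translation under the invertebrate mitochondrial code.

Sequences are uppercase strings over ``A C G T N -`` (``U`` is mapped to
``T`` on input). Sites containing ``N`` or ``-`` are treated as missing for
distance purposes: excluded per pair under pairwise deletion, excluded
globally under complete deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import AlignmentError, LocalityTableError, MappingError

VALID_SYMBOLS = frozenset("ACGTN-")
#: IUPAC ambiguity codes are accepted on input but treated as missing data.
AMBIGUOUS_AS_N = frozenset("RYSWKMBDHV")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """A fixed-length multiple alignment of haploid sequences.

    Attributes
    ----------
    ids : tuple of str
        Record identifiers, unique, in input order.
    sequences : tuple of str
        Normalized sequences, all of length ``length``.
    length : int
        Number of alignment columns (sites).
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    length: int

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise AlignmentError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        if self.length <= 0:
            raise AlignmentError("alignment length must be positive")
        for seq in self.sequences:
            if len(seq) != self.length:
                raise AlignmentError(
                    f"sequence length {len(seq)} != alignment length {self.length}"
                )
            bad = set(seq) - VALID_SYMBOLS
            if bad:
                raise AlignmentError(f"invalid symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Alignment restricted to ``ids`` (input order preserved)."""
        wanted = set(ids)
        keep = [(i, s) for i, s in zip(self.ids, self.sequences) if i in wanted]
        missing = wanted - {i for i, _ in keep}
        if missing:
            raise MappingError(f"unknown ids: {sorted(missing)}")
        return Alignment(
            ids=tuple(i for i, _ in keep),
            sequences=tuple(s for _, s in keep),
            length=self.length,
        )

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str]]) -> "Alignment":
        if not records:
            raise AlignmentError("empty alignment")
        seqs = [normalize_sequence(s) for _, s in records]
        return cls(
            ids=tuple(i for i, _ in records),
            sequences=tuple(seqs),
            length=len(seqs[0]),
        )


@dataclass(frozen=True)
class LocalityRow:
    code: str
    name: str
    lat: float
    lon: float
    #: per-species specimen counts; a species absent from a locality is
    #: simply missing from the dict (absent != 0).
    n: Mapping[str, int] = field(default_factory=dict)
    haplotypes: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass(frozen=True)
class LocalityTable:
    rows: tuple[LocalityRow, ...]
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        codes = [r.code for r in self.rows]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise LocalityTableError(f"duplicate locality codes: {dupes}")
        for r in self.rows:
            if not (-90.0 <= r.lat <= 90.0) or not (-180.0 <= r.lon <= 180.0):
                raise LocalityTableError(f"coordinates out of range for {r.code}")
            for sp, n in r.n.items():
                has_haps = bool(r.haplotypes.get(sp))
                if (n > 0) != has_haps:
                    raise LocalityTableError(
                        f"{r.code}/{sp}: haplotype list must be non-empty iff N > 0"
                    )

    def __iter__(self):
        return iter(self.rows)

    def row(self, code: str) -> LocalityRow:
        for r in self.rows:
            if r.code == code:
                return r
        raise KeyError(code)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(r.code for r in self.rows)

    def coordinates(self) -> dict[str, tuple[float, float]]:
        return {r.code: (r.lat, r.lon) for r in self.rows}


@dataclass(frozen=True)
class Haplotype:
    label: str
    sequence: str
    count: int
    occurrences: Mapping[str, int]


@dataclass(frozen=True)
class HaplotypeIndex:
    """Distinct haplotypes with counts and locality memberships."""

    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        seqs = [h.sequence for h in self.haplotypes]
        if len(set(seqs)) != len(seqs):
            raise AlignmentError("haplotype sequences must be distinct")
        for h in self.haplotypes:
            if sum(h.occurrences.values()) != h.count:
                raise MappingError(
                    f"{h.label}: occurrence counts do not sum to total count"
                )

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(h.label for h in self.haplotypes)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(h.count for h in self.haplotypes)

    @property
    def total(self) -> int:
        return sum(h.count for h in self.haplotypes)

    def by_label(self, label: str) -> Haplotype:
        for h in self.haplotypes:
            if h.label == label:
                return h
        raise KeyError(label)

    def alignment(self) -> Alignment:
        """One record per haplotype, ids = labels."""
        return Alignment(
            ids=self.labels,
            sequences=tuple(h.sequence for h in self.haplotypes),
            length=len(self.haplotypes[0].sequence),
        )

    def locality_sets(self) -> dict[str, frozenset[str]]:
        return {h.label: frozenset(h.occurrences) for h in self.haplotypes}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def normalize_sequence(seq: str) -> str:
    """Uppercase, U→T, IUPAC ambiguity codes → N; validate symbols."""
    s = seq.upper().replace("U", "T")
    s = "".join("N" if c in AMBIGUOUS_AS_N else c for c in s)
    bad = set(s) - VALID_SYMBOLS
    if bad:
        raise AlignmentError(f"non-IUPAC symbols in sequence: {sorted(bad)}")
    return s


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read a multi-FASTA file of equal-length aligned sequences."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal sequence lengths in {path}: {sorted(lengths)}")
    return Alignment.from_records(records)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, s in zip(aln.ids, aln.sequences):
            fh.write(f">{i}\n{s}\n")


def read_locality_table(path: str | Path, species: Sequence[str] | None = None
                        ) -> LocalityTable:
    """Read a TSV locality table.

    Expected columns: ``code``, ``name``, ``lat``, ``lon`` and, per species
    ``X``, ``N_X`` and ``haplotypes_X`` (comma- or semicolon-separated
    labels). Blank count cells mean the species is absent at that locality,
    not that its count is zero.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"code", "name", "lat", "lon"}
    if not required <= set(df.columns):
        raise LocalityTableError(f"missing columns: {sorted(required - set(df.columns))}")
    if species is None:
        species = [c[2:] for c in df.columns if c.startswith("N_")]
    rows = []
    for _, rec in df.iterrows():
        try:
            lat, lon = float(rec["lat"]), float(rec["lon"])
        except ValueError as exc:
            raise LocalityTableError(f"malformed coordinate at {rec['code']}: {exc}")
        counts: dict[str, int] = {}
        haps: dict[str, tuple[str, ...]] = {}
        for sp in species:
            raw_n = rec.get(f"N_{sp}", "").strip()
            raw_h = rec.get(f"haplotypes_{sp}", "").strip()
            if raw_n == "":
                continue  # absent, not zero
            counts[sp] = int(raw_n)
            labels = tuple(
                h.strip()
                for h in raw_h.replace(";", ",").split(",")
                if h.strip()
            )
            haps[sp] = labels
        rows.append(LocalityRow(code=rec["code"].strip(), name=rec["name"].strip(),
                                lat=lat, lon=lon, n=counts, haplotypes=haps))
    return LocalityTable(rows=tuple(rows), species=tuple(species))


def collapse_haplotypes(aln: Alignment,
                        locality_of: Mapping[str, str],
                        label_map: Mapping[str, str] | None = None,
                        ) -> HaplotypeIndex:
    """Collapse identical sequences into haplotypes.

    Identity is exact string match on normalized sequences; sequences
    containing ``N`` are kept distinct from compatible unambiguous
    haplotypes (conservative). Labels are H1, H2, ... in order of first
    appearance unless ``label_map`` (sequence → label) is given.
    """
    missing = [i for i in aln.ids if i not in locality_of]
    if missing:
        raise MappingError(f"sequence ids without locality: {missing}")
    order: list[str] = []
    counts: dict[str, int] = {}
    occ: dict[str, dict[str, int]] = {}
    for sid, seq in zip(aln.ids, aln.sequences):
        if seq not in counts:
            order.append(seq)
            counts[seq] = 0
            occ[seq] = {}
        counts[seq] += 1
        loc = locality_of[sid]
        occ[seq][loc] = occ[seq].get(loc, 0) + 1
    haplotypes = []
    for k, seq in enumerate(order, start=1):
        label = label_map[seq] if label_map is not None else f"H{k}"
        haplotypes.append(Haplotype(label=label, sequence=seq,
                                    count=counts[seq], occurrences=dict(occ[seq])))
    return HaplotypeIndex(haplotypes=tuple(haplotypes))


def _code_matrix(aln: Alignment) -> np.ndarray:
    """int8 matrix; A,C,G,T → 0..3, N/- → -1 (missing)."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
    mat = np.frombuffer("".join(aln.sequences).encode(), dtype=np.uint8)
    return lut[mat].reshape(aln.n, aln.length)


def pairwise_differences(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-deletion difference counts.

    Returns ``(diff, valid)``: for each pair (i, j), ``diff[i, j]`` is the
    number of sites where both sequences carry unambiguous bases that
    differ, and ``valid[i, j]`` the number of pairwise-complete sites.
    Both matrices are symmetric with zero diagonal (``valid`` diagonal
    holds each sequence's complete-site count). A pair with ``valid == 0``
    is incomparable; downstream distances are undefined there.
    """
    m = _code_matrix(aln)
    n = aln.n
    diff = np.zeros((n, n), dtype=np.int64)
    valid = np.zeros((n, n), dtype=np.int64)
    ok = m >= 0
    for i in range(n):
        both = ok[i] & ok[i:]
        d = ((m[i] != m[i:]) & both).sum(axis=1)
        v = both.sum(axis=1)
        diff[i, i:] = d
        diff[i:, i] = d
        valid[i, i:] = v
        valid[i:, i] = v
    np.fill_diagonal(diff, 0)
    return diff, valid


def complete_deletion_columns(aln: Alignment) -> np.ndarray:
    """Site matrix restricted to columns with no missing data anywhere."""
    m = _code_matrix(aln)
    return m[:, (m >= 0).all(axis=0)]


def segregating_sites(aln: Alignment) -> int:
    """Number of polymorphic sites under complete deletion."""
    m = complete_deletion_columns(aln)
    if m.size == 0:
        return 0
    return int((m != m[0]).any(axis=0).sum())


def mean_pairwise_differences(aln: Alignment, complete_deletion: bool = True
                              ) -> float:
    """Mean number of pairwise differences (count scale, k-bar)."""
    if aln.n < 2:
        raise AlignmentError("need at least two sequences")
    if complete_deletion:
        m = complete_deletion_columns(aln)
        total = 0
        n = aln.n
        for i in range(n):
            total += (m[i] != m[i + 1:]).sum()
        return float(total) / (n * (n - 1) / 2)
    diff, _ = pairwise_differences(aln)
    n = aln.n
    iu = np.triu_indices(n, k=1)
    return float(diff[iu].mean())


_INVERT_MITO = CodonTable.unambiguous_dna_by_id[5]  # invertebrate mitochondrial


def translate_codons(seq: str, code: int = 5, frame: int = 0) -> str:
    """Translate a nucleotide string codon by codon.

    ``code`` is an NCBI genetic-code id (default 5, invertebrate
    mitochondrial). Codons containing gaps or N translate to ``X``;
    the incomplete trailing codon is dropped; stop codons yield ``*``.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    s = normalize_sequence(seq)[frame:]
    if len(s) < 3:
        raise AlignmentError("fewer than one complete codon after frame shift")
    table = CodonTable.unambiguous_dna_by_id[code]
    out = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i:i + 3]
        if set(codon) - set("ACGT"):
            out.append("X")
        elif codon in table.stop_codons:
            out.append("*")
        else:
            out.append(table.forward_table[codon])
    return "".join(out)


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between (lat, lon) points in degrees."""
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * 6371.0 * math.asin(min(1.0, math.sqrt(h)))
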