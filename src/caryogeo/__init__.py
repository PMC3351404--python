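"""caryogeo: comparative phylogeography of multi-deme haplotype samples.

Library surface, by stage:

* :mod:`caryogeo.seq_data` — alignments, locality tables, haplotype
  collapsing, pairwise-deletion distances, codon translation.
* :mod:`caryogeo.diversity` — haplotype diversity H, nucleotide
  diversity pi, per-locality and dataset summaries.
* :mod:`caryogeo.neutrality` — Tajima's D, Fu's Fs, coalescent nulls,
  mismatch distributions, raggedness, McDonald-Kreitman counts.
* :mod:`caryogeo.network_motu` — statistical-parsimony networks, loop
  resolution, nesting design, MOTU assignment.
* :mod:`caryogeo.rlr` — refugium localization reconstruction and
  harmonic-mean Bayes factors.
* :mod:`caryogeo.synthetic` — structured-coalescent scenario generator
  with a recorded source deme.
* :mod:`caryogeo.pipeline` — end-to-end orchestration.
"""

from importlib.resources import files as _files

__version__ = "0.1.0"


def example_locality_table_path():
    """Path to the bundled Carychium sampling-locality table (TSV)."""
    return _files("caryogeo.data").joinpath("carychium_localities.tsv")
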