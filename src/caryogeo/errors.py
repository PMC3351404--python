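"""Exception hierarchy shared across the package."""


class CaryogeoError(Exception):
    """Base class for all package errors."""


class AlignmentError(CaryogeoError):
    """Malformed alignment: unequal lengths, empty input, bad symbols."""


class LocalityTableError(CaryogeoError):
    """Malformed locality table: duplicate codes, bad coordinates."""


class MappingError(CaryogeoError):
    """A sequence id or haplotype occurrence lacks a valid locality."""


class NotCalculable(CaryogeoError):
    """A statistic is undefined for the given input (e.g. n = 1)."""


class TreeError(CaryogeoError):
    """Tree sample problems: unrooted trees, bad subsample counts."""


class SimulationError(CaryogeoError):
    """Synthetic-data generation failures (non-coalescence, site exhaustion)."""
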