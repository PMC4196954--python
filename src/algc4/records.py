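"""Core domain records: protein sequences, short reads, and the read-quality filter config.

Protein records carry organism and taxon-group metadata because every
downstream step (enzyme typing, inventory building, origin assignment)
is stratified by lineage.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class TaxonGroup(str, Enum):
    """Closed set of lineage labels used throughout the toolkit."""

    archaea = "archaea"
    proteobacteria = "proteobacteria"
    cyanobacteria = "cyanobacteria"
    rhodophyta = "rhodophyta"
    chlorophyta_plants = "chlorophyta_plants"
    ochrophyta = "ochrophyta"
    cryptophyta = "cryptophyta"
    glaucophyta = "glaucophyta"
    other = "other"


#: Prokaryotic groups eligible as gene donors in origin assignment.
PROKARYOTE_GROUPS = frozenset(
    {TaxonGroup.archaea, TaxonGroup.proteobacteria, TaxonGroup.cyanobacteria}
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")
DNA_ALPHABET = frozenset("ACGTN")


@dataclass
class ProteinRecord:
    """One protein sequence plus its lineage metadata.

    A terminal stop ('*') is stripped from ``residues`` at construction and
    remembered on ``had_stop`` so writers can round-trip it.
    """

    id: str
    organism: str
    taxon_group: TaxonGroup
    residues: str
    enzyme_label: str | None = None
    had_stop: bool = field(default=False)

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if self.residues.endswith("*"):
            self.residues = self.residues[:-1]
            self.had_stop = True
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence after stripping '*'")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues, 1) if c in bad)
            raise ValueError(
                f"record {self.id!r}: illegal residue {self.residues[pos - 1]!r} at position {pos}"
            )
        if not isinstance(self.taxon_group, TaxonGroup):
            self.taxon_group = TaxonGroup(self.taxon_group)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ReadRecord:
    """A short sequencing read with per-base Phred quality scores."""

    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: bases ({len(self.bases)}) and quals "
                f"({len(self.quals)}) differ in length"
            )
        if len(self.bases) == 0:
            raise ValueError(f"read {self.id!r}: empty read")
        bad = set(self.bases) - DNA_ALPHABET
        if bad:
            raise ValueError(f"read {self.id!r}: illegal base(s) {sorted(bad)}")
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id!r}: negative Phred score")


@dataclass(frozen=True)
class ReadFilterConfig:
    """Thresholds for the read-quality filter.

    A read is discarded when *more than* ``max_low_quality_fraction`` of its
    bases fall below ``low_quality_threshold`` (Phred), or *more than*
    ``max_n_fraction`` of its bases are N.  Both comparisons are strict, so
    reads sitting exactly on a bound are kept.
    """

    max_low_quality_fraction: float = 0.10
    low_quality_threshold: int = 20
    max_n_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("max_low_quality_fraction", "max_n_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.low_quality_threshold < 0:
            raise ValueError("low_quality_threshold must be >= 0")
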