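"""Core domain types shared across the pipeline.

Coordinates are 1-based, fully closed intervals throughout (VCF POS/END
convention); conversion to 0-based half-open happens only at BED-style
export boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator

from .errors import DataError

__all__ = [
    "Caller",
    "Category",
    "Zygosity",
    "SvKind",
    "VariantRecord",
    "Primitive",
    "SvCall",
    "MutationEvent",
    "TreatmentCatalog",
    "Genome",
    "GeneModel",
]


class Caller(str, Enum):
    """Variant-caller roles in the five-caller panel."""

    SNV_INDEL = "snv_indel_caller"
    SR = "sr_caller"
    RP = "rp_caller"
    COMBINED_A = "combined_caller_a"
    COMBINED_B = "combined_caller_b"


class Category(str, Enum):
    """Eight-way mutation classification."""

    SBS = "SBS"
    INS1 = "Ins1"
    DEL1 = "Del1"
    INS2_99 = "Ins2_99"
    DEL2_99 = "Del2_99"
    DEL_GE100 = "DelGE100"
    SV = "SV"
    COMPLEX = "Complex"


#: Categories counted as rearrangements (rejoining of two distant breaks).
REARRANGEMENT_CATEGORIES = frozenset({Category.SV, Category.DEL_GE100})


class Zygosity(str, Enum):
    HOM = "hom"
    HET = "het"


class SvKind(str, Enum):
    INVERSION = "inversion"
    TRANSLOCATION = "translocation"
    NONE = "none"


@dataclass(frozen=True)
class VariantRecord:
    """One caller-reported candidate site.

    ``allele_fraction`` is the proportion of mutant-supporting reads at
    the site.  ``end_pos``/``sv_length`` are populated for SV records,
    ``mate_id`` for breakends (mates are cross-linked by record id).
    """

    sample_id: str
    caller: Caller
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    allele_fraction: float
    depth: int
    end_pos: int | None = None
    sv_length: int | None = None
    mate_id: str | None = None
    record_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"pos must be >= 1, got {self.pos}")
        if self.end_pos is not None and self.end_pos < self.pos:
            raise DataError(f"end_pos {self.end_pos} < pos {self.pos}")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise DataError(
                f"allele_fraction must be in [0,1], got {self.allele_fraction}"
            )
        if self.depth < 0:
            raise DataError(f"depth must be >= 0, got {self.depth}")

    @property
    def is_symbolic(self) -> bool:
        return self.alt_allele.startswith("<")

    @property
    def is_breakend(self) -> bool:
        return self.mate_id is not None or any(
            c in self.alt_allele for c in "[]"
        )

    @property
    def is_sv(self) -> bool:
        return self.is_symbolic or self.is_breakend


@dataclass(frozen=True)
class Primitive:
    """A primitive sequence change: substitution tract or short indel.

    ``start``..``end`` is the affected reference span (for a pure
    insertion ``end == start`` and the insertion sits after ``start``).
    ``deleted_bp``/``inserted_bp`` give the signed-length bookkeeping; a
    putative deletion with an accompanying unknown-sequence insertion
    nets out to their difference.
    """

    chrom: str
    start: int
    end: int
    deleted_bp: int
    inserted_bp: int
    ref: str = ""
    alt: str = ""

    @property
    def net_length(self) -> int:
        return self.inserted_bp - self.deleted_bp

    @property
    def is_substitution(self) -> bool:
        return self.deleted_bp == self.inserted_bp and self.deleted_bp >= 1

    @property
    def is_indel(self) -> bool:
        return self.net_length != 0

    @property
    def n_changed_bases(self) -> int:
        """Mismatching base count for substitution tracts, else 1."""
        if self.is_substitution and len(self.ref) == len(self.alt) >= 1:
            return sum(1 for r, a in zip(self.ref, self.alt) if r != a)
        return 1

    def to_json(self) -> dict:
        return {
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "deleted_bp": self.deleted_bp,
            "inserted_bp": self.inserted_bp,
            "ref": self.ref,
            "alt": self.alt,
        }

    @classmethod
    def from_json(cls, d: dict) -> "Primitive":
        return cls(**d)


@dataclass(frozen=True)
class SvCall:
    """A normalized structural-variation call (inversion or translocation).

    For translocations the two junction points are (chrom, start) and
    (mate_chrom, mate_pos); for inversions start..end is the inverted
    span on one chromosome.
    """

    kind: SvKind
    chrom: str
    start: int
    end: int
    mate_chrom: str | None = None
    mate_pos: int | None = None


@dataclass(frozen=True)
class MutationEvent:
    """A filtered, classified mutation event."""

    sample_id: str
    chrom: str
    start: int
    end: int
    category: Category
    net_length: int
    zygosity: Zygosity
    sv_kind: SvKind = SvKind.NONE
    structure_resolved: bool = True
    components: tuple[Primitive, ...] = ()
    source_callers: tuple[str, ...] = ()
    ref_allele: str = ""
    alt_allele: str = ""
    mate_chrom: str = ""
    mate_pos: int = 0
    event_id: str = ""

    def __post_init__(self) -> None:
        if self.category is Category.DEL2_99 and not 2 <= -self.net_length <= 99:
            raise DataError(
                f"Del2_99 requires net length in [-99,-2], got {self.net_length}"
            )
        if self.category is Category.DEL_GE100 and not -self.net_length >= 100:
            raise DataError(
                f"DelGE100 requires net length <= -100, got {self.net_length}"
            )
        if self.category is Category.COMPLEX and len(self.components) < 2:
            raise DataError("Complex events require >= 2 components")
        if self.category is Category.SV and self.sv_kind is SvKind.NONE:
            raise DataError("SV events require sv_kind")

    @property
    def is_rearrangement(self) -> bool:
        return self.category in REARRANGEMENT_CATEGORIES

    def identity(self) -> tuple:
        """Coordinates-and-class identity used for truth comparison."""
        return (
            self.sample_id,
            self.chrom,
            self.start,
            self.end,
            self.category,
            self.net_length,
            self.zygosity,
        )


@dataclass
class TreatmentCatalog:
    """All classified events for one treatment group, keyed per plant.

    Plants with zero events are represented explicitly (empty lists) so
    per-plant denominators are correct.
    """

    label: str
    plants: dict[str, list[MutationEvent]] = field(default_factory=dict)

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.plants.values())

    def events(self) -> Iterator[MutationEvent]:
        for plant in self.plants.values():
            yield from plant

    def add(self, event: MutationEvent) -> None:
        self.plants.setdefault(event.sample_id, []).append(event)

    @classmethod
    def from_events(
        cls,
        label: str,
        events: list[MutationEvent],
        plant_ids: list[str] | None = None,
    ) -> "TreatmentCatalog":
        cat = cls(label=label)
        for pid in plant_ids or []:
            cat.plants[pid] = []
        for ev in events:
            cat.add(ev)
        return cat


_ACGT = frozenset("ACGT")


@dataclass
class Genome:
    """Reference sequences keyed by chromosome name."""

    sequences: dict[str, str]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def gc_content(self) -> float:
        """GC fraction over unambiguous A/C/G/T bases only."""
        gc = acgt = 0
        for seq in self.sequences.values():
            for base in "GC":
                gc += seq.count(base)
            for base in "AT":
                acgt += seq.count(base)
        acgt += gc
        if acgt == 0:
            raise DataError("genome contains no A/C/G/T bases")
        return gc / acgt

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based closed-interval subsequence."""
        try:
            seq = self.sequences[chrom]
        except KeyError:
            raise DataError(f"unknown chromosome {chrom!r}") from None
        if start < 1 or end > len(seq) or end < start:
            raise DataError(f"span {chrom}:{start}-{end} outside sequence")
        return seq[start - 1 : end]


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (1-based closed) with strand and biotype."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise DataError(f"gene {self.gene_id}: bad strand {self.strand!r}")
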