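"""Candidate-site filters applied after caller harmonization.

Three rules, applied in order on the pooled per-sample candidate lists:

1. recurrence exclusion — a site observed in independently derived
   lines cannot be a true induced mutation, so sites shared by
   ``recurrence_min_samples_to_exclude`` or more samples are dropped
   from every sample (SV endpoints match within a configurable
   tolerance);
2. allele-fraction floor — sites with AF <= ``af_floor`` are dropped;
3. zygosity calling with a cross-sample purity check — heterozygous for
   ``af_floor < AF < hom_min_af``, homozygous for ``AF >= hom_min_af``,
   in both cases requiring every other sample's AF at the site to stay
   below ``other_sample_max_af``.

Boundaries are deliberately asymmetric: AF exactly at the floor is
excluded, AF exactly at ``hom_min_af`` is homozygous, and an
other-sample AF exactly at ``other_sample_max_af`` fails the purity
check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import ConfigError, DataError
from .records import VariantRecord, Zygosity

__all__ = [
    "FilterConfig",
    "ZygosityStatus",
    "ZygosityReason",
    "ZygosityCall",
    "call_zygosity",
    "filter_recurrent",
    "RecurrenceExclusion",
]


@dataclass(frozen=True)
class FilterConfig:
    af_floor: float = 0.25
    hom_min_af: float = 0.80
    other_sample_max_af: float = 0.05
    recurrence_min_samples_to_exclude: int = 2
    sv_endpoint_tolerance: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.af_floor < self.hom_min_af <= 1:
            raise ConfigError(
                "require 0 < af_floor < hom_min_af <= 1, got "
                f"af_floor={self.af_floor}, hom_min_af={self.hom_min_af}"
            )
        if not 0 <= self.other_sample_max_af < self.af_floor:
            raise ConfigError(
                "require 0 <= other_sample_max_af < af_floor, got "
                f"{self.other_sample_max_af}"
            )
        if self.recurrence_min_samples_to_exclude < 2:
            raise ConfigError("recurrence_min_samples_to_exclude must be >= 2")
        if self.sv_endpoint_tolerance < 0:
            raise ConfigError("sv_endpoint_tolerance must be >= 0")


class ZygosityStatus(str, Enum):
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    EXCLUDED = "excluded"


class ZygosityReason(str, Enum):
    AF_AT_OR_BELOW_FLOOR = "af_at_or_below_floor"
    RECURRENT_ACROSS_SAMPLES = "recurrent_across_samples"
    OTHER_SAMPLE_CONTAMINATION = "other_sample_contamination"
    PASSED = "passed"


@dataclass(frozen=True)
class ZygosityCall:
    status: ZygosityStatus
    reason: ZygosityReason

    def __post_init__(self) -> None:
        excluded = self.status is ZygosityStatus.EXCLUDED
        if excluded != (self.reason is not ZygosityReason.PASSED):
            raise DataError("status=excluded iff reason != passed")

    @property
    def zygosity(self) -> Zygosity:
        if self.status is ZygosityStatus.HOMOZYGOUS:
            return Zygosity.HOM
        if self.status is ZygosityStatus.HETEROZYGOUS:
            return Zygosity.HET
        raise DataError("excluded call has no zygosity")


def call_zygosity(
    af: float,
    other_sample_afs: list[float],
    config: FilterConfig | None = None,
) -> ZygosityCall:
    """Classify a site as hom/het/excluded from its allele fractions."""
    config = config or FilterConfig()
    for value in [af, *other_sample_afs]:
        if not 0.0 <= value <= 1.0:
            raise DataError(f"allele fraction outside [0,1]: {value}")
    if af <= config.af_floor:
        return ZygosityCall(
            ZygosityStatus.EXCLUDED, ZygosityReason.AF_AT_OR_BELOW_FLOOR
        )
    pure = all(x < config.other_sample_max_af for x in other_sample_afs)
    if not pure:
        return ZygosityCall(
            ZygosityStatus.EXCLUDED, ZygosityReason.OTHER_SAMPLE_CONTAMINATION
        )
    if af >= config.hom_min_af:
        return ZygosityCall(ZygosityStatus.HOMOZYGOUS, ZygosityReason.PASSED)
    return ZygosityCall(ZygosityStatus.HETEROZYGOUS, ZygosityReason.PASSED)


@dataclass(frozen=True)
class RecurrenceExclusion:
    """One recurrence-filter decision (for the exclusion log TSV)."""

    chrom: str
    pos: int
    key: str
    samples: tuple[str, ...]


def _site_group_key(rec: VariantRecord) -> tuple:
    """Exact identity for sequence-resolved variants; coarse for SVs."""
    if rec.is_breakend:
        return ("BND", rec.chrom)
    if rec.is_symbolic:
        return ("SYM", rec.chrom, rec.alt_allele)
    return ("SEQ", rec.chrom, rec.pos, rec.ref_allele, rec.alt_allele)


def filter_recurrent(
    sites: dict[str, list[VariantRecord]],
    config: FilterConfig | None = None,
) -> tuple[dict[str, list[VariantRecord]], list[RecurrenceExclusion]]:
    """Remove sites present in >= ``recurrence_min_samples_to_exclude`` samples.

    Sequence-resolved variants match on exact (chrom, pos, ref, alt);
    SV records (symbolic or breakend) of the same kind match when their
    positions lie within ``sv_endpoint_tolerance`` bp.  Excluded sites
    are removed from *all* samples and logged with the sample list.
    """
    config = config or FilterConfig()
    # Cluster records across samples.
    groups: dict[tuple, list[tuple[str, VariantRecord]]] = {}
    for sample, recs in sites.items():
        for rec in recs:
            groups.setdefault(_site_group_key(rec), []).append((sample, rec))

    excluded_ids: set[int] = set()
    log: list[RecurrenceExclusion] = []
    for key, members in groups.items():
        if key[0] == "SEQ":
            clusters = [members]
        else:
            clusters = _cluster_by_position(members, config.sv_endpoint_tolerance)
        for cluster in clusters:
            samples = sorted({s for s, _ in cluster})
            if len(samples) >= config.recurrence_min_samples_to_exclude:
                for _, rec in cluster:
                    excluded_ids.add(id(rec))
                rep = cluster[0][1]
                log.append(
                    RecurrenceExclusion(
                        chrom=rep.chrom,
                        pos=rep.pos,
                        key="/".join(str(k) for k in key),
                        samples=tuple(samples),
                    )
                )

    retained = {
        sample: [r for r in recs if id(r) not in excluded_ids]
        for sample, recs in sites.items()
    }
    return retained, log


def _cluster_by_position(
    members: list[tuple[str, VariantRecord]], tolerance: int
) -> list[list[tuple[str, VariantRecord]]]:
    """Single-linkage clustering of SV records by position."""
    ordered = sorted(members, key=lambda sr: sr[1].pos)
    clusters: list[list[tuple[str, VariantRecord]]] = []
    last_pos: int | None = None
    for sample, rec in ordered:
        if last_pos is not None and rec.pos - last_pos <= tolerance:
            clusters[-1].append((sample, rec))
        else:
            clusters.append([(sample, rec)])
        last_pos = rec.pos
    return clusters
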