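"""Normalization and eight-way classification of filtered variants.

Sequence-resolved caller records are trimmed into primitive changes
(substitution tracts and indels), multi-base substitution blocks are
split wherever a run of ``separator_run`` or more reference-matching
bases intervenes, and nearby primitives (inter-change gap below
``gap_threshold`` bases) are merged into complex events.  Net indel
length is the signed difference from the reference: a putative 10-base
deletion carrying a 3-base insertion of unknown sequence counts as a
7-base deletion.

Categories: SBS, Ins1, Del1, Ins2_99, Del2_99, DelGE100, SV (inversions
and translocations), Complex.  Net insertions of 100 bp or more have no
category and raise :class:`UnsupportedCategoryError`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .errors import DataError, UnsupportedCategoryError
from .records import (
    Category,
    MutationEvent,
    Primitive,
    SvCall,
    SvKind,
    VariantRecord,
    Zygosity,
)

__all__ = [
    "net_indel_length",
    "trim_alleles",
    "split_substitution_block",
    "normalize_variant",
    "pair_breakends",
    "categorize",
    "build_event",
    "merge_complex",
    "group_rearrangements",
    "RearrangementSet",
    "ComplexitySubclass",
    "complexity_subclass",
]

#: Indels with |net length| at or above this never join a complex cluster.
SHORT_INDEL_MAX = 10
DEFAULT_GAP_THRESHOLD = 10
DEFAULT_SEPARATOR_RUN = 2
DEFAULT_MIN_CLUSTER_SIZE = 2


def net_indel_length(deleted_bp: int, inserted_bp: int) -> int:
    """Signed net length change (negative = net deletion)."""
    if deleted_bp < 0 or inserted_bp < 0:
        raise DataError("deleted_bp and inserted_bp must be >= 0")
    if deleted_bp == 0 and inserted_bp == 0:
        raise DataError("no length change is not an InDel")
    return inserted_bp - deleted_bp


def trim_alleles(pos: int, ref: str, alt: str) -> Primitive | None:
    """Normalize an explicit REF/ALT pair into a single primitive.

    Common suffix then prefix bases are trimmed (VCF anchor-base style).
    Returns ``None`` when ref == alt.  Equal-length leftovers become a
    substitution tract; use :func:`split_substitution_block` to resolve
    internal reference-matching runs.
    """
    if not ref or not alt:
        raise DataError("empty REF or ALT allele")
    if ref == alt:
        return None
    # suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if len(ref) == len(alt):
        # strip a leading anchor that may remain on 1-vs-1 ties
        if len(ref) > 1 and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
        return Primitive(
            chrom="",
            start=pos,
            end=pos + len(ref) - 1,
            deleted_bp=len(ref),
            inserted_bp=len(alt),
            ref=ref,
            alt=alt,
        )
    if ref[0] == alt[0]:  # anchored indel
        if len(ref) > len(alt):  # deletion of ref[len(alt):]
            deleted = len(ref) - len(alt)
            return Primitive(
                chrom="",
                start=pos + 1,
                end=pos + deleted,
                deleted_bp=deleted,
                inserted_bp=0,
                ref=ref[1:],
                alt="",
            )
        inserted = len(alt) - len(ref)
        return Primitive(
            chrom="",
            start=pos,
            end=pos,
            deleted_bp=0,
            inserted_bp=inserted,
            ref="",
            alt=alt[1:],
        )
    # unanchored replacement: deletion + insertion in one record
    return Primitive(
        chrom="",
        start=pos,
        end=pos + len(ref) - 1,
        deleted_bp=len(ref),
        inserted_bp=len(alt),
        ref=ref,
        alt=alt,
    )


def split_substitution_block(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    separator_run: int = DEFAULT_SEPARATOR_RUN,
) -> list[Primitive]:
    """Split an equal-length substitution block at reference-matching runs.

    Runs of ``separator_run`` or more bases identical to the reference
    are taken as non-mutated sequence and separate the block into
    independent primitives; shorter matching runs stay inside a single
    substitution tract.
    """
    if len(ref) != len(alt):
        raise DataError("substitution block requires equal-length alleles")
    mismatches = [i for i in range(len(ref)) if ref[i] != alt[i]]
    if not mismatches:
        return []
    segments: list[tuple[int, int]] = []
    seg_start = mismatches[0]
    prev = mismatches[0]
    for i in mismatches[1:]:
        if i - prev - 1 >= separator_run:
            segments.append((seg_start, prev))
            seg_start = i
        prev = i
    segments.append((seg_start, prev))
    out = []
    for a, b in segments:
        out.append(
            Primitive(
                chrom=chrom,
                start=pos + a,
                end=pos + b,
                deleted_bp=b - a + 1,
                inserted_bp=b - a + 1,
                ref=ref[a : b + 1],
                alt=alt[a : b + 1],
            )
        )
    return out


def normalize_variant(
    rec: VariantRecord, separator_run: int = DEFAULT_SEPARATOR_RUN
) -> list[Primitive] | SvCall:
    """Normalize a non-breakend caller record into primitives or an SV call.

    Symbolic deletions/duplications collapse to the same canonical
    chrom/start/end/net-length representation as sequence-explicit ones.
    """
    if rec.is_breakend:
        raise DataError("breakend records must go through pair_breakends")
    if rec.is_symbolic:
        symbol = rec.alt_allele.strip("<>").split(":")[0]
        if rec.end_pos is None and rec.sv_length is None:
            raise DataError(
                f"{rec.chrom}:{rec.pos}: symbolic SV without END or SVLEN"
            )
        if symbol == "DEL":
            end = rec.end_pos
            if end is None:
                end = rec.pos + abs(rec.sv_length)  # type: ignore[arg-type]
            deleted = end - rec.pos
            return [
                Primitive(
                    chrom=rec.chrom,
                    start=rec.pos + 1,
                    end=end,
                    deleted_bp=deleted,
                    inserted_bp=0,
                )
            ]
        if symbol == "DUP":
            end = rec.end_pos or (rec.pos + abs(rec.sv_length or 0))
            return [
                Primitive(
                    chrom=rec.chrom,
                    start=rec.pos,
                    end=rec.pos,
                    deleted_bp=0,
                    inserted_bp=end - rec.pos,
                )
            ]
        if symbol == "INV":
            if rec.end_pos is None:
                raise DataError(f"{rec.chrom}:{rec.pos}: <INV> without END")
            return SvCall(
                kind=SvKind.INVERSION,
                chrom=rec.chrom,
                start=rec.pos,
                end=rec.end_pos,
            )
        raise DataError(f"unsupported symbolic allele {rec.alt_allele!r}")
    prim = trim_alleles(rec.pos, rec.ref_allele, rec.alt_allele)
    if prim is None:
        return []
    prim = Primitive(
        chrom=rec.chrom,
        start=prim.start,
        end=prim.end,
        deleted_bp=prim.deleted_bp,
        inserted_bp=prim.inserted_bp,
        ref=prim.ref,
        alt=prim.alt,
    )
    if prim.is_substitution and len(prim.ref) > 1:
        return split_substitution_block(
            rec.chrom, prim.start, prim.ref, prim.alt, separator_run
        )
    return [prim]


def pair_breakends(
    records: Sequence[VariantRecord],
) -> list[tuple[SvCall, tuple[VariantRecord, VariantRecord]]]:
    """Collapse mated breakend pairs into single SV calls.

    Two inter-chromosomal mates form one translocation (the junction
    pair is canonically ordered); same-chromosome mates form one
    inversion spanning the two junction points.
    """
    by_id = {r.record_id: r for r in records if r.record_id}
    seen: set[str] = set()
    out: list[tuple[SvCall, tuple[VariantRecord, VariantRecord]]] = []
    for rec in records:
        if rec.record_id in seen:
            continue
        if rec.mate_id is None:
            raise DataError(
                f"breakend {rec.record_id} at {rec.chrom}:{rec.pos} lacks MATEID"
            )
        mate = by_id.get(rec.mate_id)
        if mate is None:
            from .errors import OrphanBreakendError

            raise OrphanBreakendError(
                f"breakend {rec.record_id} has no mate {rec.mate_id!r}"
            )
        seen.update({rec.record_id, mate.record_id})
        a, b = sorted([rec, mate], key=lambda r: (r.chrom, r.pos))
        if a.chrom == b.chrom:
            call = SvCall(
                kind=SvKind.INVERSION, chrom=a.chrom, start=a.pos, end=b.pos
            )
        else:
            call = SvCall(
                kind=SvKind.TRANSLOCATION,
                chrom=a.chrom,
                start=a.pos,
                end=a.pos,
                mate_chrom=b.chrom,
                mate_pos=b.pos,
            )
        out.append((call, (a, b)))
    return out


def categorize(change: Primitive | SvCall) -> Category:
    """Assign the eight-way category to a normalized change."""
    if isinstance(change, SvCall):
        return Category.SV
    if not isinstance(change, Primitive):
        raise DataError(f"cannot categorize {type(change).__name__}")
    if change.is_substitution:
        return Category.SBS if change.n_changed_bases == 1 else Category.COMPLEX
    net = change.net_length
    if net == -1:
        return Category.DEL1
    if net == 1:
        return Category.INS1
    if -99 <= net <= -2:
        return Category.DEL2_99
    if 2 <= net <= 99:
        return Category.INS2_99
    if net <= -100:
        return Category.DEL_GE100
    raise UnsupportedCategoryError(
        f"net insertion of {net} bp (>= 100 bp) has no category"
    )


def _expand_components(p: Primitive) -> list[Primitive]:
    """Expand a multi-mismatch substitution tract into per-base SBSs."""
    if (
        p.is_substitution
        and len(p.ref) == len(p.alt) >= 1
        and p.n_changed_bases >= 2
    ):
        return [
            Primitive(
                chrom=p.chrom,
                start=p.start + i,
                end=p.start + i,
                deleted_bp=1,
                inserted_bp=1,
                ref=p.ref[i],
                alt=p.alt[i],
            )
            for i in range(len(p.ref))
            if p.ref[i] != p.alt[i]
        ]
    return [p]


def build_event(
    change: Primitive | SvCall,
    sample_id: str,
    zygosity: Zygosity,
    source_callers: tuple[str, ...] = (),
    event_id: str = "",
    structure_resolved: bool = True,
) -> MutationEvent:
    """Wrap a single normalized change as a classified event."""
    category = categorize(change)
    if isinstance(change, SvCall):
        return MutationEvent(
            sample_id=sample_id,
            chrom=change.chrom,
            start=change.start,
            end=change.end,
            category=Category.SV,
            net_length=0,
            zygosity=zygosity,
            sv_kind=change.kind,
            structure_resolved=structure_resolved,
            mate_chrom=change.mate_chrom or "",
            mate_pos=change.mate_pos or 0,
            source_callers=source_callers,
            event_id=event_id,
        )
    if category is Category.COMPLEX:
        components = tuple(_expand_components(change))
        return MutationEvent(
            sample_id=sample_id,
            chrom=change.chrom,
            start=change.start,
            end=change.end,
            category=Category.COMPLEX,
            net_length=change.net_length,
            zygosity=zygosity,
            components=components,
            source_callers=source_callers,
            event_id=event_id,
        )
    return MutationEvent(
        sample_id=sample_id,
        chrom=change.chrom,
        start=change.start,
        end=change.end,
        category=category,
        net_length=0 if category is Category.SBS else change.net_length,
        zygosity=zygosity,
        ref_allele=change.ref,
        alt_allele=change.alt,
        source_callers=source_callers,
        event_id=event_id,
    )


def merge_complex(
    primitives: Sequence[Primitive],
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    short_indel_max: int = SHORT_INDEL_MAX,
    sample_id: str = "",
    zygosities: Sequence[Zygosity] | None = None,
    callers: Sequence[tuple[str, ...]] | None = None,
) -> list[MutationEvent]:
    """Merge nearby primitives on one sample+chromosome into events.

    Primitives whose inter-change gaps are all below ``gap_threshold``
    form one cluster; clusters of ``min_cluster_size`` or more become a
    single complex event.  Indels with |net length| >=
    ``short_indel_max`` never participate in clustering and always pass
    through as their own events.  Input must be position-sorted and
    non-overlapping.
    """
    if zygosities is None:
        zygosities = [Zygosity.HET] * len(primitives)
    if callers is None:
        callers = [()] * len(primitives)
    if not (len(primitives) == len(zygosities) == len(callers)):
        raise DataError("primitives/zygosities/callers length mismatch")
    for a, b in zip(primitives, primitives[1:]):
        if b.start < a.start:
            raise DataError("primitives must be position-sorted")
        if b.start <= a.end:
            raise DataError(
                f"overlapping primitives at {a.chrom}:{a.start}-{a.end} "
                f"and {b.start}"
            )

    def mergeable(p: Primitive) -> bool:
        return abs(p.net_length) < short_indel_max

    clusters: list[list[int]] = []
    for i, p in enumerate(primitives):
        if clusters and mergeable(p):
            prev = primitives[clusters[-1][-1]]
            gap = p.start - prev.end - 1
            if mergeable(prev) and gap < gap_threshold:
                clusters[-1].append(i)
                continue
        clusters.append([i])

    events: list[MutationEvent] = []
    for idx in clusters:
        members = [primitives[i] for i in idx]
        zygs = [zygosities[i] for i in idx]
        srcs = tuple(
            sorted({c for i in idx for c in callers[i]})
        )
        zyg = _majority_zygosity(zygs)
        if len(members) >= min_cluster_size:
            components = tuple(
                c for m in members for c in _expand_components(m)
            )
            events.append(
                MutationEvent(
                    sample_id=sample_id,
                    chrom=members[0].chrom,
                    start=members[0].start,
                    end=max(m.end for m in members),
                    category=Category.COMPLEX,
                    net_length=sum(m.net_length for m in members),
                    zygosity=zyg,
                    components=components,
                    source_callers=srcs,
                )
            )
        else:
            for i in idx:
                events.append(
                    build_event(
                        primitives[i],
                        sample_id,
                        zygosities[i],
                        source_callers=tuple(sorted(callers[i])),
                    )
                )
    return events


def _majority_zygosity(zygs: Sequence[Zygosity]) -> Zygosity:
    counts = Counter(zygs)
    if counts[Zygosity.HOM] > counts[Zygosity.HET]:
        return Zygosity.HOM
    return Zygosity.HET


@dataclass
class RearrangementSet:
    """Events interpreted as rejoining of two distant breaks."""

    events: list[MutationEvent]

    def __len__(self) -> int:
        return len(self.events)


def group_rearrangements(events) -> RearrangementSet:
    """Select SV and DelGE100 events from a catalog or event iterable."""
    if hasattr(events, "events"):
        events = events.events()
    return RearrangementSet(
        events=[e for e in events if e.is_rearrangement]
    )


class ComplexitySubclass(str, Enum):
    NO_INDEL = "no_indel"
    ONE_INDEL = "one_indel"
    TWO_PLUS_INDELS = "two_plus_indels"


def complexity_subclass(event: MutationEvent) -> ComplexitySubclass:
    """Subclassify a complex event by how many of its components are indels."""
    if event.category is not Category.COMPLEX:
        raise DataError("complexity_subclass requires a Complex event")
    n_indels = sum(1 for c in event.components if c.is_indel)
    if n_indels == 0:
        return ComplexitySubclass.NO_INDEL
    if n_indels == 1:
        return ComplexitySubclass.ONE_INDEL
    return ComplexitySubclass.TWO_PLUS_INDELS
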