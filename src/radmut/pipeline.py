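"""Stage orchestration: caller records -> filtered -> classified events.

This glues the per-module operations into the canonical chain:
recurrence filtering across samples, AF-floor + zygosity calling with
cross-sample purity, per-sample cross-caller deduplication, breakend
pairing, normalization and complex merging.  Counts in and out of every
stage are collected so logs reconcile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataError
from .event_classification import (
    DEFAULT_GAP_THRESHOLD,
    DEFAULT_MIN_CLUSTER_SIZE,
    DEFAULT_SEPARATOR_RUN,
    SHORT_INDEL_MAX,
    build_event,
    merge_complex,
    normalize_variant,
    pair_breakends,
)
from .records import (
    MutationEvent,
    Primitive,
    SvCall,
    SvKind,
    TreatmentCatalog,
    VariantRecord,
    Zygosity,
)
from .site_filtering import (
    FilterConfig,
    ZygosityReason,
    ZygosityStatus,
    call_zygosity,
    filter_recurrent,
)

__all__ = ["ClassifyOptions", "StageLog", "run_sample_chain", "run_cohort"]


@dataclass(frozen=True)
class ClassifyOptions:
    gap_threshold: int = DEFAULT_GAP_THRESHOLD
    separator_run: int = DEFAULT_SEPARATOR_RUN
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
    short_indel_max: int = SHORT_INDEL_MAX


@dataclass
class StageLog:
    """Per-stage in/out bookkeeping so totals reconcile."""

    n_input_records: int = 0
    n_recurrent_excluded: int = 0
    n_af_excluded: int = 0
    n_contamination_excluded: int = 0
    n_retained_records: int = 0
    n_events: int = 0
    recurrence_log: list = field(default_factory=list)
    zygosity_exclusions: list = field(default_factory=list)


def _seq_key(rec: VariantRecord) -> tuple:
    return (rec.chrom, rec.pos, rec.ref_allele, rec.alt_allele)


def _af_lookup(records_by_sample: dict[str, list[VariantRecord]]) -> dict:
    """(site key) -> {sample: af} over sequence-resolved records."""
    lookup: dict[tuple, dict[str, float]] = {}
    for sample, recs in records_by_sample.items():
        for rec in recs:
            if rec.is_sv:
                continue
            lookup.setdefault(_seq_key(rec), {})[sample] = max(
                rec.allele_fraction,
                lookup.get(_seq_key(rec), {}).get(sample, 0.0),
            )
    return lookup


def _dedupe_primitives(
    items: list[tuple[Primitive, Zygosity, tuple[str, ...], float]],
) -> list[tuple[Primitive, Zygosity, tuple[str, ...]]]:
    """Merge identical changes reported by several callers."""
    merged: dict[tuple, list] = {}
    for prim, zyg, callers, af in items:
        key = (prim.chrom, prim.start, prim.end, prim.deleted_bp, prim.inserted_bp)
        merged.setdefault(key, []).append((prim, zyg, callers, af))
    out = []
    for group in merged.values():
        prim = group[0][0]
        zyg = group[0][1]
        callers = tuple(sorted({c for _, _, cs, _ in group for c in cs}))
        out.append((prim, zyg, callers))
    return out


def _dedupe_svs(
    items: list[tuple[SvCall, Zygosity, tuple[str, ...]]],
    tolerance: int,
) -> list[tuple[SvCall, Zygosity, tuple[str, ...]]]:
    out: list[tuple[SvCall, Zygosity, tuple[str, ...]]] = []
    for call, zyg, callers in items:
        matched = False
        for i, (other, ozyg, ocallers) in enumerate(out):
            if (
                other.kind == call.kind
                and other.chrom == call.chrom
                and other.mate_chrom == call.mate_chrom
                and abs(other.start - call.start) <= tolerance
                and abs(other.end - call.end) <= tolerance
                and abs((other.mate_pos or 0) - (call.mate_pos or 0)) <= tolerance
            ):
                out[i] = (
                    other,
                    ozyg,
                    tuple(sorted(set(ocallers) | set(callers))),
                )
                matched = True
                break
        if not matched:
            out.append((call, zyg, callers))
    return out


def run_sample_chain(
    sample_id: str,
    records: list[VariantRecord],
    af_lookup: dict,
    config: FilterConfig,
    options: ClassifyOptions,
    log: StageLog,
) -> list[MutationEvent]:
    """Zygosity-call, deduplicate, normalize and classify one sample."""
    # 1. zygosity per record
    kept: list[tuple[VariantRecord, Zygosity]] = []
    for rec in records:
        if rec.is_sv:
            others: list[float] = []
        else:
            site = af_lookup.get(_seq_key(rec), {})
            others = [af for s, af in site.items() if s != sample_id]
        call = call_zygosity(rec.allele_fraction, others, config)
        if call.status is ZygosityStatus.EXCLUDED:
            if call.reason is ZygosityReason.AF_AT_OR_BELOW_FLOOR:
                log.n_af_excluded += 1
            else:
                log.n_contamination_excluded += 1
            log.zygosity_exclusions.append(
                (sample_id, rec.chrom, rec.pos, call.reason.value)
            )
            continue
        kept.append((rec, call.zygosity))
    log.n_retained_records += len(kept)

    # 2. breakend pairing (per caller to keep mate-id namespaces separate)
    sv_items: list[tuple[SvCall, Zygosity, tuple[str, ...]]] = []
    seq_items: list[tuple[Primitive, Zygosity, tuple[str, ...], float]] = []
    by_caller_bnds: dict[str, list[VariantRecord]] = {}
    zyg_of: dict[int, Zygosity] = {}
    for rec, zyg in kept:
        zyg_of[id(rec)] = zyg
        if rec.is_breakend:
            by_caller_bnds.setdefault(rec.caller.value, []).append(rec)
        else:
            result = normalize_variant(rec, options.separator_run)
            if isinstance(result, SvCall):
                sv_items.append((result, zyg, (rec.caller.value,)))
            else:
                for prim in result:
                    seq_items.append(
                        (prim, zyg, (rec.caller.value,), rec.allele_fraction)
                    )
    for caller, bnds in by_caller_bnds.items():
        for call, (a, _b) in pair_breakends(bnds):
            sv_items.append((call, zyg_of[id(a)], (caller,)))

    # 3. cross-caller dedup
    prims = _dedupe_primitives(seq_items)
    svs = _dedupe_svs(sv_items, config.sv_endpoint_tolerance)

    # 4. merge + classify
    events: list[MutationEvent] = []
    by_chrom: dict[str, list[tuple[Primitive, Zygosity, tuple[str, ...]]]] = {}
    for prim, zyg, callers in prims:
        by_chrom.setdefault(prim.chrom, []).append((prim, zyg, callers))
    for chrom in sorted(by_chrom):
        triples = sorted(by_chrom[chrom], key=lambda t: (t[0].start, t[0].end))
        events.extend(
            merge_complex(
                [t[0] for t in triples],
                gap_threshold=options.gap_threshold,
                min_cluster_size=options.min_cluster_size,
                short_indel_max=options.short_indel_max,
                sample_id=sample_id,
                zygosities=[t[1] for t in triples],
                callers=[t[2] for t in triples],
            )
        )
    for call, zyg, callers in svs:
        events.append(build_event(call, sample_id, zyg, source_callers=callers))
    events.sort(key=lambda e: (e.chrom, e.start, e.end))
    log.n_events += len(events)
    return events


def run_cohort(
    records_by_sample: dict[str, list[VariantRecord]],
    config: FilterConfig | None = None,
    options: ClassifyOptions | None = None,
    label: str = "cohort",
) -> tuple[TreatmentCatalog, StageLog]:
    """Full chain over a cohort of per-sample candidate records."""
    config = config or FilterConfig()
    options = options or ClassifyOptions()
    log = StageLog(
        n_input_records=sum(len(v) for v in records_by_sample.values())
    )
    retained, rec_log = filter_recurrent(records_by_sample, config)
    log.recurrence_log = rec_log
    log.n_recurrent_excluded = log.n_input_records - sum(
        len(v) for v in retained.values()
    )
    lookup = _af_lookup(records_by_sample)
    catalog = TreatmentCatalog(label=label)
    for sample in records_by_sample:
        catalog.plants[sample] = run_sample_chain(
            sample, retained.get(sample, []), lookup, config, options, log
        )
    return catalog, log
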