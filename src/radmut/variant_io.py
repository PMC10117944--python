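"""File IO: caller VCFs, reference FASTA, harmonized catalog TSV.

VCF input honors INFO keys END/SVLEN/SVTYPE/MATEID and FORMAT keys
AD/DP (plus AF when a caller emits it directly).  Writing VCF is out of
scope here; the synthetic-data module emits caller files itself.
"""

from __future__ import annotations

import csv
import json
from typing import Iterable

import pysam
from Bio import SeqIO

from .errors import DataError, OrphanBreakendError, VcfParseError
from .records import (
    Caller,
    Category,
    GeneModel,
    Genome,
    MutationEvent,
    Primitive,
    SvKind,
    VariantRecord,
    Zygosity,
)

__all__ = [
    "read_caller_vcf",
    "read_fasta",
    "write_catalog",
    "read_catalog",
    "write_records",
    "read_records",
    "read_gff3_genes",
]


def _prescan_vcf(path: str) -> None:
    """Cheap structural check so parse errors can name a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise VcfParseError(
                    f"expected >= 8 tab-separated fields, got {len(fields)}",
                    line_number=lineno,
                )
            if not fields[1].isdigit():
                raise VcfParseError(
                    f"POS is not a positive integer: {fields[1]!r}",
                    line_number=lineno,
                )


def _record_af_depth(rec: "pysam.VariantRecord") -> tuple[float, int]:
    """Allele fraction and depth for a single-sample record.

    Prefers an explicit FORMAT AF; otherwise computes alt-supporting
    reads / depth from AD/DP.
    """
    if not rec.samples:
        raise DataError(f"{rec.chrom}:{rec.pos}: record carries no sample data")
    sample = rec.samples[0]
    depth = sample.get("DP")
    ad = sample.get("AD")
    af = sample.get("AF")
    if af is not None:
        af = float(af[0] if isinstance(af, tuple) else af)
        return af, int(depth or 0)
    if ad is None or depth in (None, 0):
        raise DataError(
            f"{rec.chrom}:{rec.pos}: cannot determine allele fraction "
            "(no AF and no AD/DP)"
        )
    alt_reads = int(ad[1])
    return alt_reads / int(depth), int(depth)


def read_caller_vcf(path: str, caller: Caller, sample_id: str) -> list[VariantRecord]:
    """Read one caller's VCF into :class:`VariantRecord` objects.

    Breakend mates are cross-linked by MATEID; a breakend whose partner
    is absent raises :class:`OrphanBreakendError`.
    """
    _prescan_vcf(path)
    caller = Caller(caller)
    records: list[VariantRecord] = []
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(str(exc)) from exc
    with vf:
        for rec in vf:
            if rec.alts is None:
                continue
            alt = rec.alts[0]
            info = rec.info
            is_sv = alt.startswith("<") or "[" in alt or "]" in alt
            # pysam surfaces INFO/END as rec.stop (same value as the
            # 1-based inclusive END).
            end = info.get("END", rec.stop if is_sv else None)
            svlen = info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            mate_id = info.get("MATEID")
            if isinstance(mate_id, tuple):
                mate_id = mate_id[0]
            af, depth = _record_af_depth(rec)
            records.append(
                VariantRecord(
                    sample_id=sample_id,
                    caller=caller,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    allele_fraction=af,
                    depth=depth,
                    end_pos=int(end) if end is not None and is_sv else None,
                    sv_length=int(svlen) if svlen is not None else None,
                    mate_id=str(mate_id) if mate_id is not None else None,
                    record_id=rec.id,
                )
            )
    _check_breakend_pairing(records)
    return records


def _check_breakend_pairing(records: Iterable[VariantRecord]) -> None:
    bnds = {r.record_id: r for r in records if r.mate_id is not None}
    for rec in bnds.values():
        mate = bnds.get(rec.mate_id)
        if mate is None or mate.mate_id != rec.record_id:
            raise OrphanBreakendError(
                f"breakend {rec.record_id} at {rec.chrom}:{rec.pos} has no "
                f"mate {rec.mate_id!r}"
            )


_IUPAC = frozenset("ACGTURYSWKMBDHVN")


def read_fasta(path: str) -> Genome:
    """Read a FASTA reference into a :class:`Genome`."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise DataError(
                f"record {rec.id!r} contains non-nucleotide characters: "
                f"{sorted(bad)}"
            )
        sequences[rec.id] = seq
    if not sequences:
        raise DataError(f"no FASTA records in {path!r}")
    return Genome(sequences=sequences)


# Fixed catalog column order; the first eight are the documented core.
CATALOG_COLUMNS = [
    "sample",
    "chrom",
    "start",
    "end",
    "category",
    "net_length",
    "zygosity",
    "source_callers",
    "sv_kind",
    "structure_resolved",
    "mate_chrom",
    "mate_pos",
    "ref",
    "alt",
    "components",
    "event_id",
]


def write_catalog(events: list[MutationEvent], path: str) -> None:
    """Write classified events as TSV (lossless round trip)."""
    for ev in events:
        if not isinstance(ev.category, Category):
            raise DataError(f"unclassified event at {ev.chrom}:{ev.start}")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CATALOG_COLUMNS)
        for ev in events:
            w.writerow(
                [
                    ev.sample_id,
                    ev.chrom,
                    ev.start,
                    ev.end,
                    ev.category.value,
                    ev.net_length,
                    ev.zygosity.value,
                    ",".join(ev.source_callers),
                    ev.sv_kind.value,
                    "true" if ev.structure_resolved else "false",
                    ev.mate_chrom,
                    ev.mate_pos,
                    ev.ref_allele,
                    ev.alt_allele,
                    json.dumps([c.to_json() for c in ev.components])
                    if ev.components
                    else "",
                    ev.event_id,
                ]
            )


def read_catalog(path: str) -> list[MutationEvent]:
    """Inverse of :func:`write_catalog`."""
    events: list[MutationEvent] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != CATALOG_COLUMNS:
            raise DataError(f"unexpected catalog header in {path!r}: {header}")
        for row in reader:
            d = dict(zip(CATALOG_COLUMNS, row))
            events.append(
                MutationEvent(
                    sample_id=d["sample"],
                    chrom=d["chrom"],
                    start=int(d["start"]),
                    end=int(d["end"]),
                    category=Category(d["category"]),
                    net_length=int(d["net_length"]),
                    zygosity=Zygosity(d["zygosity"]),
                    source_callers=tuple(
                        c for c in d["source_callers"].split(",") if c
                    ),
                    sv_kind=SvKind(d["sv_kind"]),
                    structure_resolved=d["structure_resolved"] == "true",
                    mate_chrom=d["mate_chrom"],
                    mate_pos=int(d["mate_pos"]),
                    ref_allele=d["ref"],
                    alt_allele=d["alt"],
                    components=tuple(
                        Primitive.from_json(c)
                        for c in json.loads(d["components"])
                    )
                    if d["components"]
                    else (),
                    event_id=d["event_id"],
                )
            )
    return events


RECORD_COLUMNS = [
    "sample",
    "caller",
    "chrom",
    "pos",
    "ref",
    "alt",
    "allele_fraction",
    "depth",
    "end_pos",
    "sv_length",
    "mate_id",
    "record_id",
]


def write_records(records: list[VariantRecord], path: str) -> None:
    """Stage candidate-site records between CLI steps (TSV)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RECORD_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.sample_id,
                    r.caller.value,
                    r.chrom,
                    r.pos,
                    r.ref_allele,
                    r.alt_allele,
                    repr(r.allele_fraction),
                    r.depth,
                    "" if r.end_pos is None else r.end_pos,
                    "" if r.sv_length is None else r.sv_length,
                    r.mate_id or "",
                    r.record_id or "",
                ]
            )


def read_records(path: str) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != RECORD_COLUMNS:
            raise DataError(f"unexpected records header in {path!r}: {header}")
        for row in reader:
            d = dict(zip(RECORD_COLUMNS, row))
            records.append(
                VariantRecord(
                    sample_id=d["sample"],
                    caller=Caller(d["caller"]),
                    chrom=d["chrom"],
                    pos=int(d["pos"]),
                    ref_allele=d["ref"],
                    alt_allele=d["alt"],
                    allele_fraction=float(d["allele_fraction"]),
                    depth=int(d["depth"]),
                    end_pos=int(d["end_pos"]) if d["end_pos"] else None,
                    sv_length=int(d["sv_length"]) if d["sv_length"] else None,
                    mate_id=d["mate_id"] or None,
                    record_id=d["record_id"] or None,
                )
            )
    return records


def read_gff3_genes(path: str) -> list[GeneModel]:
    """Read gene features from a GFF3 subset (``gene`` lines only).

    Biotype is taken from a ``biotype=`` or ``gene_biotype=`` attribute,
    defaulting to ``protein_coding``.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise DataError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr.get("ID", f"gene_{lineno}")
            if gene_id in seen:
                raise DataError(f"{path}:{lineno}: duplicate gene id {gene_id}")
            seen.add(gene_id)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                    biotype=attr.get(
                        "biotype", attr.get("gene_biotype", "protein_coding")
                    ),
                )
            )
    return genes
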