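"""Synthetic inputs for exercising every pipeline stage offline.

Generates a reference genome with a target GC content, non-overlapping
gene models (with a packed-block option for multi-gene-deletion
fixtures), ground-truth per-plant mutation catalogs drawn from
configurable treatment profiles, noisy multi-caller VCF emissions with
traceable true/false-positive labels, and binomially sampled survival
assays.

The default treatment profiles encode qualitative contrasts between the
material-radiation combinations (carbon: more 2-99 bp deletions and
rearrangements; gamma: more substitutions; dry material: more A:T>T:A)
and are illustrative compositions, not published estimates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .records import (
    Caller,
    Category,
    GeneModel,
    Genome,
    MutationEvent,
    Primitive,
    SvKind,
    TreatmentCatalog,
    Zygosity,
)
from .survival_model import SurvivalCurve, survival

__all__ = [
    "make_genome",
    "write_fasta",
    "make_gene_models",
    "write_gff3",
    "TreatmentProfile",
    "default_profiles",
    "SyntheticTruth",
    "simulate_catalog",
    "NoiseModel",
    "EmissionResult",
    "emit_caller_outputs",
    "simulate_survival",
    "CALLER_VISIBILITY",
]

_BASES = np.array(list("ACGT"))
MIN_GENOME_LENGTH = 10_000


def make_genome(
    length: int,
    gc: float = 0.36,
    seed: int | None = None,
    n_chroms: int = 1,
) -> Genome:
    """I.i.d. random genome with P(G) + P(C) = ``gc``.

    The total ``length`` is split evenly across ``n_chroms``
    chromosomes named ``chr1``..``chrN``.
    """
    if not 0 < gc < 1:
        raise ConfigError(f"gc must be in (0,1), got {gc}")
    if length < MIN_GENOME_LENGTH:
        raise ConfigError(f"length must be >= {MIN_GENOME_LENGTH}, got {length}")
    if n_chroms < 1:
        raise ConfigError("n_chroms must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    per = [length // n_chroms] * n_chroms
    per[-1] += length - sum(per)
    sequences = {}
    for i, n in enumerate(per, start=1):
        idx = rng.choice(4, size=n, p=p)
        sequences[f"chr{i}"] = "".join(_BASES[idx])
    return Genome(sequences=sequences)


def write_fasta(genome: Genome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_gene_models(
    genome: Genome,
    n_genes: int,
    mean_length: int = 2000,
    seed: int | None = None,
    packed_block: dict | None = None,
) -> list[GeneModel]:
    """Place non-overlapping protein-coding gene intervals.

    ``packed_block`` (keys: ``n_genes``, ``span``, optional ``chrom``
    and ``start``) adds a contiguous run of genes filling ``span`` bp,
    for multi-gene-deletion fixtures.  Raises when placement without
    overlap is impossible.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.sequences}

    def overlaps(chrom: str, start: int, end: int) -> bool:
        return any(start <= e and end >= s for s, e in used[chrom])

    if packed_block is not None:
        k = int(packed_block["n_genes"])
        span = int(packed_block["span"])
        chrom = packed_block.get("chrom") or next(iter(genome.sequences))
        chrom_len = len(genome.sequences[chrom])
        start = int(packed_block.get("start") or 1 + (chrom_len - span) // 2)
        if k < 1 or span < 2 * k or start + span - 1 > chrom_len:
            raise DataError("packed block does not fit the genome")
        width = span // k
        for i in range(k):
            g_start = start + i * width
            g_end = g_start + width - 2  # 1 bp gap between neighbors
            genes.append(
                GeneModel(
                    gene_id=f"packed_g{i + 1:03d}",
                    chrom=chrom,
                    start=g_start,
                    end=min(g_end, start + span - 1),
                )
            )
        used[chrom].append((start, start + span - 1))

    chroms = list(genome.sequences)
    lengths = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    for i in range(n_genes):
        length = int(rng.integers(max(2, mean_length // 2), mean_length * 3 // 2 + 1))
        placed = False
        for _ in range(500):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            chrom_len = len(genome.sequences[chrom])
            if chrom_len <= length + 2:
                continue
            start = int(rng.integers(1, chrom_len - length))
            end = start + length - 1
            if not overlaps(chrom, start, end):
                used[chrom].append((start, end))
                genes.append(
                    GeneModel(
                        gene_id=f"g{i + 1:05d}",
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand="+" if rng.random() < 0.5 else "-",
                    )
                )
                placed = True
                break
        if not placed:
            raise DataError(
                f"cannot place gene {i + 1}/{n_genes} without overlap"
            )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff3(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tradmut\tgene\t{g.start}\t{g.end}\t.\t{g.strand}"
                f"\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )


_CATEGORY_ORDER = [
    Category.SBS,
    Category.INS1,
    Category.DEL1,
    Category.INS2_99,
    Category.DEL2_99,
    Category.DEL_GE100,
    Category.SV,
    Category.COMPLEX,
]

from .mutation_stats import SPECTRUM_CLASSES  # noqa: E402


@dataclass(frozen=True)
class TreatmentProfile:
    """Generation parameters for one material-radiation combination."""

    label: str
    events_per_plant: float
    category_mix: dict[Category, float]
    sbs_class_mix: dict[str, float]
    hom_probability: float = 1.0 / 3.0
    del_small_range: tuple[int, int] = (2, 99)
    del_large_range: tuple[int, int] = (100, 400_000)
    ins_small_range: tuple[int, int] = (2, 99)
    inversion_span_range: tuple[int, int] = (1_000, 50_000)
    translocation_probability: float = 0.5

    def __post_init__(self) -> None:
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ConfigError(f"{self.label}: category_mix must sum to 1")
        if abs(sum(self.sbs_class_mix.values()) - 1.0) > 1e-9:
            raise ConfigError(f"{self.label}: sbs_class_mix must sum to 1")
        if any(v < 0 for v in self.category_mix.values()) or any(
            v < 0 for v in self.sbs_class_mix.values()
        ):
            raise ConfigError(f"{self.label}: probabilities must be >= 0")
        if not 0 <= self.hom_probability <= 1:
            raise ConfigError(f"{self.label}: hom_probability outside [0,1]")
        if self.events_per_plant < 0:
            raise ConfigError(f"{self.label}: events_per_plant must be >= 0")

    @property
    def rearrangement_rate(self) -> float:
        return self.category_mix[Category.SV] + self.category_mix[Category.DEL_GE100]


def _mix(values: list[float]) -> dict[Category, float]:
    return dict(zip(_CATEGORY_ORDER, values))


def _smix(values: list[float]) -> dict[str, float]:
    return dict(zip(SPECTRUM_CLASSES, values))


def default_profiles(
    events_per_plant: float = 25.0,
    del_large_max: int = 400_000,
) -> dict[str, TreatmentProfile]:
    """Illustrative profiles for the four material-radiation combinations."""

    def prof(label, cats, sbs):
        return TreatmentProfile(
            label=label,
            events_per_plant=events_per_plant,
            category_mix=_mix(cats),
            sbs_class_mix=_smix(sbs),
            del_large_range=(100, del_large_max),
        )

    return {
        "gamma_dry": prof(
            "gamma_dry",
            [0.55, 0.05, 0.12, 0.03, 0.08, 0.04, 0.05, 0.08],
            [0.25, 0.15, 0.12, 0.10, 0.28, 0.10],
        ),
        "gamma_seedling": prof(
            "gamma_seedling",
            [0.58, 0.05, 0.10, 0.03, 0.09, 0.03, 0.04, 0.08],
            [0.28, 0.20, 0.16, 0.14, 0.10, 0.12],
        ),
        "carbon_dry": prof(
            "carbon_dry",
            [0.38, 0.04, 0.08, 0.03, 0.22, 0.09, 0.08, 0.08],
            [0.22, 0.15, 0.12, 0.10, 0.31, 0.10],
        ),
        "carbon_seedling": prof(
            "carbon_seedling",
            [0.45, 0.04, 0.07, 0.03, 0.15, 0.08, 0.08, 0.10],
            [0.30, 0.18, 0.15, 0.12, 0.12, 0.13],
        ),
    }


@dataclass
class SyntheticTruth:
    """Ground-truth event sets plus the parameters that generated them."""

    profile: TreatmentProfile
    seed: int
    plants: dict[str, list[MutationEvent]]

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.plants.values())

    def events(self):
        for evs in self.plants.values():
            yield from evs

    def to_catalog(self) -> TreatmentCatalog:
        return TreatmentCatalog(
            label=self.profile.label,
            plants={p: list(evs) for p, evs in self.plants.items()},
        )


def _log_uniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    if hi <= lo:
        return lo
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi + 1))))


class _Placer:
    """Rejection-samples event spans keeping a minimum spacing."""

    def __init__(self, genome: Genome, rng: np.random.Generator, min_spacing: int):
        self.genome = genome
        self.rng = rng
        self.min_spacing = min_spacing
        self.chroms = list(genome.sequences)
        lengths = np.array(
            [len(genome.sequences[c]) for c in self.chroms], dtype=float
        )
        self.weights = lengths / lengths.sum()
        self.used: dict[str, list[tuple[int, int]]] = {c: [] for c in self.chroms}

    def _free(self, chrom: str, start: int, end: int) -> bool:
        pad = self.min_spacing
        return not any(
            start - pad <= e and end + pad >= s for s, e in self.used[chrom]
        )

    def place(
        self, span: int, base_filter=None, chrom: str | None = None
    ) -> tuple[str, int] | None:
        for _ in range(300):
            c = (
                chrom
                or self.chroms[self.rng.choice(len(self.chroms), p=self.weights)]
            )
            chrom_len = len(self.genome.sequences[c])
            if chrom_len < span + 4:
                continue
            start = int(self.rng.integers(2, chrom_len - span - 1))
            if not self._free(c, start, start + span - 1):
                continue
            if base_filter is not None and not base_filter(c, start):
                continue
            self.used[c].append((start, start + span - 1))
            return c, start
        return None


_SBS_ALT = {}
for cls in SPECTRUM_CLASSES:
    orig, dest = cls.split(">")
    _SBS_ALT[(cls, orig[0])] = dest[0]
    _SBS_ALT[(cls, orig[1])] = dest[1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def simulate_catalog(
    profile: TreatmentProfile,
    n_plants: int,
    genome: Genome,
    seed: int | None = None,
    min_spacing: int = 25,
) -> SyntheticTruth:
    """Draw a ground-truth catalog: Poisson event counts per plant,
    categories/classes/sizes per the profile, 1:2 hom:het zygosity by
    default, and complex events built as sub-10-bp-gap clusters."""
    rng = np.random.default_rng(seed)
    cat_probs = np.array([profile.category_mix[c] for c in _CATEGORY_ORDER])
    sbs_probs = np.array([profile.sbs_class_mix[c] for c in SPECTRUM_CLASSES])
    plants: dict[str, list[MutationEvent]] = {}
    for p in range(n_plants):
        plant_id = f"{profile.label}_P{p + 1:02d}"
        placer = _Placer(genome, rng, min_spacing)
        n_events = rng.poisson(profile.events_per_plant)
        events: list[MutationEvent] = []
        for k in range(n_events):
            category = _CATEGORY_ORDER[rng.choice(8, p=cat_probs)]
            zyg = Zygosity.HOM if rng.random() < profile.hom_probability else Zygosity.HET
            eid = f"{plant_id}_E{k + 1:03d}"
            ev = _make_event(
                category, profile, genome, placer, rng, sbs_probs, plant_id, zyg, eid
            )
            if ev is not None:
                events.append(ev)
        events.sort(key=lambda e: (e.chrom, e.start))
        plants[plant_id] = events
    return SyntheticTruth(profile=profile, seed=seed or 0, plants=plants)


def _make_event(
    category: Category,
    profile: TreatmentProfile,
    genome: Genome,
    placer: _Placer,
    rng: np.random.Generator,
    sbs_probs: np.ndarray,
    plant_id: str,
    zyg: Zygosity,
    eid: str,
) -> MutationEvent | None:
    if category is Category.SBS:
        cls = SPECTRUM_CLASSES[rng.choice(6, p=sbs_probs)]
        wanted = set(cls.split(">")[0])

        def base_ok(c, s):
            return genome.sequences[c][s - 1] in wanted

        spot = placer.place(1, base_filter=base_ok)
        if spot is None:
            return None
        chrom, pos = spot
        ref = genome.sequences[chrom][pos - 1]
        alt = _SBS_ALT[(cls, ref)]
        return MutationEvent(
            sample_id=plant_id, chrom=chrom, start=pos, end=pos,
            category=Category.SBS, net_length=0, zygosity=zyg,
            ref_allele=ref, alt_allele=alt, event_id=eid,
        )
    if category in (Category.INS1, Category.INS2_99):
        n = 1 if category is Category.INS1 else _log_uniform_int(
            rng, *profile.ins_small_range
        )
        spot = placer.place(1)
        if spot is None:
            return None
        chrom, pos = spot
        return MutationEvent(
            sample_id=plant_id, chrom=chrom, start=pos, end=pos,
            category=category, net_length=n, zygosity=zyg,
            alt_allele=_random_seq(rng, n), event_id=eid,
        )
    if category in (Category.DEL1, Category.DEL2_99, Category.DEL_GE100):
        if category is Category.DEL1:
            n = 1
        elif category is Category.DEL2_99:
            n = _log_uniform_int(rng, *profile.del_small_range)
        else:
            lo, hi = profile.del_large_range
            max_fit = max(lo, min(hi, min(len(s) for s in genome.sequences.values()) // 4))
            n = _log_uniform_int(rng, lo, max_fit)
        spot = placer.place(n)
        if spot is None:
            return None
        chrom, start = spot
        ref = genome.fetch(chrom, start, start + n - 1) if n <= 99 else ""
        return MutationEvent(
            sample_id=plant_id, chrom=chrom, start=start, end=start + n - 1,
            category=category, net_length=-n, zygosity=zyg,
            ref_allele=ref, event_id=eid,
        )
    if category is Category.SV:
        n_chroms = len(genome.sequences)
        translocate = n_chroms >= 2 and rng.random() < profile.translocation_probability
        if translocate:
            spot1 = placer.place(1)
            if spot1 is None:
                return None
            c1, p1 = spot1
            spot2 = None
            for _ in range(50):
                cand = placer.place(1)
                if cand is not None and cand[0] != c1:
                    spot2 = cand
                    break
            if spot2 is None:
                return None
            (ca, pa), (cb, pb) = sorted([(c1, p1), spot2])
            return MutationEvent(
                sample_id=plant_id, chrom=ca, start=pa, end=pa,
                category=Category.SV, net_length=0, zygosity=zyg,
                sv_kind=SvKind.TRANSLOCATION, mate_chrom=cb, mate_pos=pb,
                event_id=eid,
            )
        lo, hi = profile.inversion_span_range
        max_fit = max(lo, min(hi, min(len(s) for s in genome.sequences.values()) // 4))
        span = _log_uniform_int(rng, lo, max_fit)
        spot = placer.place(span)
        if spot is None:
            return None
        chrom, start = spot
        return MutationEvent(
            sample_id=plant_id, chrom=chrom, start=start, end=start + span - 1,
            category=Category.SV, net_length=0, zygosity=zyg,
            sv_kind=SvKind.INVERSION, event_id=eid,
        )
    # Complex: a cluster of 2-3 primitives, gaps of 2-8 reference bases.
    n_prims = int(rng.integers(2, 4))
    max_span = 60
    spot = placer.place(max_span)
    if spot is None:
        return None
    chrom, cursor = spot
    seq = genome.sequences[chrom]
    comps: list[Primitive] = []
    for _ in range(n_prims):
        kind = rng.random()
        if kind < 0.6:  # SBS component
            ref = seq[cursor - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            comps.append(
                Primitive(chrom=chrom, start=cursor, end=cursor,
                          deleted_bp=1, inserted_bp=1, ref=ref, alt=alt)
            )
            last_end = cursor
        elif kind < 0.8:  # short deletion (1-5 bp)
            n = int(rng.integers(1, 6))
            comps.append(
                Primitive(chrom=chrom, start=cursor, end=cursor + n - 1,
                          deleted_bp=n, inserted_bp=0,
                          ref=seq[cursor - 1 : cursor + n - 1], alt="")
            )
            last_end = cursor + n - 1
        else:  # short insertion (1-5 bp)
            n = int(rng.integers(1, 6))
            comps.append(
                Primitive(chrom=chrom, start=cursor, end=cursor,
                          deleted_bp=0, inserted_bp=n,
                          ref="", alt=_random_seq(rng, n))
            )
            last_end = cursor
        cursor = last_end + 1 + int(rng.integers(2, 9))  # gap in [2, 8]
    return MutationEvent(
        sample_id=plant_id,
        chrom=chrom,
        start=comps[0].start,
        end=max(c.end for c in comps),
        category=Category.COMPLEX,
        net_length=sum(c.net_length for c in comps),
        zygosity=zyg,
        components=tuple(comps),
        event_id=eid,
    )


#: Which categories each caller role can detect.
CALLER_VISIBILITY: dict[Caller, frozenset[Category]] = {
    Caller.SNV_INDEL: frozenset(
        {Category.SBS, Category.INS1, Category.DEL1, Category.INS2_99,
         Category.DEL2_99, Category.COMPLEX}
    ),
    Caller.SR: frozenset({Category.DEL_GE100, Category.SV}),
    Caller.RP: frozenset({Category.DEL_GE100, Category.SV}),
    Caller.COMBINED_A: frozenset({Category.DEL_GE100, Category.SV}),
    Caller.COMBINED_B: frozenset({Category.DEL_GE100, Category.SV}),
}


@dataclass(frozen=True)
class NoiseModel:
    """Read-sampling and detection noise for caller emission.

    Defaults are noise-free: exact allele fractions (1.0 hom / 0.5
    het), no shared false positives, unit sensitivity everywhere.
    ``sensitivity`` maps caller -> category -> detection probability and
    overrides the unit default per entry.
    """

    depth: int = 40
    af_binomial: bool = False
    fp_shared_rate: float = 0.0
    sensitivity: dict = field(default_factory=dict)

    def detect_p(self, caller: Caller, category: Category) -> float:
        return float(self.sensitivity.get(caller, {}).get(category, 1.0))


@dataclass
class EmissionResult:
    vcf_paths: dict[tuple[str, Caller], str]
    fp_sites: list[dict]
    n_emitted: int


def _vcf_header(genome: Genome, sample_id: str) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for name, seq in genome.sequences.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines += [
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="SV length">',
        '##INFO=<ID=MATEID,Number=.,Type=String,Description="Breakend mate">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id,
    ]
    return "\n".join(lines) + "\n"


def _fmt(gt: str, alt_reads: int, depth: int) -> str:
    return f"{gt}:{depth - alt_reads},{alt_reads}:{depth}"


def _sample_af(
    rng: np.random.Generator, zyg: Zygosity, noise: NoiseModel
) -> tuple[int, int]:
    p = 1.0 if zyg is Zygosity.HOM else 0.5
    depth = noise.depth
    if noise.af_binomial:
        alt = int(rng.binomial(depth, p))
    else:
        alt = int(round(depth * p))
    return alt, depth


def _event_vcf_lines(
    ev: MutationEvent,
    genome: Genome,
    rng: np.random.Generator,
    noise: NoiseModel,
) -> list[str]:
    alt_reads, depth = _sample_af(rng, ev.zygosity, noise)
    if alt_reads == 0:
        return []
    gt = "1/1" if ev.zygosity is Zygosity.HOM else "0/1"
    fmt = _fmt(gt, alt_reads, depth)
    seq = genome.sequences[ev.chrom]

    def line(chrom, pos, vid, ref, alt, info="."):
        return f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT:AD:DP\t{fmt}"

    if ev.category is Category.SBS:
        return [line(ev.chrom, ev.start, ev.event_id, ev.ref_allele, ev.alt_allele)]
    if ev.category in (Category.INS1, Category.INS2_99):
        anchor = seq[ev.start - 1]
        return [line(ev.chrom, ev.start, ev.event_id, anchor, anchor + ev.alt_allele)]
    if ev.category in (Category.DEL1, Category.DEL2_99):
        pos = ev.start - 1
        ref = seq[pos - 1 : ev.end]
        return [line(ev.chrom, pos, ev.event_id, ref, ref[0])]
    if ev.category is Category.DEL_GE100:
        pos = ev.start - 1
        size = ev.end - ev.start + 1
        info = f"END={ev.end};SVTYPE=DEL;SVLEN=-{size}"
        return [line(ev.chrom, pos, ev.event_id, seq[pos - 1], "<DEL>", info)]
    if ev.category is Category.SV:
        if ev.sv_kind is SvKind.INVERSION:
            info = f"END={ev.end};SVTYPE=INV"
            return [line(ev.chrom, ev.start, ev.event_id, seq[ev.start - 1], "<INV>", info)]
        a_id, b_id = f"{ev.event_id}_bnd1", f"{ev.event_id}_bnd2"
        ref_a = seq[ev.start - 1]
        ref_b = genome.sequences[ev.mate_chrom][ev.mate_pos - 1]
        return [
            line(ev.chrom, ev.start, a_id, ref_a,
                 f"{ref_a}[{ev.mate_chrom}:{ev.mate_pos}[",
                 f"SVTYPE=BND;MATEID={b_id}"),
            line(ev.mate_chrom, ev.mate_pos, b_id, ref_b,
                 f"]{ev.chrom}:{ev.start}]{ref_b}",
                 f"SVTYPE=BND;MATEID={a_id}"),
        ]
    if ev.category is Category.COMPLEX:
        lines = []
        for i, c in enumerate(ev.components):
            vid = f"{ev.event_id}_c{i + 1}"
            if c.is_substitution:
                lines.append(line(c.chrom, c.start, vid, c.ref, c.alt))
            elif c.net_length > 0:  # insertion
                anchor = seq[c.start - 1]
                lines.append(line(c.chrom, c.start, vid, anchor, anchor + c.alt))
            else:  # deletion
                pos = c.start - 1
                ref = seq[pos - 1 : c.end]
                lines.append(line(c.chrom, pos, vid, ref, ref[0]))
        return lines
    raise DataError(f"cannot emit category {ev.category}")


def emit_caller_outputs(
    truth: SyntheticTruth,
    genome: Genome,
    outdir: str,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    panel: list[Caller] | None = None,
) -> EmissionResult:
    """Write per-sample, per-caller VCFs for a truth catalog.

    Every emitted record's ID traces to a truth event id; injected
    shared false positives carry ``FP``-prefixed ids and are listed in
    the returned ``fp_sites``.
    """
    noise = noise or NoiseModel()
    panel = panel or list(Caller)
    rng = np.random.default_rng(seed)
    os.makedirs(outdir, exist_ok=True)
    samples = list(truth.plants)

    # Shared false positives: identical SNV site in >= 2 samples.
    fp_sites: list[dict] = []
    fp_lines: dict[str, list[str]] = {s: [] for s in samples}
    if noise.fp_shared_rate > 0 and len(samples) >= 2:
        n_fp = int(rng.poisson(noise.fp_shared_rate))
        chroms = list(genome.sequences)
        for i in range(n_fp):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(2, len(genome.sequences[chrom]) - 1))
            ref = genome.sequences[chrom][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            k = int(rng.integers(2, min(3, len(samples)) + 1))
            chosen = list(rng.choice(samples, size=k, replace=False))
            depth = noise.depth
            for s in chosen:
                alt_reads = int(rng.integers(int(0.3 * depth), int(0.7 * depth) + 1))
                fp_lines[s].append(
                    f"{chrom}\t{pos}\tFP{i + 1}\t{ref}\t{alt}\t.\tPASS\t.\t"
                    f"GT:AD:DP\t0/1:{depth - alt_reads},{alt_reads}:{depth}"
                )
            fp_sites.append({"chrom": chrom, "pos": pos, "samples": sorted(chosen)})

    paths: dict[tuple[str, Caller], str] = {}
    n_emitted = 0
    for sample in samples:
        events = truth.plants[sample]
        for caller in panel:
            lines: list[str] = []
            for ev in events:
                if ev.category not in CALLER_VISIBILITY[caller]:
                    continue
                if rng.random() >= noise.detect_p(caller, ev.category):
                    continue
                lines.extend(_event_vcf_lines(ev, genome, rng, noise))
            if caller is Caller.SNV_INDEL:
                lines.extend(fp_lines[sample])
            # VCF requires positional sorting per chromosome.
            parsed = [l.split("\t") for l in lines]
            parsed.sort(key=lambda f: (f[0], int(f[1])))
            path = os.path.join(outdir, f"{sample}.{caller.value}.vcf")
            with open(path, "w") as fh:
                fh.write(_vcf_header(genome, sample))
                for f in parsed:
                    fh.write("\t".join(f) + "\n")
            paths[(sample, caller)] = path
            n_emitted += len(parsed)
    return EmissionResult(vcf_paths=paths, fp_sites=fp_sites, n_emitted=n_emitted)


def simulate_survival(
    curve: SurvivalCurve,
    doses: list[float],
    n_per_replicate: int = 30,
    replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binomial survival assay: survivors ~ Binom(n, survival(D))."""
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        p = survival(float(dose), curve)
        for rep in range(1, replicates + 1):
            rows.append(
                {
                    "dose": float(dose),
                    "survivors": int(rng.binomial(n_per_replicate, p)),
                    "total": n_per_replicate,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)
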