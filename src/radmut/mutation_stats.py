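"""Summary statistics and hypothesis tests over classified catalogs.

Covers per-genome mutation frequency, the six-class merged-complement
SBS spectrum (Ti/Tv and G:C/A:T with an exact binomial test against
genome base composition), rearrangement bookkeeping per plant, the
M2 zygosity-ratio test (expected 1 hom : 2 het among carriers), caller
augmentation accounting, and group comparisons (pairwise Fisher exact
tests or one-way ANOVA + Tukey HSD) with Holm correction and compact
letter displays.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from ._report import report_percent, report_round
from .errors import ConfigError, DataError
from .records import Category, Genome, MutationEvent, TreatmentCatalog

__all__ = [
    "SPECTRUM_CLASSES",
    "SpectrumSummary",
    "GroupComparison",
    "PairResult",
    "mutation_frequency",
    "sbs_spectrum",
    "expected_gc_at_ratio",
    "rearrangement_summary",
    "proportion_test",
    "zygosity_ratio_test",
    "ZygosityRatioResult",
    "augmentation_report",
    "AugmentationReport",
    "anova_with_cld",
    "compact_letters",
]

#: Merged-complement substitution classes, keyed by original base pair.
SPECTRUM_CLASSES = (
    "GC>AT",
    "AT>GC",
    "GC>TA",
    "GC>CG",
    "AT>TA",
    "AT>CG",
)

_CLASS_BY_SUB = {
    ("G", "A"): "GC>AT",
    ("C", "T"): "GC>AT",
    ("A", "G"): "AT>GC",
    ("T", "C"): "AT>GC",
    ("G", "T"): "GC>TA",
    ("C", "A"): "GC>TA",
    ("G", "C"): "GC>CG",
    ("C", "G"): "GC>CG",
    ("A", "T"): "AT>TA",
    ("T", "A"): "AT>TA",
    ("A", "C"): "AT>CG",
    ("T", "G"): "AT>CG",
}

_TRANSITION_CLASSES = frozenset({"GC>AT", "AT>GC"})
_GC_ORIGIN_CLASSES = frozenset({"GC>AT", "GC>TA", "GC>CG"})


def mutation_frequency(n_events: int, genome_length: float) -> float:
    """Mutation events per reference base pair."""
    if genome_length <= 0:
        raise DataError(f"genome_length must be > 0, got {genome_length}")
    if n_events < 0:
        raise DataError("n_events must be >= 0")
    return n_events / genome_length


@dataclass
class SpectrumSummary:
    """Six-class SBS spectrum with Ti/Tv and G:C/A:T summaries.

    ``ti_tv`` / ``gc_at`` are ``None`` (flagged undefined) when their
    denominators are zero rather than infinity.
    """

    counts: dict[str, int]
    ti_tv: float | None
    gc_at: float | None
    gc_at_p: float

    @property
    def n_sbs(self) -> int:
        return sum(self.counts.values())


def _sub_pair(event) -> tuple[str, str]:
    if isinstance(event, MutationEvent):
        ref, alt = event.ref_allele, event.alt_allele
    else:
        ref, alt = event
    ref, alt = ref.upper(), alt.upper()
    if (ref, alt) not in _CLASS_BY_SUB:
        raise DataError(f"not a single-base substitution: {ref}>{alt}")
    return ref, alt


def sbs_spectrum(sbs_events: Iterable, genome: Genome | float) -> SpectrumSummary:
    """Spectrum of single-base substitutions.

    ``sbs_events`` are :class:`MutationEvent` objects carrying ref/alt
    bases, or plain ``(ref, alt)`` pairs.  ``genome`` (or a bare GC
    fraction) provides the null success probability for the exact
    binomial test of the G:C-original count against composition.
    """
    gc_content = genome.gc_content if isinstance(genome, Genome) else float(genome)
    if not 0 < gc_content < 1:
        raise DataError(f"gc_content must be in (0,1), got {gc_content}")
    counts = {cls: 0 for cls in SPECTRUM_CLASSES}
    for ev in sbs_events:
        counts[_CLASS_BY_SUB[_sub_pair(ev)]] += 1
    n = sum(counts.values())
    ti = sum(counts[c] for c in _TRANSITION_CLASSES)
    tv = n - ti
    gc_orig = sum(counts[c] for c in _GC_ORIGIN_CLASSES)
    at_orig = n - gc_orig
    ti_tv = ti / tv if tv > 0 else None
    gc_at = gc_orig / at_orig if at_orig > 0 else None
    gc_at_p = (
        sps.binomtest(gc_orig, n, gc_content).pvalue if n > 0 else 1.0
    )
    return SpectrumSummary(counts=counts, ti_tv=ti_tv, gc_at=gc_at, gc_at_p=gc_at_p)


def expected_gc_at_ratio(gc_content: float) -> float:
    """Null G:C/A:T ratio implied by genome composition: GC/(1-GC)."""
    if not 0 < gc_content < 1:
        raise DataError(f"gc_content must be in (0,1), got {gc_content}")
    return gc_content / (1.0 - gc_content)


def rearrangement_summary(catalog: TreatmentCatalog) -> dict:
    """Per-plant rearrangement bookkeeping for one treatment group.

    Returns the share of plants carrying at least one rearrangement
    (whole percent) and the mean number of rearrangement events per
    plant (one decimal), plus the raw counts.
    """
    if catalog.n_plants == 0:
        raise DataError("rearrangement_summary requires at least one plant")
    n_plants = catalog.n_plants
    per_plant = [
        sum(1 for ev in events if ev.is_rearrangement)
        for events in catalog.plants.values()
    ]
    n_with = sum(1 for k in per_plant if k > 0)
    total = sum(per_plant)
    return {
        "n_plants": n_plants,
        "n_plants_with_rearrangement": n_with,
        "n_rearrangements": total,
        "percent_plants_with_rearrangement": report_percent(n_with / n_plants),
        "mean_events_per_plant": report_round(total / n_plants, 1),
    }


@dataclass(frozen=True)
class PairResult:
    group_a: str
    group_b: str
    p_value: float
    adjusted_p: float
    significant: bool


@dataclass
class GroupComparison:
    """Pairwise group comparison with a compact letter display."""

    groups: list[str]
    statistic: dict[str, float]
    pairwise: list[PairResult]
    letters: dict[str, str]
    alpha: float
    warnings: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return sum(1 for p in self.pairwise if p.significant)


_ADJUST_METHODS = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh"}


def _adjust(pvalues: Sequence[float], method: str) -> np.ndarray:
    if method not in _ADJUST_METHODS:
        raise ConfigError(
            f"unknown correction method {method!r}; choose from "
            f"{sorted(_ADJUST_METHODS)}"
        )
    if not pvalues:
        return np.array([])
    return multipletests(pvalues, method=_ADJUST_METHODS[method])[1]


def compact_letters(
    groups: Sequence[str], significant_pairs: Iterable[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; every
    significant pair ends up with disjoint letter sets.
    """
    sets: list[set[str]] = [set(groups)]
    for a, b in significant_pairs:
        nxt: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                nxt.append(s - {a})
                nxt.append(s - {b})
            else:
                nxt.append(s)
        # absorb: drop any set contained in another
        sets = [
            s
            for i, s in enumerate(nxt)
            if s
            and not any(
                (s < t) or (s == t and i > j)
                for j, t in enumerate(nxt)
                if j != i
            )
        ]
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in s:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def proportion_test(
    category_counts: Mapping[str, tuple[int, int]],
    alpha: float = 0.05,
    method: str = "holm",
) -> GroupComparison:
    """Pairwise 2x2 Fisher exact tests of a category share across groups.

    ``category_counts`` maps group label to (count in category of
    interest, total events).  Groups with zero total are excluded with a
    warning.  P-values are Holm-adjusted by default; letters follow the
    adjusted significance graph at ``alpha``.
    """
    warnings = []
    usable: dict[str, tuple[int, int]] = {}
    for g, (k, n) in category_counts.items():
        if n <= 0:
            warnings.append(f"group {g!r} excluded: zero total events")
        elif not 0 <= k <= n:
            raise DataError(f"group {g!r}: count {k} outside [0, {n}]")
        else:
            usable[g] = (k, n)
    if len(usable) < 2:
        raise DataError("proportion_test requires >= 2 groups with events")
    groups = list(usable)
    pairs = list(itertools.combinations(groups, 2))
    pvals = []
    for a, b in pairs:
        ka, na = usable[a]
        kb, nb = usable[b]
        table = [[ka, na - ka], [kb, nb - kb]]
        pvals.append(sps.fisher_exact(table).pvalue)
    adj = _adjust(pvals, method)
    pairwise = [
        PairResult(a, b, p, ap, ap < alpha)
        for (a, b), p, ap in zip(pairs, pvals, adj)
    ]
    letters = compact_letters(
        groups, [(r.group_a, r.group_b) for r in pairwise if r.significant]
    )
    return GroupComparison(
        groups=groups,
        statistic={g: usable[g][0] / usable[g][1] for g in groups},
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
        warnings=warnings,
    )


@dataclass
class ZygosityRatioResult:
    n_hom: int
    n_het: int
    ratio_het_per_hom: float | None
    p_vs_expected: float


def zygosity_ratio_test(
    n_hom: int, n_het: int, expected_hom_fraction: float = 1.0 / 3.0
) -> ZygosityRatioResult:
    """Het-per-hom ratio with an exact binomial test against 1 hom : 2 het.

    The ratio is reported to one decimal and flagged ``None`` when no
    homozygous events were observed.
    """
    if n_hom < 0 or n_het < 0:
        raise DataError("counts must be >= 0")
    n = n_hom + n_het
    if n == 0:
        raise DataError("zygosity_ratio_test requires at least one event")
    ratio = report_round(n_het / n_hom, 1) if n_hom > 0 else None
    p = sps.binomtest(n_hom, n, expected_hom_fraction).pvalue
    return ZygosityRatioResult(
        n_hom=n_hom, n_het=n_het, ratio_het_per_hom=ratio, p_vs_expected=p
    )


@dataclass
class AugmentationReport:
    n_base: int
    n_added: int
    percent_of_total: int
    sv_before: int
    sv_after: int
    sv_fold: float | None


def _count_sv(events: Iterable[MutationEvent]) -> int:
    return sum(1 for e in events if e.category is Category.SV)


def augmentation_report(
    base_catalog: Sequence[MutationEvent],
    added_events: Sequence[MutationEvent],
) -> AugmentationReport:
    """Account for events contributed by additional SV callers.

    ``percent_of_total`` is the added events' whole-percent share of the
    combined catalog; ``sv_fold`` is the SV-count fold change (one
    decimal, ``None`` when no SVs existed before but do after).
    """
    base_ids = {e.identity() for e in base_catalog}
    if any(e.identity() in base_ids for e in added_events):
        raise DataError("added_events overlap the base catalog")
    n_base, n_added = len(base_catalog), len(added_events)
    total = n_base + n_added
    if total == 0:
        raise DataError("augmentation_report requires a non-empty catalog")
    sv_before = _count_sv(base_catalog)
    sv_after = sv_before + _count_sv(added_events)
    if sv_before > 0:
        sv_fold: float | None = report_round(sv_after / sv_before, 1)
    elif sv_after == 0:
        sv_fold = 1.0
    else:
        sv_fold = None
    return AugmentationReport(
        n_base=n_base,
        n_added=n_added,
        percent_of_total=report_percent(n_added / total),
        sv_before=sv_before,
        sv_after=sv_after,
        sv_fold=sv_fold,
    )


def anova_with_cld(
    per_sample_values: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA with Tukey HSD post hoc and compact letters.

    Groups with fewer than two samples are excluded with a warning.
    When every value is identical the variance is degenerate: the F test
    is undefined and all groups share one letter.
    """
    warnings = []
    usable: dict[str, np.ndarray] = {}
    for g, vals in per_sample_values.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            warnings.append(f"group {g!r} excluded: fewer than 2 samples")
        else:
            usable[g] = arr
    if len(usable) < 2:
        raise DataError("anova_with_cld requires >= 2 groups with >= 2 samples")
    groups = list(usable)
    means = {g: float(np.mean(v)) for g, v in usable.items()}
    pooled = np.concatenate(list(usable.values()))
    if np.ptp(pooled) == 0.0:
        warnings.append("degenerate variance: all values identical")
        return GroupComparison(
            groups=groups,
            statistic=means,
            pairwise=[],
            letters={g: "a" for g in groups},
            alpha=alpha,
            warnings=warnings,
            extra={"anova_F": float("nan"), "anova_p": float("nan")},
        )
    f_stat, p = sps.f_oneway(*usable.values())
    labels = np.concatenate(
        [np.repeat(g, len(v)) for g, v in usable.items()]
    )
    tukey = pairwise_tukeyhsd(pooled, labels, alpha=alpha)
    tukey_groups = list(tukey.groupsunique)
    pairwise = []
    for (i, j), pv, rej in zip(
        itertools.combinations(range(len(tukey_groups)), 2),
        tukey.pvalues,
        tukey.reject,
    ):
        pairwise.append(
            PairResult(
                tukey_groups[i],
                tukey_groups[j],
                float(pv),
                float(pv),  # Tukey p-values are already family-wise
                bool(rej),
            )
        )
    letters = compact_letters(
        groups, [(r.group_a, r.group_b) for r in pairwise if r.significant]
    )
    return GroupComparison(
        groups=groups,
        statistic=means,
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
        warnings=warnings,
        extra={"anova_F": float(f_stat), "anova_p": float(p)},
    )
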