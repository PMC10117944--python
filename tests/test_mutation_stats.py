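import itertools

import numpy as np
import pytest
from scipy import stats as sps

from radmut._report import report_round
from radmut.errors import DataError
from radmut.mutation_stats import (
    SPECTRUM_CLASSES,
    anova_with_cld,
    augmentation_report,
    compact_letters,
    expected_gc_at_ratio,
    mutation_frequency,
    proportion_test,
    rearrangement_summary,
    sbs_spectrum,
    zygosity_ratio_test,
)
from radmut.records import Category, TreatmentCatalog, Zygosity

from conftest import mk_event

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


class TestMutationFrequency:
    def test_zero_events(self):
        assert mutation_frequency(0, 1.19e8) == 0.0

    def test_simple_arithmetic(self):
        assert mutation_frequency(119, 1.19e8) == pytest.approx(1.0e-6)

    def test_nonpositive_genome_errors(self):
        with pytest.raises(DataError):
            mutation_frequency(5, 0)

    def test_truth_catalog_exact(self, genome):
        from radmut.synthetic_data import default_profiles, simulate_catalog

        prof = default_profiles(events_per_plant=12, del_large_max=2000)["gamma_dry"]
        truth = simulate_catalog(prof, 3, genome, seed=2)
        for plant, evs in truth.plants.items():
            mf = mutation_frequency(len(evs), genome.total_length)
            assert mf == len(evs) / genome.total_length


class TestSbsSpectrum:
    def test_balanced_example(self):
        s = sbs_spectrum([("G", "A"), ("C", "T"), ("A", "C"), ("T", "G")], 0.36)
        assert s.ti_tv == pytest.approx(1.0)
        assert s.gc_at == pytest.approx(1.0)
        assert s.n_sbs == 4

    def test_complement_relabel_invariance(self):
        rng = np.random.default_rng(3)
        subs = [
            (r, a)
            for r in "ACGT"
            for a in "ACGT"
            if r != a
            for _ in range(int(rng.integers(1, 20)))
        ]
        flipped = [(_COMPLEMENT[r], _COMPLEMENT[a]) for r, a in subs]
        assert sbs_spectrum(subs, 0.36).counts == sbs_spectrum(flipped, 0.36).counts

    def test_counts_sum_to_n(self):
        subs = [("G", "A")] * 7 + [("A", "T")] * 3
        s = sbs_spectrum(subs, 0.36)
        assert sum(s.counts.values()) == 10

    def test_zero_transversions_flagged(self):
        s = sbs_spectrum([("G", "A"), ("A", "G")], 0.36)
        assert s.ti_tv is None

    def test_zero_at_originals_flagged(self):
        s = sbs_spectrum([("G", "A"), ("C", "G")], 0.36)
        assert s.gc_at is None

    def test_expected_ratio_constant(self):
        assert report_round(expected_gc_at_ratio(0.36), 2) == 0.56

    def test_null_simulation_gc_at(self):
        # 10,000 substitutions with originals drawn at genome composition
        rng = np.random.default_rng(7)
        subs = []
        for _ in range(10_000):
            ref = rng.choice(list("ACGT"), p=[0.32, 0.18, 0.18, 0.32])
            alt = rng.choice([b for b in "ACGT" if b != ref])
            subs.append((str(ref), str(alt)))
        s = sbs_spectrum(subs, 0.36)
        gc_orig = sum(s.counts[c] for c in ("GC>AT", "GC>TA", "GC>CG"))
        # within exact binomial CI of composition
        ci = sps.binomtest(gc_orig, 10_000, 0.36).proportion_ci(0.999)
        assert ci.low <= 0.36 <= ci.high
        assert s.gc_at_p > 1e-4

    def test_rejects_non_sbs(self):
        with pytest.raises(DataError):
            sbs_spectrum([("A", "A")], 0.36)


def catalog_with(n_plants, plants_with_events):
    """plants_with_events: {plant_index: n_rearrangements}."""
    cat = TreatmentCatalog(label="t")
    for i in range(n_plants):
        events = []
        for k in range(plants_with_events.get(i, 0)):
            events.append(
                mk_event(
                    sample=f"P{i}",
                    category=Category.SV,
                    start=1000 * (k + 1),
                    end=1000 * (k + 1) + 10,
                )
            )
        cat.plants[f"P{i}"] = events
    return cat


class TestRearrangementSummary:
    def test_table_style_percent(self):
        cat = catalog_with(12, {i: 1 for i in range(10)})
        out = rearrangement_summary(cat)
        assert out["percent_plants_with_rearrangement"] == 83

    def test_table_style_mean(self):
        spread = {i: 1 for i in range(10)}
        spread[0] = 5
        spread[1] = 5
        cat = catalog_with(12, spread)  # 18 events... adjust to 19
        cat.plants["P2"].append(
            mk_event(sample="P2", category=Category.DEL_GE100,
                     net_length=-150, start=50_000)
        )
        out = rearrangement_summary(cat)
        assert out["n_rearrangements"] == 19
        assert out["mean_events_per_plant"] == 1.6

    def test_all_empty(self):
        out = rearrangement_summary(catalog_with(5, {}))
        assert out["percent_plants_with_rearrangement"] == 0
        assert out["mean_events_per_plant"] == 0.0

    def test_zero_plants_errors(self):
        with pytest.raises(DataError):
            rearrangement_summary(TreatmentCatalog(label="x"))

    def test_order_invariance(self):
        cat = catalog_with(4, {0: 3, 2: 1})
        out1 = rearrangement_summary(cat)
        for p in cat.plants.values():
            p.reverse()
        assert rearrangement_summary(cat) == out1


class TestProportionTest:
    def test_identical_groups_share_letter(self):
        out = proportion_test({"a": (10, 100), "b": (10, 100), "c": (10, 100)})
        assert all(p.adjusted_p == 1.0 for p in out.pairwise)
        assert set(out.letters.values()) == {"a"}

    def test_strong_difference_distinct_letters(self):
        out = proportion_test({"g1": (50, 100), "g2": (5, 100)})
        assert out.pairwise[0].adjusted_p < 0.05
        assert out.letters["g1"] != out.letters["g2"]
        assert not (set(out.letters["g1"]) & set(out.letters["g2"]))

    def test_single_differing_pair_two_letters(self):
        out = proportion_test({"A": (30, 40), "B": (10, 40), "C": (20, 40)})
        sig = {(p.group_a, p.group_b) for p in out.pairwise if p.significant}
        assert sig == {("A", "B")}
        used = set("".join(out.letters.values()))
        assert len(used) == 2
        # brute-force consistency: significant pairs disjoint, others share
        for p in out.pairwise:
            shared = set(out.letters[p.group_a]) & set(out.letters[p.group_b])
            assert bool(shared) == (not p.significant)

    def test_zero_total_group_excluded(self):
        out = proportion_test({"a": (5, 50), "b": (25, 50), "c": (0, 0)})
        assert "c" not in out.groups
        assert out.warnings

    def test_holm_never_beats_raw_fisher(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            counts = {
                f"g{i}": (int(rng.integers(0, 30)), 40) for i in range(4)
            }
            out = proportion_test(counts)
            raw_sig = sum(1 for p in out.pairwise if p.p_value < out.alpha)
            assert out.n_significant <= raw_sig


class TestCompactLetters:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_graph_consistency(self, seed):
        rng = np.random.default_rng(seed)
        groups = [f"g{i}" for i in range(5)]
        sig = [
            pair
            for pair in itertools.combinations(groups, 2)
            if rng.random() < 0.4
        ]
        letters = compact_letters(groups, sig)
        sig_set = {frozenset(p) for p in sig}
        for a, b in itertools.combinations(groups, 2):
            shared = set(letters[a]) & set(letters[b])
            if frozenset((a, b)) in sig_set:
                assert not shared, (a, b, letters)
            else:
                assert shared, (a, b, letters)


class TestZygosityRatio:
    def test_post_augmentation_ratio(self):
        out = zygosity_ratio_test(16, 34)
        assert out.ratio_het_per_hom == 2.1

    def test_pre_augmentation_ratio(self):
        assert zygosity_ratio_test(12, 18).ratio_het_per_hom == 1.5

    def test_most_probable_outcome_p_is_one(self):
        assert zygosity_ratio_test(10, 20).p_vs_expected == pytest.approx(1.0)

    def test_zero_hom_flagged(self):
        assert zygosity_ratio_test(0, 10).ratio_het_per_hom is None

    def test_both_zero_errors(self):
        with pytest.raises(DataError):
            zygosity_ratio_test(0, 0)


def _events(n, category=Category.SBS, prefix="b"):
    step = 200
    return [
        mk_event(
            sample=f"{prefix}{i % 7}",
            start=100 + step * i,
            end=100 + step * i + (1000 if category is Category.SV else 0),
            category=category,
        )
        for i in range(n)
    ]


class TestAugmentationReport:
    def test_percent_of_total(self):
        base = _events(2481) + _events(30, Category.SV)
        added = _events(25, Category.SV, prefix="n")
        out = augmentation_report(base, added)
        assert out.percent_of_total == 1
        assert out.n_base + out.n_added == 2536

    def test_sv_fold(self):
        base = _events(10) + _events(30, Category.SV)
        added = _events(20, Category.SV, prefix="n")
        out = augmentation_report(base, added)
        assert (out.sv_before, out.sv_after) == (30, 50)
        assert out.sv_fold == 1.7

    def test_nothing_added(self):
        out = augmentation_report(_events(10), [])
        assert out.percent_of_total == 0 and out.sv_fold == 1.0

    def test_fold_undefined_from_zero(self):
        out = augmentation_report(_events(5), _events(3, Category.SV, prefix="n"))
        assert out.sv_fold is None

    def test_overlap_rejected(self):
        base = _events(5)
        with pytest.raises(DataError):
            augmentation_report(base, base[:1])


class TestAnovaWithCld:
    def test_far_apart_groups_distinct_letters(self):
        rng = np.random.default_rng(0)
        vals = {
            "lo": rng.normal(0, 1, 10),
            "hi": rng.normal(10, 1, 10),
        }
        out = anova_with_cld(vals)
        assert out.letters["lo"] != out.letters["hi"]
        assert out.extra["anova_p"] < 1e-6

    def test_identical_constants_degenerate(self):
        out = anova_with_cld({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert set(out.letters.values()) == {"a"}
        assert np.isnan(out.extra["anova_F"])
        assert any("degenerate" in w for w in out.warnings)

    def test_small_group_excluded(self):
        rng = np.random.default_rng(1)
        out = anova_with_cld(
            {"a": rng.normal(size=5), "b": rng.normal(size=5), "c": [1.0]}
        )
        assert "c" not in out.groups and out.warnings

    def test_null_rejection_rate(self):
        # all groups from one normal: family-wise rejections ~ alpha
        rng = np.random.default_rng(42)
        rejected = 0
        reps = 400
        for _ in range(reps):
            vals = {f"g{i}": rng.normal(size=8) for i in range(3)}
            out = anova_with_cld(vals)
            if len(set(out.letters.values())) > 1:
                rejected += 1
        assert 0.01 < rejected / reps < 0.10
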