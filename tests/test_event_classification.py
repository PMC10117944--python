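import numpy as np
import pytest

from radmut.errors import DataError, OrphanBreakendError, UnsupportedCategoryError
from radmut.event_classification import (
    ComplexitySubclass,
    categorize,
    complexity_subclass,
    group_rearrangements,
    merge_complex,
    net_indel_length,
    pair_breakends,
    split_substitution_block,
    trim_alleles,
)
from radmut.records import (
    Caller,
    Category,
    Primitive,
    SvCall,
    SvKind,
    VariantRecord,
    Zygosity,
)


def sbs(pos, ref="A", alt="T", chrom="chr1"):
    return Primitive(chrom, pos, pos, 1, 1, ref, alt)


def indel(pos, net, chrom="chr1"):
    if net < 0:
        return Primitive(chrom, pos, pos - net - 1, -net, 0)
    return Primitive(chrom, pos, pos, 0, net)


class TestNetIndelLength:
    def test_deletion_with_unknown_insertion(self):
        assert net_indel_length(10, 3) == -7

    def test_single_base_deletion(self):
        assert net_indel_length(1, 0) == -1

    def test_both_zero_errors(self):
        with pytest.raises(DataError):
            net_indel_length(0, 0)

    def test_large_net_insertion_has_no_category(self):
        net = net_indel_length(0, 150)
        assert net == 150
        with pytest.raises(UnsupportedCategoryError):
            categorize(indel(100, net))


class TestCategorize:
    @pytest.mark.parametrize(
        "net,category",
        [
            (-150, Category.DEL_GE100),
            (-100, Category.DEL_GE100),
            (-99, Category.DEL2_99),
            (-2, Category.DEL2_99),
            (-1, Category.DEL1),
            (1, Category.INS1),
            (5, Category.INS2_99),
            (99, Category.INS2_99),
        ],
    )
    def test_net_length_rules(self, net, category):
        assert categorize(indel(500, net)) is category

    def test_sbs(self):
        assert categorize(sbs(10)) is Category.SBS

    def test_inversion_is_sv(self):
        assert categorize(SvCall(SvKind.INVERSION, "chr1", 10, 500)) is Category.SV

    def test_exactly_one_category(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            net = int(rng.integers(-300, 100))
            prim = sbs(50) if net == 0 else indel(50, net)
            assert categorize(prim) in Category


class TestTrimAndSplit:
    def test_block_with_internal_reference_run(self):
        # matches at offsets 1-3 (run of 3 >= 2): two SBS primitives
        prims = split_substitution_block("chr1", 100, "ACGTA", "TCGTC")
        assert [(p.start, p.ref, p.alt) for p in prims] == [
            (100, "A", "T"),
            (104, "A", "C"),
        ]
        events = merge_complex(prims)
        assert len(events) == 1
        assert events[0].category is Category.COMPLEX
        assert len(events[0].components) == 2

    def test_single_matching_base_stays_one_tract(self):
        prims = split_substitution_block("chr1", 100, "ACA", "TCT")
        assert len(prims) == 1
        assert prims[0].n_changed_bases == 2
        (event,) = merge_complex(prims)
        assert event.category is Category.COMPLEX
        assert len(event.components) == 2

    def test_trim_anchored_deletion(self):
        p = trim_alleles(999, "ACCT", "A")
        assert (p.start, p.end, p.net_length) == (1000, 1002, -3)

    def test_trim_anchored_insertion(self):
        p = trim_alleles(50, "A", "ACCT")
        assert (p.start, p.end, p.net_length) == (50, 50, 3)

    def test_trim_replacement_net(self):
        # 10-base deletion with a 3-base unknown-sequence insertion: -7
        p = trim_alleles(10, "G" + "ATATATATAT", "G" + "CGC")
        assert p.net_length == -7
        assert categorize(p) is Category.DEL2_99


class TestMergeComplex:
    def test_two_sbs_gap4_merge(self):
        events = merge_complex([sbs(100), sbs(105, ref="G", alt="C")])
        assert [e.category for e in events] == [Category.COMPLEX]
        assert len(events[0].components) == 2

    def test_two_sbs_gap19_stay_separate(self):
        events = merge_complex([sbs(100), sbs(120)])
        assert [e.category for e in events] == [Category.SBS, Category.SBS]

    def test_gap_boundary_is_exclusive(self):
        # gap of exactly 10 does not merge; gap 9 does
        assert len(merge_complex([sbs(100), sbs(111)])) == 2
        assert len(merge_complex([sbs(100), sbs(110)])) == 1

    def test_large_indel_terminates_cluster(self):
        big = indel(104, -50)
        events = merge_complex([sbs(100), big, sbs(160)])
        assert [e.category for e in events] == [
            Category.SBS,
            Category.DEL2_99,
            Category.SBS,
        ]

    def test_min_cluster_size_three_configurable(self):
        events = merge_complex([sbs(100), sbs(105)], min_cluster_size=3)
        assert [e.category for e in events] == [Category.SBS, Category.SBS]
        events = merge_complex(
            [sbs(100), sbs(105), sbs(109)], min_cluster_size=3
        )
        assert [e.category for e in events] == [Category.COMPLEX]

    def test_unsorted_errors(self):
        with pytest.raises(DataError, match="sorted"):
            merge_complex([sbs(105), sbs(100)])

    def test_overlap_errors(self):
        with pytest.raises(DataError, match="overlap"):
            merge_complex([indel(100, -5), sbs(102)])

    def test_idempotent_given_sorted_input(self):
        prims = [sbs(100), indel(106, -2), sbs(140)]
        first = merge_complex(prims)
        assert merge_complex(prims) == first

    def test_net_length_sums(self):
        (event,) = merge_complex([indel(100, -3), indel(108, 2)])
        assert event.net_length == -1
        assert event.category is Category.COMPLEX


def brute_force_events(prims, gap_threshold=10, short_max=10):
    """Oracle: enumerate maximal clusters by scanning all split points."""
    mergeable = [abs(p.net_length) < short_max for p in prims]
    clusters = []
    i = 0
    while i < len(prims):
        j = i
        while (
            j + 1 < len(prims)
            and mergeable[j]
            and mergeable[j + 1]
            and prims[j + 1].start - prims[j].end - 1 < gap_threshold
        ):
            j += 1
        clusters.append((i, j))
        i = j + 1
    out = []
    for i, j in clusters:
        members = prims[i : j + 1]
        is_complex = len(members) >= 2 or any(
            p.n_changed_bases >= 2 for p in members
        )
        out.append(
            (members[0].start, max(p.end for p in members), is_complex)
        )
    return out


@pytest.mark.parametrize("seed", range(5))
def test_merge_complex_agrees_with_bruteforce(seed):
    rng = np.random.default_rng(seed)
    for _ in range(200):
        prims = []
        pos = 1
        while pos < 200:
            kind = rng.random()
            if kind < 0.5:
                p = sbs(pos)
            elif kind < 0.8:
                p = indel(pos, int(rng.integers(1, 9)) * (1 if rng.random() < 0.5 else -1))
            else:
                p = indel(pos, -int(rng.integers(10, 60)))
            prims.append(p)
            pos = p.end + 1 + int(rng.integers(1, 25))
        events = merge_complex(prims)
        got = [
            (e.start, e.end, e.category is Category.COMPLEX) for e in events
        ]
        assert got == brute_force_events(prims)


class TestPairBreakends:
    def bnd(self, rid, mate, chrom, pos):
        return VariantRecord(
            sample_id="S1", caller=Caller.COMBINED_A, chrom=chrom, pos=pos,
            ref_allele="A", alt_allele=f"A[{chrom}:1[", allele_fraction=0.5,
            depth=40, mate_id=mate, record_id=rid,
        )

    def test_interchromosomal_pair_is_translocation(self):
        pairs = pair_breakends(
            [self.bnd("a", "b", "chr1", 5000), self.bnd("b", "a", "chr3", 7000)]
        )
        assert len(pairs) == 1
        call, _ = pairs[0]
        assert call.kind is SvKind.TRANSLOCATION
        assert (call.chrom, call.start, call.mate_chrom, call.mate_pos) == (
            "chr1", 5000, "chr3", 7000,
        )

    def test_same_chrom_pair_is_inversion(self):
        pairs = pair_breakends(
            [self.bnd("a", "b", "chr2", 9000), self.bnd("b", "a", "chr2", 1000)]
        )
        call, _ = pairs[0]
        assert call.kind is SvKind.INVERSION
        assert (call.start, call.end) == (1000, 9000)

    def test_orphan_raises(self):
        with pytest.raises(OrphanBreakendError):
            pair_breakends([self.bnd("a", "missing", "chr1", 5000)])


class TestRearrangementsAndComplexity:
    def test_group_rearrangements(self, event_factory):
        evs = [
            event_factory(category=Category.SBS),
            event_factory(category=Category.DEL1, net_length=-1, start=200),
            event_factory(category=Category.DEL_GE100, net_length=-150, start=300),
            event_factory(category=Category.SV, start=1000, end=2000),
        ]
        got = group_rearrangements(evs)
        assert sorted(e.category for e in got.events) == sorted(
            [Category.DEL_GE100, Category.SV]
        )

    def test_group_rearrangements_empty(self, event_factory):
        assert len(group_rearrangements([event_factory()])) == 0

    @pytest.mark.parametrize(
        "nets,expected",
        [
            ([0, 0], ComplexitySubclass.NO_INDEL),
            ([0, -1], ComplexitySubclass.ONE_INDEL),
            ([-1, 1, 0], ComplexitySubclass.TWO_PLUS_INDELS),
        ],
    )
    def test_complexity_subclass(self, event_factory, nets, expected):
        comps = []
        pos = 100
        for net in nets:
            comps.append(sbs(pos) if net == 0 else indel(pos, net))
            pos += 12
        ev = event_factory(
            category=Category.COMPLEX,
            start=100,
            end=pos,
            net_length=sum(nets),
            components=tuple(comps),
        )
        assert complexity_subclass(ev) is expected

    def test_complexity_requires_complex(self, event_factory):
        with pytest.raises(DataError):
            complexity_subclass(event_factory(category=Category.SBS))
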