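"""Large-SV filter cascade, size stratification, and SNV impact filter."""

import pytest

from conftest import make_sv
from svkaryo.filters import (
    FilterConfig,
    REASON_NO_COVERAGE,
    REASON_QUALITY,
    REASON_SUPPORT_DEPTH,
    cross_callset_confirm,
    heatmap_bins,
    prefilter_large,
    sample_by_support,
    snv_impact_filter,
    stratify_sizes,
    support_coverage_filter,
)
from svkaryo.records import Callset, SnvRecord, SvType, Technology


def callset(records, depth=18.0, tech=Technology.LONG_READ):
    return Callset(name="cs", caller="c", technology=tech, mean_depth=depth,
                   records=records)


class TestPrefilterLarge:
    def test_large_deletion_retained(self):
        cs = callset([make_sv(id="d", pos1=35_660_443, size=25_777_364)])
        kept, discarded = prefilter_large(cs)
        assert len(kept) == 1 and discarded == 0

    def test_interchromosomal_bnd_retained_regardless_of_size(self):
        cs = callset([make_sv(id="t", svtype=SvType.BND, chrom1="chr12",
                              pos1=11_874_372, chrom2="chr21", pos2=34_948_109)])
        kept, _ = prefilter_large(cs)
        assert len(kept) == 1

    def test_threshold_is_strict(self):
        cs = callset([
            make_sv(id="under", size=50_000),
            make_sv(id="at", pos1=200_000, size=100_000),
            make_sv(id="over", pos1=600_000, size=100_001),
        ])
        kept, discarded = prefilter_large(cs)
        assert [r.id for r in kept.records] == ["over"] and discarded == 2

    def test_idempotent(self):
        cs = callset([make_sv(id=f"r{i}", pos1=10_000 + 300_000 * i,
                              size=60_000 + 30_000 * i) for i in range(6)])
        once, _ = prefilter_large(cs)
        twice, n = prefilter_large(once)
        assert [r.id for r in twice.records] == [r.id for r in once.records]
        assert n == 0


class TestSupportCoverageFilter:
    def test_long_read_arithmetic(self):
        # depth 18: support 5 passes (5 >= 5 and 5 > 3.6), coverage 20 <= 27
        cs = callset([make_sv(id="ok", support=5, position_coverage=20.0)], depth=18)
        kept, rejected = support_coverage_filter(cs)
        assert len(kept) == 1 and not rejected

    def test_short_read_depth_fraction_boundary(self):
        # depth 34.7: support must exceed 6.94, so 6 fails and 7 passes
        cs = callset(
            [
                make_sv(id="s6", support=6, position_coverage=30.0),
                make_sv(id="s7", pos1=500_000, support=7, position_coverage=30.0),
            ],
            depth=34.7,
        )
        kept, rejected = support_coverage_filter(cs)
        assert [r.id for r in kept.records] == ["s7"]
        assert rejected[0][1] == REASON_SUPPORT_DEPTH

    def test_quality_failure_dominates(self):
        cs = callset([make_sv(id="q", support=100, quality_pass=False,
                              position_coverage=20.0)], depth=18)
        kept, rejected = support_coverage_filter(cs)
        assert not kept.records and rejected[0][1] == REASON_QUALITY

    def test_coverage_cap_inclusive(self):
        cs = callset(
            [
                make_sv(id="at", support=10, position_coverage=27.0),
                make_sv(id="over", pos1=500_000, support=10, position_coverage=27.1),
            ],
            depth=18,
        )
        kept, rejected = support_coverage_filter(cs)
        assert [r.id for r in kept.records] == ["at"]

    def test_missing_coverage_labeled(self):
        cs = callset([make_sv(id="nc", support=10, position_coverage=None)], depth=18)
        _, rejected = support_coverage_filter(cs)
        assert rejected[0][1] == REASON_NO_COVERAGE

    def test_partition_and_monotonicity(self, small_sim_config):
        from svkaryo.synthcell import make_truth, simulate_sv_callset

        truth = make_truth(small_sim_config)
        cs = simulate_sv_callset(truth, small_sim_config.tech_profiles[0])
        base_cfg = FilterConfig()
        kept, rejected = support_coverage_filter(cs, base_cfg)
        assert len(kept) + len(rejected) == len(cs)
        # raising min_support can only shrink the retained set
        prev = len(kept)
        for min_support in (8, 12, 20):
            k, r = support_coverage_filter(cs, FilterConfig(min_support=min_support))
            assert len(k) <= prev
            assert len(k) + len(r) == len(cs)
            prev = len(k)
        # relaxing the coverage cap can only grow it
        loose, _ = support_coverage_filter(cs, FilterConfig(coverage_cap_fraction=10.0))
        assert len(loose) >= len(kept)


class TestSampleBySupport:
    def test_exact_support_selection(self):
        cs = callset([make_sv(id=f"s{i}", pos1=1000 + 100_000 * i, support=v)
                      for i, v in enumerate([14, 15, 15, 16])])
        picked = sample_by_support(cs)
        assert [r.support for r in picked.records] == [15, 15]
        assert sorted(r.id for r in picked.records) == ["s1", "s2"]

    def test_empty_when_no_match(self):
        cs = callset([make_sv(id="a", support=9)])
        assert len(sample_by_support(cs)) == 0

    def test_deterministic_order(self):
        recs = [make_sv(id=f"r{i}", pos1=1000 + 50_000 * i, support=15)
                for i in (3, 1, 2, 0)]
        a = [r.id for r in sample_by_support(callset(recs)).records]
        b = [r.id for r in sample_by_support(callset(list(reversed(recs)))).records]
        assert a == b


class TestCrossCallsetConfirm:
    def _candidate(self):
        return callset([make_sv(id="c", pos1=100_000, pos2=300_000)])

    def test_confirmed_when_matched_in_other(self):
        other = callset([make_sv(id="o", pos1=100_500, pos2=300_500)])
        confirmed, unconfirmed = cross_callset_confirm(self._candidate(), [other])
        assert len(confirmed) == 1 and len(unconfirmed) == 0

    def test_unconfirmed_when_matched_nowhere(self):
        other = callset([make_sv(id="o", pos1=900_000, pos2=990_000)])
        confirmed, unconfirmed = cross_callset_confirm(self._candidate(), [other])
        assert len(confirmed) == 0 and len(unconfirmed) == 1

    @pytest.mark.parametrize("offset,ok", [(1000, True), (1001, False)])
    def test_tolerance_boundary(self, offset, ok):
        other = callset([make_sv(id="o", pos1=100_000 + offset, pos2=300_000 + offset)])
        confirmed, _ = cross_callset_confirm(self._candidate(), [other], tol=1000)
        assert bool(confirmed.records) is ok

    def test_type_must_match(self):
        other = callset([make_sv(id="o", svtype=SvType.DUP, pos1=100_000, pos2=300_000)])
        confirmed, _ = cross_callset_confirm(self._candidate(), [other])
        assert not confirmed.records


class TestStratifySizes:
    @pytest.mark.parametrize(
        "size,stratum",
        [(100, "Small"), (1000, "Small"), (1001, "Medium"),
         (10_000, "Medium"), (10_001, "Large")],
    )
    def test_bin_boundaries(self, size, stratum):
        counts, labels, below = stratify_sizes([make_sv(size=size)])
        assert counts[stratum] == 1 and below == 0
        assert labels[0][1] == stratum

    def test_below_floor_counted_separately(self):
        counts, labels, below = stratify_sizes([make_sv(size=99)])
        assert below == 1 and sum(counts.values()) == 0 and labels[0][1] is None

    def test_enumeration(self):
        records = [make_sv(id=f"r{i}", size=s) for i, s in
                   enumerate([150, 5000, 20_000])]
        counts, _, _ = stratify_sizes(records)
        assert counts == {"Small": 1, "Medium": 1, "Large": 1}


class TestHeatmapBins:
    def test_intrachromosomal_counts_once(self):
        bins = heatmap_bins([make_sv(pos1=500, size=400)], window=1000)
        assert bins == {("chr1", 0): 1}

    def test_interchromosomal_counts_both_ends(self):
        rec = make_sv(svtype=SvType.BND, chrom1="chr1", pos1=500,
                      chrom2="chr2", pos2=1500)
        bins = heatmap_bins([rec], window=1000)
        assert bins == {("chr1", 0): 1, ("chr2", 1): 1}

    def test_breakpoint_conservation(self, small_sim_config):
        from svkaryo.synthcell import make_truth

        truth = make_truth(small_sim_config)
        bins = heatmap_bins(truth.svs, window=1_000_000)
        expected = sum(2 if r.interchromosomal else 1 for r in truth.svs)
        assert sum(bins.values()) == expected

    def test_empty_input(self):
        assert heatmap_bins([], window=1000) == {}


class TestSnvImpactFilter:
    def _snv(self, **kw):
        defaults = dict(chrom="chr9", pos=36_882_052, ref="C", alt="T",
                        depth=30, alt_depth=15, population_af=None,
                        consequence="LOF", affected_transcript_fraction=0.5)
        defaults.update(kw)
        return SnvRecord(**defaults)

    def test_common_variant_excluded(self):
        assert snv_impact_filter([self._snv(population_af=0.001)]) == []

    def test_population_af_boundary_inclusive(self):
        assert len(snv_impact_filter([self._snv(population_af=0.0001)])) == 1

    def test_nmd_quarter_of_transcripts_retained(self):
        kept = snv_impact_filter(
            [self._snv(consequence="NMD", affected_transcript_fraction=0.25)]
        )
        assert len(kept) == 1

    def test_fraction_below_threshold_excluded(self):
        assert snv_impact_filter([self._snv(affected_transcript_fraction=0.2)]) == []

    def test_missense_excluded(self):
        assert snv_impact_filter([self._snv(consequence="other")]) == []

    def test_missing_population_af_passes(self):
        assert len(snv_impact_filter([self._snv(population_af=None)])) == 1
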