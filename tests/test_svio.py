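"""VCF/BED parsing, dialect normalization, and round-trip fidelity."""

import math

import pytest

from conftest import make_sv
from svkaryo.records import Callset, SvType, Technology
from svkaryo.svio import (
    SvVcfParseError,
    BlacklistIntervals,
    format_bnd_alt,
    load_blacklist,
    parse_bnd_alt,
    parse_snv_vcf,
    parse_sv_vcf,
    write_sv_vcf,
)


class TestParseSvVcf:
    def test_symbolic_del_size_from_end(self, sv_vcf_factory):
        # a 26-Mb chr3 deletion: size must equal END - POS exactly
        p = sv_vcf_factory(
            "del.vcf",
            ["chr3\t35660443\tdel1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=61437807;SUPPORT=16"],
        )
        cs = parse_sv_vcf(p, caller="sniffles", technology="long_read", mean_depth=18)
        (rec,) = cs.records
        assert rec.svtype is SvType.DEL
        assert rec.size == 25_777_364
        assert rec.pos1 == 35_660_443 and rec.pos2 == 61_437_807
        assert rec.support == 16

    def test_empty_vcf_yields_empty_callset(self, sv_vcf_factory):
        cs = parse_sv_vcf(
            sv_vcf_factory("empty.vcf", []),
            caller="tiddit",
            technology="short_read",
            mean_depth=34,
        )
        assert len(cs) == 0

    def test_bnd_mate_pair_collapses_to_one_record(self, sv_vcf_factory):
        p = sv_vcf_factory(
            "bnd.vcf",
            [
                "chr12\t11874372\tbnd_a\tN\tN[chr21:34948109[\t.\tPASS\tSVTYPE=BND;MATEID=bnd_b",
                "chr21\t34948109\tbnd_b\tN\t]chr12:11874372]N\t.\tPASS\tSVTYPE=BND;MATEID=bnd_a",
            ],
        )
        cs = parse_sv_vcf(p, caller="tiddit", technology="short_read", mean_depth=34)
        (rec,) = cs.records
        assert rec.svtype is SvType.BND
        assert (rec.chrom1, rec.pos1) == ("chr12", 11_874_372)
        assert (rec.chrom2, rec.pos2) == ("chr21", 34_948_109)
        assert rec.size == 0 and rec.interchromosomal

    def test_bnd_dedup_halves_fully_mated_vcf(self, sv_vcf_factory):
        lines = []
        for k, (pos, mate) in enumerate([(100_000, 200_000), (300_000, 450_000)]):
            lines.append(
                f"chr12\t{pos}\tb{k}_1\tN\tN[chr21:{mate}[\t.\tPASS\tSVTYPE=BND;MATEID=b{k}_2"
            )
            lines.append(
                f"chr21\t{mate}\tb{k}_2\tN\t]chr12:{pos}]N\t.\tPASS\tSVTYPE=BND;MATEID=b{k}_1"
            )
        cs = parse_sv_vcf(
            sv_vcf_factory("mates.vcf", lines),
            caller="x",
            technology="short_read",
            mean_depth=30,
        )
        assert len(cs) == 2

    def test_malformed_bnd_alt_names_record(self, sv_vcf_factory):
        p = sv_vcf_factory(
            "bad.vcf",
            ["chr12\t1000\tbad1\tN\tN[chr21:999\t.\tPASS\tSVTYPE=BND"],
        )
        with pytest.raises(SvVcfParseError, match="bad1"):
            parse_sv_vcf(p, caller="x", technology="short_read", mean_depth=30)

    def test_missing_end_and_svlen_rejected(self, sv_vcf_factory):
        p = sv_vcf_factory(
            "noend.vcf", ["chr3\t1000\tr1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL"]
        )
        with pytest.raises(SvVcfParseError, match="r1"):
            parse_sv_vcf(p, caller="x", technology="short_read", mean_depth=30)

    def test_missing_support_becomes_zero(self, sv_vcf_factory):
        p = sv_vcf_factory(
            "nosupport.vcf",
            ["chr3\t1000\tr1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=5000"],
        )
        cs = parse_sv_vcf(p, caller="x", technology="short_read", mean_depth=30)
        assert cs.records[0].support == 0

    def test_low_qual_filter_flag(self, sv_vcf_factory):
        p = sv_vcf_factory(
            "filt.vcf",
            [
                "chr3\t1000\tr1\tN\t<DEL>\t.\tq5\tSVTYPE=DEL;END=5000;SUPPORT=9",
                "chr3\t90000\tr2\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=95000;SUPPORT=9",
            ],
        )
        cs = parse_sv_vcf(p, caller="x", technology="short_read", mean_depth=30)
        assert [r.quality_pass for r in cs.records] == [False, True]


class TestBndAlt:
    @pytest.mark.parametrize("strands", ["++", "+-", "-+", "--"])
    def test_format_parse_inverse(self, strands):
        alt = format_bnd_alt("N", "chr5", 123456, strands)
        chrom, pos, got = parse_bnd_alt(alt)
        assert (chrom, pos, got) == ("chr5", 123456, strands)


class TestRoundTrip:
    @pytest.mark.parametrize(
        "svtype,kw",
        [
            (SvType.DEL, dict(size=250_000)),
            (SvType.DUP, dict(size=115_823)),
            (SvType.INV, dict(size=1_000_000, strand_pair="++")),
            (SvType.INS, dict(size=500)),
            (SvType.BND, dict(chrom2="chr21", pos2=34_948_109, strand_pair="+-")),
        ],
    )
    def test_all_five_types(self, tmp_path, svtype, kw):
        rec = make_sv(
            id="ev1",
            svtype=svtype,
            chrom1="chr12",
            pos1=11_874_372,
            support=13,
            quality_pass=False,
            position_coverage=21.5,
            allele_fraction=0.5,
            **kw,
        )
        cs = Callset(
            name="t", caller="c", technology=Technology.LONG_READ, mean_depth=18,
            records=[rec],
        )
        path = tmp_path / "rt.vcf"
        write_sv_vcf(cs, path)
        back = parse_sv_vcf(path, caller="c", technology="long_read", mean_depth=18)
        (got,) = back.records
        for f in ("id", "svtype", "chrom1", "pos1", "chrom2", "pos2",
                  "strand_pair", "size", "support", "quality_pass"):
            assert getattr(got, f) == getattr(rec, f), f
        assert math.isclose(got.position_coverage, rec.position_coverage, rel_tol=1e-5)
        assert math.isclose(got.allele_fraction, rec.allele_fraction, abs_tol=1e-5)

    def test_empty_callset_round_trips(self, tmp_path):
        cs = Callset(name="e", caller="c", technology=Technology.SHORT_READ, mean_depth=34)
        path = tmp_path / "empty.vcf"
        write_sv_vcf(cs, path)
        assert len(parse_sv_vcf(path, caller="c", technology="short_read", mean_depth=34)) == 0

    def test_simulated_callset_round_trips_losslessly(self, tmp_path, small_sim_config):
        from svkaryo.synthcell import make_truth, simulate_sv_callset

        truth = make_truth(small_sim_config)
        cs = simulate_sv_callset(truth, small_sim_config.tech_profiles[1])
        path = tmp_path / "sim.vcf"
        write_sv_vcf(cs, path)
        back = parse_sv_vcf(path, caller=cs.caller, technology=cs.technology,
                            mean_depth=cs.mean_depth)
        assert len(back) == len(cs)
        by_id = {r.id: r for r in back.records}
        for a in cs.records:
            b = by_id[a.id]
            assert (a.svtype, a.chrom1, a.pos1, a.chrom2, a.pos2,
                    a.strand_pair, a.size, a.support, a.quality_pass) == (
                b.svtype, b.chrom1, b.pos1, b.chrom2, b.pos2,
                b.strand_pair, b.size, b.support, b.quality_pass)


class TestSnvVcf:
    HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=POP_AF,Number=1,Type=Float,Description="x">
##INFO=<ID=LOF,Number=.,Type=String,Description="x">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">
##contig=<ID=chr5,length=181538259>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""

    def _vcf(self, tmp_path, body):
        p = tmp_path / "snv.vcf"
        p.write_text(self.HEADER + body)
        return p

    def test_vaf_from_allele_depths(self, tmp_path):
        p = self._vcf(
            tmp_path,
            "chr5\t100\t.\tA\tG\t.\tPASS\t.\tAD\t10,10\n"
            "chr5\t200\t.\tC\tT\t.\tPASS\t.\tAD\t0,12\n",
        )
        recs = parse_snv_vcf(p)
        assert [r.vaf for r in recs] == [0.5, 1.0]

    def test_missing_allele_depth_dropped(self, tmp_path):
        p = self._vcf(
            tmp_path,
            "chr5\t100\t.\tA\tG\t.\tPASS\t.\tAD\t10,10\n"
            "chr5\t200\t.\tC\tT\t.\tPASS\t.\tAD\t.\n"
            "chr5\t300\t.\tG\tA\t.\tPASS\t.\tAD\t5,15\n",
        )
        assert len(parse_snv_vcf(p)) == 2

    def test_snpeff_lof_annotation_parsed(self, tmp_path):
        p = self._vcf(
            tmp_path,
            "chr5\t143300653\t.\tC\tT\t.\tPASS\tPOP_AF=0.00001;LOF=(NR3C1|ENSG1|4|0.25)\tAD\t12,15\n",
        )
        (rec,) = parse_snv_vcf(p)
        assert rec.consequence.value == "LOF"
        assert rec.affected_transcript_fraction == 0.25
        assert rec.population_af == pytest.approx(1e-5)


class TestBlacklist:
    def test_point_queries_half_open(self, write_text):
        bl = load_blacklist(write_text("bl.bed", "chr1\t100\t200\n"))
        assert bl.contains("chr1", 150)
        assert bl.contains("chr1", 101)  # 1-based pos 101 -> 0-based 100
        assert not bl.contains("chr1", 100)
        assert not bl.contains("chr1", 201)  # half-open end
        assert not bl.contains("chr2", 150)

    def test_overlapping_intervals_still_hit(self):
        bl = BlacklistIntervals()
        bl.add("chr1", 100, 200)
        bl.add("chr1", 150, 300)
        # brute-force oracle over the union
        for pos1 in range(95, 310):
            expected = (100 <= pos1 - 1 < 200) or (150 <= pos1 - 1 < 300)
            assert bl.contains("chr1", pos1) == expected

    def test_invalid_interval_rejected(self, write_text):
        with pytest.raises(ValueError, match="start >= end"):
            load_blacklist(write_text("bad.bed", "chr1\t200\t100\n"))


class TestBndAltProperty:
    """Bracket-notation encoding is a bijection over (chrom, pos, strands)."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(
        chrom=st.from_regex(r"chr([1-9]|1[0-9]|2[0-2]|X|Y)", fullmatch=True),
        pos=st.integers(min_value=1, max_value=250_000_000),
        strands=st.sampled_from(["++", "+-", "-+", "--"]),
        ref=st.sampled_from(["A", "C", "G", "T", "N"]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_parse_inverts_format(chrom, pos, strands, ref):
        alt = format_bnd_alt(ref, chrom, pos, strands)
        assert parse_bnd_alt(alt) == (chrom, pos, strands)
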