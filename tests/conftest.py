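import textwrap

import pytest

from svkaryo.records import SvRecord, SvType, Technology
from svkaryo.synthcell import SimConfig


@pytest.fixture
def write_text(tmp_path):
    """Write dedented text to a temp file and return its path."""

    def _write(name: str, content: str):
        p = tmp_path / name
        p.write_text(textwrap.dedent(content).lstrip())
        return p

    return _write


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
##INFO=<ID=END,Number=1,Type=Integer,Description="x">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="x">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="x">
##INFO=<ID=MATEID,Number=1,Type=String,Description="x">
##contig=<ID=chr3,length=200000000>
##contig=<ID=chr12,length=133275309>
##contig=<ID=chr21,length=46709983>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


@pytest.fixture
def sv_vcf_factory(tmp_path):
    """Build a small SV VCF from raw body lines (header supplied)."""

    def _build(name: str, body_lines: list[str]):
        p = tmp_path / name
        p.write_text(VCF_HEADER + "".join(line + "\n" for line in body_lines))
        return p

    return _build


def make_sv(
    id="r1",
    svtype=SvType.DEL,
    chrom1="chr1",
    pos1=1000,
    chrom2=None,
    pos2=None,
    size=None,
    **kwargs,
):
    """Terse SvRecord builder for tests."""
    chrom2 = chrom2 or chrom1
    if pos2 is None:
        pos2 = pos1 + (size if size is not None else 5000)
    defaults = dict(caller="test", technology=Technology.LONG_READ, support=10)
    defaults.update(kwargs)
    return SvRecord(
        id=id,
        svtype=svtype,
        chrom1=chrom1,
        pos1=pos1,
        chrom2=chrom2,
        pos2=pos2,
        **defaults,
    )


@pytest.fixture
def small_sim_config():
    """A fast simulator configuration for unit tests."""
    return SimConfig(
        seed=7,
        chromosomes=[(f"chr{i}", 5_000_000) for i in range(1, 6)],
        copy_states={"chr4": 3, "chr5": 1},
        loh_segments=[("chr3", 1_000_001, 3_000_000, "cnLOH")],
        n_truth_sv={"DEL": 40, "DUP": 20, "INV": 20, "INS": 10},
        n_translocations=10,
        snv_per_mb=100.0,
    )
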