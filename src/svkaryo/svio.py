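"""Reading and writing the formats the pipeline touches.

SV callers disagree on how they encode events in VCF: symbolic ALTs
(``<DEL>``) with ``END``/``SVLEN``, sequence-resolved ALTs with an
``SVTYPE`` INFO key, and bracketed breakend (BND) notation where one
rearrangement junction occupies two mate lines.  :func:`parse_sv_vcf`
normalizes all of these into :class:`~svkaryo.records.SvRecord`, with BND
mate pairs deduplicated to one record per junction (the lexicographically
smaller ``(chrom, pos)`` end is kept as breakpoint 1).

Coordinates are VCF 1-based; intrachromosomal size is ``end - start``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam
from intervaltree import IntervalTree

from .records import Callset, Consequence, SnvRecord, SvRecord, SvType, Technology

log = logging.getLogger(__name__)


class SvVcfParseError(ValueError):
    """Raised when a VCF record cannot be normalized into an SvRecord."""


# ---------------------------------------------------------------------------
# breakend bracket notation
# ---------------------------------------------------------------------------

_BND_RE = re.compile(
    r"^(?P<leading>[ACGTNacgtn.]*)"
    r"(?P<b1>[\[\]])(?P<chrom>[^\[\]:]+):(?P<pos>\d+)(?P<b2>[\[\]])"
    r"(?P<trailing>[ACGTNacgtn.]*)$"
)

# (sequence first?, bracket char) -> (strand at this end, strand at mate).
# t[p[ joins the right side of t to the left side of p ("+-"); t]p] joins
# right side to right side ("++"); ]p]t left-to-right ("-+"); [p[t
# left-to-left ("--").
_BND_STRANDS = {
    (True, "["): ("+", "-"),
    (True, "]"): ("+", "+"),
    (False, "]"): ("-", "+"),
    (False, "["): ("-", "-"),
}
_ALT_TEMPLATES = {
    ("+", "-"): "{ref}[{chrom}:{pos}[",
    ("+", "+"): "{ref}]{chrom}:{pos}]",
    ("-", "+"): "]{chrom}:{pos}]{ref}",
    ("-", "-"): "[{chrom}:{pos}[{ref}",
}


def parse_bnd_alt(alt: str, record_name: str = "?") -> tuple[str, int, str]:
    """Decompose a bracketed BND ALT into (mate_chrom, mate_pos, strand_pair).

    ``strand_pair`` is oriented from this line's breakend to its mate.
    """
    m = _BND_RE.match(alt)
    if not m:
        raise SvVcfParseError(f"record {record_name}: malformed BND ALT {alt!r}")
    if m.group("b1") != m.group("b2"):
        raise SvVcfParseError(f"record {record_name}: mismatched brackets in {alt!r}")
    seq_first = bool(m.group("leading"))
    if seq_first and m.group("trailing"):
        raise SvVcfParseError(f"record {record_name}: malformed BND ALT {alt!r}")
    s_here, s_mate = _BND_STRANDS[(seq_first, m.group("b1"))]
    return m.group("chrom"), int(m.group("pos")), s_here + s_mate


def format_bnd_alt(ref: str, mate_chrom: str, mate_pos: int, strand_pair: str) -> str:
    sp = strand_pair if strand_pair != "NA" else "+-"
    return _ALT_TEMPLATES[(sp[0], sp[1])].format(ref=ref, chrom=mate_chrom, pos=mate_pos)


# ---------------------------------------------------------------------------
# SV VCF reading
# ---------------------------------------------------------------------------

#: INFO then FORMAT keys tried, in order, when looking up read support.
#: Covers the Sniffles (SUPPORT/RE) and TIDDIT/short-read (PE + FORMAT DV)
#: dialects; first hit wins.
DEFAULT_SUPPORT_KEYS = ("SUPPORT", "RE", "PE", "SR", "DV", "RV")
DEFAULT_COVERAGE_KEYS = ("COVERAGE", "DP")
DEFAULT_AF_KEYS = ("AF", "VAF")


def _info_get(rec, key):
    """INFO lookup tolerant of keys missing from the header entirely."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _info_or_format(rec, key):
    value = _info_get(rec, key)
    if value is not None:
        return value
    try:
        if rec.samples and key in rec.samples[0]:
            return rec.samples[0][key]
    except (KeyError, ValueError):
        pass
    return None


def _scalar(value):
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
    return value


def _lookup_number(rec, keys) -> Optional[float]:
    for key in keys:
        value = _scalar(_info_or_format(rec, key))
        if value is not None:
            try:
                return float(value)
            except (TypeError, ValueError):
                continue
    return None


def parse_sv_vcf(
    path: str | Path,
    caller: str,
    technology: Technology | str,
    mean_depth: float,
    name: Optional[str] = None,
    support_keys: Sequence[str] = DEFAULT_SUPPORT_KEYS,
) -> Callset:
    """Read an SV VCF into a normalized :class:`Callset`.

    BND mate pairs (linked by ``EVENT``, ``MATEID``, or reciprocal
    coordinates) collapse to a single record.  Intrachromosomal records
    must carry ``END`` or ``SVLEN``; records with neither are rejected.
    """
    technology = Technology(technology)
    records: list[SvRecord] = []
    seen_bnd: dict = {}  # dedup key -> index into records
    n_support_missing = 0

    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            rid = rec.id or f"{caller}_{i}"
            alt = rec.alts[0] if rec.alts else None
            if alt is None:
                continue
            svtype_info = _scalar(_info_get(rec, "SVTYPE"))
            is_bracket = isinstance(alt, str) and ("[" in alt or "]" in alt)

            support = _lookup_number(rec, support_keys)
            if support is None:
                n_support_missing += 1
                support = 0
            coverage = _lookup_number(rec, DEFAULT_COVERAGE_KEYS)
            af = _lookup_number(rec, DEFAULT_AF_KEYS)
            qual_pass = (not rec.filter.keys()) or ("PASS" in rec.filter.keys())
            common = dict(
                caller=caller,
                technology=technology,
                support=int(support),
                quality_pass=qual_pass,
                position_coverage=coverage,
                allele_fraction=af,
            )

            if is_bracket or svtype_info == "BND":
                mate_chrom, mate_pos, strands = parse_bnd_alt(alt, rid)
                event = _scalar(_info_get(rec, "EVENT")) or None
                chrom1, pos1 = rec.chrom, rec.pos
                chrom2, pos2 = mate_chrom, mate_pos
                # canonical orientation: smaller (chrom, pos) end first
                if (chrom2, pos2) < (chrom1, pos1):
                    chrom1, pos1, chrom2, pos2 = chrom2, pos2, chrom1, pos1
                    strands = strands[::-1]
                key = event if event is not None else (chrom1, pos1, chrom2, pos2)
                if key in seen_bnd:
                    continue  # mate line of an event already recorded
                seen_bnd[key] = len(records)
                size = pos2 - pos1 if chrom1 == chrom2 else 0
                records.append(
                    SvRecord(
                        id=str(event) if event is not None else rid,
                        svtype=SvType.BND,
                        chrom1=chrom1,
                        pos1=pos1,
                        chrom2=chrom2,
                        pos2=pos2,
                        strand_pair=strands,
                        size=size,
                        **common,
                    )
                )
                continue

            # symbolic or sequence-resolved intrachromosomal record
            if isinstance(alt, str) and alt.startswith("<"):
                svtype_name = alt.strip("<>").split(":")[0]
            elif svtype_info:
                svtype_name = str(svtype_info)
            else:
                raise SvVcfParseError(
                    f"record {rid}: cannot determine SVTYPE from ALT {alt!r}"
                )
            try:
                svtype = SvType(svtype_name)
            except ValueError as exc:
                raise SvVcfParseError(f"record {rid}: unknown SVTYPE {svtype_name!r}") from exc

            svlen = _scalar(_info_get(rec, "SVLEN"))
            end = rec.stop if "END" in rec.info or rec.stop > rec.pos else None
            if svtype is SvType.INS:
                if svlen is None:
                    raise SvVcfParseError(f"record {rid}: INS without SVLEN")
                size = abs(int(svlen))
                pos2 = rec.pos + size
            else:
                if end is None and svlen is None:
                    raise SvVcfParseError(f"record {rid}: missing both END and SVLEN")
                pos2 = int(end) if end is not None else rec.pos + abs(int(svlen))
                size = pos2 - rec.pos
            strands = _scalar(_info_get(rec, "STRANDS"))
            strand_pair = str(strands) if strands in ("++", "+-", "-+", "--") else "NA"
            records.append(
                SvRecord(
                    id=rid,
                    svtype=svtype,
                    chrom1=rec.chrom,
                    pos1=rec.pos,
                    chrom2=rec.chrom,
                    pos2=pos2,
                    strand_pair=strand_pair,
                    size=size,
                    **common,
                )
            )

    if n_support_missing:
        log.warning(
            "%s: %d record(s) without a read-support field (set to 0)",
            path,
            n_support_missing,
        )
    return Callset(
        name=name or caller,
        caller=caller,
        technology=technology,
        mean_depth=mean_depth,
        records=records,
    )


# ---------------------------------------------------------------------------
# SV VCF writing
# ---------------------------------------------------------------------------

def _chrom_sort_key(chrom: str):
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(body)) if body.isdigit() else (1, body)


def _sv_header(callset: Callset) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Read support">')
    header.add_line(
        '##INFO=<ID=COVERAGE,Number=1,Type=Float,Description="Depth at position">'
    )
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">')
    header.add_line('##INFO=<ID=STRANDS,Number=1,Type=String,Description="Breakpoint strands">')
    header.add_line('##INFO=<ID=EVENT,Number=1,Type=String,Description="Event id of BND pair">')
    header.add_line('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">')
    header.add_line('##FILTER=<ID=LowQual,Description="Failed caller quality filters">')
    chroms = sorted(
        {c for r in callset.records for c in (r.chrom1, r.chrom2)}, key=_chrom_sort_key
    )
    for chrom in chroms:
        max_pos = max(
            max(r.pos2 for r in callset.records if r.chrom2 == chrom or r.chrom1 == chrom),
            max(r.pos1 for r in callset.records if r.chrom1 == chrom or r.chrom2 == chrom),
        )
        header.contigs.add(chrom, length=max_pos + 1000)
    return header


def write_sv_vcf(callset: Callset, path: str | Path) -> None:
    """Write a callset as VCF; BND events are emitted as proper mate pairs.

    ``parse_sv_vcf(write_sv_vcf(cs), ...)`` preserves all record fields.
    """
    header = _sv_header(callset)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in callset.records:
            if r.svtype is SvType.BND:
                sp = r.strand_pair
                mate_sp = sp if sp == "NA" else sp[::-1]
                for endno, (ca, pa, cb, pb, strands) in enumerate(
                    [
                        (r.chrom1, r.pos1, r.chrom2, r.pos2, sp),
                        (r.chrom2, r.pos2, r.chrom1, r.pos1, mate_sp),
                    ],
                    start=1,
                ):
                    rec = out.new_record(
                        contig=ca,
                        start=pa - 1,
                        alleles=("N", format_bnd_alt("N", cb, pb, strands)),
                    )
                    rec.id = f"{r.id}_{endno}"
                    rec.stop = pa
                    rec.info["SVTYPE"] = "BND"
                    rec.info["EVENT"] = r.id
                    rec.info["MATEID"] = f"{r.id}_{3 - endno}"
                    _set_common_info(rec, r)
                    out.write(rec)
            else:
                rec = out.new_record(
                    contig=r.chrom1, start=r.pos1 - 1, alleles=("N", f"<{r.svtype.value}>")
                )
                rec.id = r.id
                rec.info["SVTYPE"] = r.svtype.value
                rec.stop = r.pos2
                rec.info["SVLEN"] = r.size
                if r.strand_pair != "NA":
                    rec.info["STRANDS"] = r.strand_pair
                _set_common_info(rec, r)
                out.write(rec)


def _set_common_info(rec, r: SvRecord) -> None:
    rec.info["SUPPORT"] = r.support
    if r.position_coverage is not None:
        rec.info["COVERAGE"] = r.position_coverage
    if r.allele_fraction is not None:
        rec.info["AF"] = r.allele_fraction
    if not r.quality_pass:
        rec.filter.add("LowQual")
    else:
        rec.filter.add("PASS")


# ---------------------------------------------------------------------------
# SNV VCF
# ---------------------------------------------------------------------------

DEFAULT_POP_AF_KEYS = ("POP_AF", "gnomAD_AF", "PAF")


def _parse_snpeff_impact(rec) -> tuple[Optional[Consequence], Optional[float]]:
    """Read SnpEff-style ``LOF=(GENE|ID|NTR|FRACTION)`` / ``NMD=`` tags, or
    the plain ``CONSEQUENCE``/``TFRAC`` keys used for pre-digested input."""
    for key, cons in (("LOF", Consequence.LOF), ("NMD", Consequence.NMD)):
        raw = _scalar(_info_get(rec, key))
        if raw:
            fields = str(raw).strip("()").split("|")
            try:
                return cons, float(fields[-1])
            except ValueError:
                return cons, None
    raw = _scalar(_info_get(rec, "CONSEQUENCE"))
    if raw:
        frac = _scalar(_info_get(rec, "TFRAC"))
        return Consequence(str(raw)), (float(frac) if frac is not None else None)
    return None, None


def parse_snv_vcf(
    path: str | Path, pop_af_keys: Sequence[str] = DEFAULT_POP_AF_KEYS
) -> list[SnvRecord]:
    """Read SNVs with allele depths; records without usable AD are dropped
    (the count is logged)."""
    out: list[SnvRecord] = []
    n_dropped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ad = None
            if rec.samples:
                ad = rec.samples[0].get("AD")
            if ad is None or len(ad) < 2 or any(v is None for v in ad[:2]):
                n_dropped += 1
                continue
            ref_d, alt_d = int(ad[0]), int(ad[1])
            depth = ref_d + alt_d
            if depth == 0:
                n_dropped += 1
                continue
            pop_af = _lookup_number(rec, pop_af_keys)
            cons, frac = _parse_snpeff_impact(rec)
            out.append(
                SnvRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref or "N",
                    alt=str(rec.alts[0]) if rec.alts else "N",
                    depth=depth,
                    alt_depth=alt_d,
                    population_af=pop_af,
                    consequence=cons,
                    affected_transcript_fraction=frac,
                )
            )
    if n_dropped:
        log.info("%s: dropped %d SNV record(s) without allele depths", path, n_dropped)
    return out


def write_snv_vcf(records: Iterable[SnvRecord], path: str | Path) -> None:
    records = list(records)
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=POP_AF,Number=1,Type=Float,Description="Population AF">')
    header.add_line('##INFO=<ID=CONSEQUENCE,Number=1,Type=String,Description="Impact class">')
    header.add_line(
        '##INFO=<ID=TFRAC,Number=1,Type=Float,Description="Affected transcript fraction">'
    )
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    header.add_sample("SAMPLE")
    for chrom in sorted({r.chrom for r in records}, key=_chrom_sort_key):
        header.contigs.add(
            chrom, length=max(r.pos for r in records if r.chrom == chrom) + 1000
        )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt))
            if r.population_af is not None:
                rec.info["POP_AF"] = r.population_af
            if r.consequence is not None:
                rec.info["CONSEQUENCE"] = r.consequence.value
            if r.affected_transcript_fraction is not None:
                rec.info["TFRAC"] = r.affected_transcript_fraction
            rec.samples["SAMPLE"]["AD"] = (r.depth - r.alt_depth, r.alt_depth)
            rec.samples["SAMPLE"]["DP"] = r.depth
            out.write(rec)


# ---------------------------------------------------------------------------
# blacklist intervals
# ---------------------------------------------------------------------------

@dataclass
class BlacklistIntervals:
    """Genomic exclusion intervals (BED convention: 0-based, half-open)."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int) -> None:
        if start >= end:
            raise ValueError(f"blacklist interval {chrom}:{start}-{end}: start >= end")
        self.trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def contains(self, chrom: str, pos1: int) -> bool:
        """Point query with a 1-based position."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree[pos1 - 1])

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())


def load_blacklist(path: str | Path) -> BlacklistIntervals:
    bl = BlacklistIntervals()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                bl.add(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return bl


def load_gene_list(path: str | Path) -> set[str]:
    """Plain-text gene list, one symbol per line; '#' comments allowed."""
    with open(path) as fh:
        return {
            line.strip()
            for line in fh
            if line.strip() and not line.lstrip().startswith("#")
        }
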