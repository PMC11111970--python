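"""Candidate filtering for large-scale SV evaluation.

The cascade mirrors a curation workflow for rearrangement discovery in a
tumor genome without a matched normal:

1. a pre-filter keeping only large events (> 100 kb) and interchromosomal
   breakends;
2. a three-criterion support/coverage filter — caller quality flags, a
   minimum read support that must also exceed 20% of the dataset's mean
   depth of coverage, and a position-coverage cap at 150% of mean depth
   (suppressing collapsed-repeat pileups);
3. a pseudorandom sample of short-read candidates at one exact support
   value, and cross-callset confirmation as a deterministic stand-in for
   manual inspection of read evidence.

Size stratification (Small 100 bp–1 kb, Medium 1–10 kb, Large > 10 kb)
and per-window breakpoint binning support the landscape summaries, and an
impact filter selects loss-of-function / NMD SNVs at low population
frequency.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from .records import Callset, SnvRecord, SvRecord, SvType, Consequence


@dataclass
class FilterConfig:
    large_sv_min: int = 100_000          # strict >, bp
    min_support: int = 5                 # reads, inclusive
    support_depth_fraction: float = 0.2  # support must exceed this x mean depth
    coverage_cap_fraction: float = 1.5   # position coverage <= this x mean depth
    sample_support_value: int = 15       # exact-support pseudorandom sample
    small_bin: tuple[int, int] = (100, 1000)       # closed
    medium_bin: tuple[int, int] = (1000, 10_000)   # half-open (lo, hi]
    large_bin_min: int = 10_000                    # strict >
    snv_max_pop_af: float = 1e-4
    snv_min_transcript_fraction: float = 0.25


def _subset(callset: Callset, records: list[SvRecord], suffix: str) -> Callset:
    return Callset(
        name=f"{callset.name}{suffix}",
        caller=callset.caller,
        technology=callset.technology,
        mean_depth=callset.mean_depth,
        records=records,
    )


def prefilter_large(
    callset: Callset, cfg: FilterConfig | None = None
) -> tuple[Callset, int]:
    """Keep candidates with size > ``large_sv_min`` or interchromosomal
    breakends; returns (retained callset, discarded count)."""
    cfg = cfg or FilterConfig()
    kept = [
        r
        for r in callset.records
        if r.size > cfg.large_sv_min
        or (r.svtype is SvType.BND and r.interchromosomal)
    ]
    return _subset(callset, kept, ""), len(callset.records) - len(kept)


#: rejection reasons of the three-criterion filter, in evaluation order
REASON_QUALITY = "quality"
REASON_MIN_SUPPORT = "min-support"
REASON_SUPPORT_DEPTH = "support-depth"
REASON_NO_COVERAGE = "no-coverage"
REASON_COVERAGE_CAP = "coverage-cap"


def support_coverage_filter(
    callset: Callset, cfg: FilterConfig | None = None
) -> tuple[Callset, list[tuple[SvRecord, str]]]:
    """Three-criterion filter against the callset's mean depth of coverage.

    A record is retained iff it passes the caller's quality filters, has
    support >= ``min_support`` and > ``support_depth_fraction`` x mean
    depth, and position coverage <= ``coverage_cap_fraction`` x mean
    depth.  Rejections are labeled with the first failed criterion.
    """
    cfg = cfg or FilterConfig()
    depth = callset.mean_depth
    kept: list[SvRecord] = []
    rejected: list[tuple[SvRecord, str]] = []
    for r in callset.records:
        if not r.quality_pass:
            rejected.append((r, REASON_QUALITY))
        elif r.support < cfg.min_support:
            rejected.append((r, REASON_MIN_SUPPORT))
        elif not r.support > cfg.support_depth_fraction * depth:
            rejected.append((r, REASON_SUPPORT_DEPTH))
        elif r.position_coverage is None:
            rejected.append((r, REASON_NO_COVERAGE))
        elif not r.position_coverage <= cfg.coverage_cap_fraction * depth:
            rejected.append((r, REASON_COVERAGE_CAP))
        else:
            kept.append(r)
    return _subset(callset, kept, ""), rejected


def sample_by_support(callset: Callset, cfg: FilterConfig | None = None) -> Callset:
    """Records with exactly ``sample_support_value`` supporting reads, in
    deterministic coordinate order — a pseudorandom slice through a noisy
    short-read callset that needs no random number generator."""
    cfg = cfg or FilterConfig()
    kept = sorted(
        (r for r in callset.records if r.support == cfg.sample_support_value),
        key=lambda r: (r.chrom1, r.pos1, r.chrom2, r.pos2, r.id),
    )
    return _subset(callset, kept, "")


def cross_callset_confirm(
    candidates: Callset, others: list[Callset], tol: int = 1000
) -> tuple[Callset, Callset]:
    """Confirm candidates seen (same type, both ends within ``tol``) in at
    least one other callset, i.e. present in >= 2 callsets in total.

    Returns (confirmed, unconfirmed).  This is a deterministic proxy for
    manual inspection of split reads / discordant mates in a browser.
    """
    confirmed: list[SvRecord] = []
    unconfirmed: list[SvRecord] = []
    pool: list[SvRecord] = [r for cs in others for r in cs.records]
    index: dict[tuple, list[SvRecord]] = {}
    for r in pool:
        index.setdefault((r.svtype, r.chrom1, r.chrom2), []).append(r)
    for cand in candidates.records:
        hits = index.get((cand.svtype, cand.chrom1, cand.chrom2), ())
        ok = any(
            abs(cand.pos1 - r.pos1) <= tol and abs(cand.pos2 - r.pos2) <= tol
            for r in hits
        )
        (confirmed if ok else unconfirmed).append(cand)
    return _subset(candidates, confirmed, ""), _subset(candidates, unconfirmed, "")


SIZE_STRATA = ("Small", "Medium", "Large")


def stratify_sizes(
    records: Iterable[SvRecord], cfg: FilterConfig | None = None
) -> tuple[dict[str, int], list[tuple[SvRecord, Optional[str]]], int]:
    """Bin non-translocation SVs by size.

    Small = [100 bp, 1 kb], Medium = (1 kb, 10 kb], Large = (10 kb, inf);
    records below the Small floor are excluded and counted separately.
    Returns (stratum counts, per-record labels, n_below_min).
    """
    cfg = cfg or FilterConfig()
    counts = {s: 0 for s in SIZE_STRATA}
    labels: list[tuple[SvRecord, Optional[str]]] = []
    below = 0
    for r in records:
        if r.size < cfg.small_bin[0]:
            below += 1
            labels.append((r, None))
            continue
        if r.size <= cfg.small_bin[1]:
            stratum = "Small"
        elif r.size <= cfg.medium_bin[1]:
            stratum = "Medium"
        else:
            stratum = "Large"
        counts[stratum] += 1
        labels.append((r, stratum))
    return counts, labels, below


def heatmap_bins(
    records: Iterable[SvRecord], window: int
) -> dict[tuple[str, int], int]:
    """Per-(chromosome, window-index) breakpoint counts.

    Each record contributes its ``pos1`` window, plus its ``pos2`` window
    when interchromosomal, so total counts are conserved.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    counts: Counter[tuple[str, int]] = Counter()
    for r in records:
        counts[(r.chrom1, (r.pos1 - 1) // window)] += 1
        if r.interchromosomal:
            counts[(r.chrom2, (r.pos2 - 1) // window)] += 1
    return dict(counts)


def snv_impact_filter(
    snvs: Iterable[SnvRecord], cfg: FilterConfig | None = None
) -> list[SnvRecord]:
    """High-impact, rare SNVs: population AF missing or <= threshold, a
    loss-of-function or NMD consequence, and at least the configured
    fraction of the gene's transcripts affected."""
    cfg = cfg or FilterConfig()
    out = []
    for s in snvs:
        if s.population_af is not None and s.population_af > cfg.snv_max_pop_af:
            continue
        if s.consequence not in (Consequence.LOF, Consequence.NMD):
            continue
        if (
            s.affected_transcript_fraction is None
            or s.affected_transcript_fraction < cfg.snv_min_transcript_fraction
        ):
            continue
        out.append(s)
    return out
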