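"""Karyotype profiling from depth of coverage and SNV allele fractions.

Aneuploidy is called per chromosome from the ratio of its mean depth of
coverage to a diploid baseline.  The baseline self-bootstraps: it is the
median autosomal depth, refined once by excluding chromosomes whose
first-pass ratio already looks aberrant, so a trisomy (ratio ~1.5) or a
monosomy (~0.5) cannot drag the baseline with it.

Loss of heterozygosity is detected from windowed SNV allele fractions:
heterozygous sites cluster at VAF ~0.5 under disomy, so a run of windows
with (near-)zero heterozygous fraction marks an LOH segment.  A segment
whose depth ratio stays in the neutral band is copy-neutral LOH (cnLOH);
one with depleted coverage is deletion-driven LOH.
"""

from __future__ import annotations

import csv
import enum
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .records import SnvRecord


class CopyState(str, enum.Enum):
    LOSS = "loss"
    DISOMY = "disomy"
    GAIN = "gain"


class LohKind(str, enum.Enum):
    LOH = "LOH"
    CNLOH = "cnLOH"


@dataclass
class DepthTable:
    """Mean depth of coverage per chromosome, optionally per window."""

    per_chrom: dict[str, float]
    per_window: Optional[dict[tuple[str, int], float]] = None
    window: Optional[int] = None

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.per_chrom.values()):
            raise ValueError("depths must be >= 0")


def load_depth_table(path: str | Path) -> DepthTable:
    """Two-column TSV (chrom, mean_depth); '#' comments allowed."""
    per_chrom: dict[str, float] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            per_chrom[row[0]] = float(row[1])
    return DepthTable(per_chrom=per_chrom)


def write_depth_table(dt: DepthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tmean_depth\n")
        for chrom, depth in dt.per_chrom.items():
            fh.write(f"{chrom}\t{depth:.4f}\n")


@dataclass
class CopyStateCall:
    chrom: str
    ratio: float
    state: CopyState


def _is_autosome(chrom: str) -> bool:
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return body.isdigit()


def diploid_baseline(
    dt: DepthTable, neutral_band: tuple[float, float] = (0.75, 1.25)
) -> float:
    """Median autosomal depth with one refinement pass that drops
    chromosomes already outside the neutral ratio band."""
    autosomes = {c: d for c, d in dt.per_chrom.items() if _is_autosome(c)}
    pool = autosomes or dict(dt.per_chrom)
    first = statistics.median(pool.values())
    if first <= 0:
        raise ValueError("all-zero depth table")
    kept = [d for d in pool.values() if neutral_band[0] <= d / first <= neutral_band[1]]
    return statistics.median(kept) if kept else first


def call_copy_states(
    dt: DepthTable, loss_below: float = 0.75, gain_above: float = 1.25
) -> list[CopyStateCall]:
    """Classify every chromosome as loss / disomy / gain by depth ratio."""
    baseline = diploid_baseline(dt, (loss_below, gain_above))
    calls = []
    for chrom, depth in dt.per_chrom.items():
        ratio = depth / baseline
        if ratio < loss_below:
            state = CopyState.LOSS
        elif ratio > gain_above:
            state = CopyState.GAIN
        else:
            state = CopyState.DISOMY
        calls.append(CopyStateCall(chrom=chrom, ratio=ratio, state=state))
    return calls


@dataclass
class VafWindow:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # inclusive
    n_snv: int
    het_fraction: float
    mean_het_vaf: Optional[float]


def vaf_windows(
    snvs: Iterable[SnvRecord],
    window: int = 1_000_000,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> list[VafWindow]:
    """Windowed heterozygosity summary of an SNV callset.

    A site is heterozygous iff its VAF lies in ``het_band`` (symmetric by
    default, so relabeling ref/alt leaves het_fraction unchanged).
    Windows without SNVs are omitted.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    acc: dict[tuple[str, int], list[float]] = {}
    for s in snvs:
        acc.setdefault((s.chrom, (s.pos - 1) // window), []).append(s.vaf)
    out = []
    for (chrom, idx), vafs in sorted(acc.items()):
        het = [v for v in vafs if het_band[0] <= v <= het_band[1]]
        out.append(
            VafWindow(
                chrom=chrom,
                start=idx * window + 1,
                end=(idx + 1) * window,
                n_snv=len(vafs),
                het_fraction=len(het) / len(vafs),
                mean_het_vaf=(sum(het) / len(het)) if het else None,
            )
        )
    return out


@dataclass
class LohSegment:
    chrom: str
    start: int
    end: int
    kind: LohKind
    mean_depth_ratio: float
    n_windows: int = 0


def detect_loh(
    windows: list[VafWindow],
    dt: DepthTable,
    min_run: int = 5,
    het_max: float = 0.05,
    neutral_band: tuple[float, float] = (0.8, 1.2),
) -> list[LohSegment]:
    """Maximal runs of >= ``min_run`` adjacent het-depleted windows.

    Windows qualify when het_fraction <= ``het_max``; adjacency means
    consecutive genomic windows on one chromosome.  Segment kind is cnLOH
    when the mean depth ratio over the segment sits in ``neutral_band``,
    else (deletion-driven) LOH.
    """
    baseline = diploid_baseline(dt)

    def depth_ratio(chrom: str, start: int, end: int) -> float:
        if dt.per_window is not None and dt.window:
            vals = [
                d
                for (c, i), d in dt.per_window.items()
                if c == chrom and start <= i * dt.window + 1 <= end
            ]
            if vals:
                return (sum(vals) / len(vals)) / baseline
        return dt.per_chrom.get(chrom, baseline) / baseline

    segments: list[LohSegment] = []
    run: list[VafWindow] = []

    def flush() -> None:
        if len(run) >= min_run:
            chrom, start, end = run[0].chrom, run[0].start, run[-1].end
            ratio = depth_ratio(chrom, start, end)
            kind = (
                LohKind.CNLOH
                if neutral_band[0] <= ratio <= neutral_band[1]
                else LohKind.LOH
            )
            segments.append(
                LohSegment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    kind=kind,
                    mean_depth_ratio=ratio,
                    n_windows=len(run),
                )
            )
        run.clear()

    for w in sorted(windows, key=lambda w: (w.chrom, w.start)):
        qualifies = w.het_fraction <= het_max
        adjacent = (
            bool(run)
            and w.chrom == run[-1].chrom
            and w.start == run[-1].end + 1
        )
        if qualifies and (not run or adjacent):
            run.append(w)
        else:
            flush()
            if qualifies:
                run.append(w)
    flush()
    return segments


def write_loh_bed(segments: Iterable[LohSegment], path: str | Path) -> None:
    """Segments as BED (0-based half-open) with kind and depth-ratio columns."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.kind.value}\t"
                f"{s.mean_depth_ratio:.3f}\n"
            )
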