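"""Cross-callset consensus merging of structural variants.

Events from independent callsets are clustered into consensus groups when
they agree on SV type and strand orientation and both breakpoints lie
within a distance tolerance (default 1 kb) of the group representative.
Records shorter than a minimum size (default 100 bp; interchromosomal
breakends are exempt, having no length) or falling in blacklist intervals
are excluded before clustering.

Clustering is greedy single linkage in a deterministic record order
(sorted by chrom1, pos1, chrom2, pos2, id): each record joins the
matching group with the smallest breakpoint-distance sum to its
representative, or seeds a new group.  The representative is the first
member's breakpoints, which keeps merging idempotent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .records import Callset, SvRecord, SvType
from .svio import BlacklistIntervals


@dataclass
class ConsensusConfig:
    max_distance: int = 1000
    min_size: int = 100
    require_type: bool = True
    require_strand: bool = True
    blacklist: Optional[BlacklistIntervals] = None

    def __post_init__(self) -> None:
        if self.max_distance < 0 or self.min_size < 0:
            raise ValueError("max_distance and min_size must be >= 0")


@dataclass
class ConsensusGroup:
    """A cluster of concordant SV calls across callsets."""

    representative: tuple[str, int, str, int, SvType]
    members: dict[str, list[SvRecord]] = field(default_factory=dict)

    @property
    def supported_by(self) -> frozenset[str]:
        return frozenset(name for name, recs in self.members.items() if recs)

    def add(self, callset_name: str, record: SvRecord) -> None:
        self.members.setdefault(callset_name, []).append(record)

    def all_records(self) -> list[SvRecord]:
        return [r for recs in self.members.values() for r in recs]


@dataclass
class MergeStats:
    n_input: int = 0
    excluded_min_size: int = 0
    excluded_blacklist: int = 0
    n_grouped: int = 0


def _strand_compatible(a: str, b: str) -> bool:
    return a == "NA" or b == "NA" or a == b


def _match_distance(
    rec: SvRecord, group: ConsensusGroup, cfg: ConsensusConfig
) -> Optional[int]:
    """Distance sum to the group representative, or None if incompatible."""
    c1, p1, c2, p2, svtype = group.representative
    if cfg.require_type and rec.svtype is not svtype:
        return None
    if (rec.chrom1, rec.chrom2) != (c1, c2):
        return None
    d1 = abs(rec.pos1 - p1)
    d2 = abs(rec.pos2 - p2)
    if d1 > cfg.max_distance or d2 > cfg.max_distance:
        return None
    if cfg.require_strand:
        first = group.all_records()[0]
        if not _strand_compatible(rec.strand_pair, first.strand_pair):
            return None
    return d1 + d2


def merge_callsets(
    callsets: list[Callset], cfg: ConsensusConfig | None = None
) -> tuple[list[ConsensusGroup], MergeStats]:
    """Cluster records from one or more callsets into consensus groups.

    Every surviving input record belongs to exactly one group; the stats
    object accounts for records excluded by the size filter or blacklist
    so that ``excluded + grouped == input``.
    """
    cfg = cfg or ConsensusConfig()
    stats = MergeStats()
    tagged: list[tuple[str, SvRecord]] = []
    for cs in callsets:
        for rec in cs.records:
            stats.n_input += 1
            if rec.svtype is not SvType.BND and rec.size < cfg.min_size:
                stats.excluded_min_size += 1
                continue
            if cfg.blacklist is not None and (
                cfg.blacklist.contains(rec.chrom1, rec.pos1)
                or cfg.blacklist.contains(rec.chrom2, rec.pos2)
            ):
                stats.excluded_blacklist += 1
                continue
            tagged.append((cs.name, rec))
    tagged.sort(key=lambda t: (t[1].chrom1, t[1].pos1, t[1].chrom2, t[1].pos2, t[1].id))

    groups: list[ConsensusGroup] = []
    # bucket groups by (chrom pair, svtype) for near-linear matching
    buckets: dict[tuple, list[ConsensusGroup]] = {}
    for name, rec in tagged:
        key = (rec.chrom1, rec.chrom2, rec.svtype if cfg.require_type else None)
        best: Optional[ConsensusGroup] = None
        best_d: Optional[int] = None
        for group in buckets.get(key, ()):
            d = _match_distance(rec, group, cfg)
            if d is not None and (best_d is None or d < best_d):
                best, best_d = group, d
        if best is None:
            best = ConsensusGroup(
                representative=(rec.chrom1, rec.pos1, rec.chrom2, rec.pos2, rec.svtype)
            )
            groups.append(best)
            buckets.setdefault(key, []).append(best)
        best.add(name, rec)
        stats.n_grouped += 1
    return groups, stats


def combination_counts(groups: Iterable[ConsensusGroup]) -> dict[frozenset[str], int]:
    """Count groups by the exact combination of callsets supporting them
    (the Venn-diagram tallies); counts sum to the number of groups."""
    return dict(Counter(g.supported_by for g in groups))


def consensus_subset(
    groups: list[ConsensusGroup], required: Iterable[str]
) -> list[ConsensusGroup]:
    """Groups supported by (at least) every callset in ``required``.

    With ``required`` empty this returns all groups; requiring more
    callsets always yields a subset (three-way consensus nests inside
    every pairwise consensus).
    """
    required = set(required)
    known = set().union(*(g.supported_by for g in groups)) if groups else set()
    unknown = required - known
    if unknown:
        raise KeyError(f"unknown callset name(s): {sorted(unknown)}")
    return [g for g in groups if required <= g.supported_by]


def sv_allele_fractions(
    groups: Iterable[ConsensusGroup],
) -> tuple[list[float], int]:
    """Per-group mean allele fraction over members that carry one.

    Returns the values and the count of groups skipped for lack of data.
    Under a subclone-free model these are binomially spread around 0.5
    (heterozygous) with a homozygous mode at 1.0.
    """
    values: list[float] = []
    skipped = 0
    for g in groups:
        afs = [r.allele_fraction for r in g.all_records() if r.allele_fraction is not None]
        if not afs:
            skipped += 1
            continue
        values.append(sum(afs) / len(afs))
    return values, skipped
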