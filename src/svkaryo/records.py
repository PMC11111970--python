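"""Core record types shared across the pipeline.

The common currency of the package is the normalized structural-variant
call (:class:`SvRecord`): one event with two breakpoints, regardless of
which caller dialect it came from.  Interchromosomal rearrangements are
represented as a single breakend (BND) event joining ``(chrom1, pos1)``
to ``(chrom2, pos2)``; intrachromosomal events satisfy
``size == pos2 - pos1``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class Technology(str, enum.Enum):
    """Sequencing technology class of a callset."""

    SHORT_READ = "short_read"
    LONG_READ = "long_read"


class SvType(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    INS = "INS"
    BND = "BND"


#: Breakpoint strand orientations.  Symmetric SV types (DEL/DUP/INS) carry
#: ``NA`` and are compatible with everything during strand matching.
STRAND_PAIRS = ("++", "+-", "-+", "--", "NA")


@dataclass
class SvRecord:
    """One normalized structural-variant call.

    ``support`` counts split reads for long-read callsets and discordant
    mate pairs for short-read callsets.  ``size`` is ``pos2 - pos1`` for
    intrachromosomal events and 0 for interchromosomal breakends (an
    insertion's size is its inserted length, with ``pos2`` normalized to
    ``pos1 + size``).
    """

    id: str
    caller: str
    technology: Technology
    svtype: SvType
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    strand_pair: str = "NA"
    size: int = 0
    support: int = 0
    quality_pass: bool = True
    position_coverage: Optional[float] = None
    allele_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if isinstance(self.technology, str):
            self.technology = Technology(self.technology)
        if isinstance(self.svtype, str):
            self.svtype = SvType(self.svtype)
        if self.strand_pair not in STRAND_PAIRS:
            raise ValueError(f"invalid strand pair {self.strand_pair!r}")
        if self.pos1 < 1 or self.pos2 < 1:
            raise ValueError(f"{self.id}: positions must be >= 1")
        if self.chrom1 != self.chrom2 and self.svtype is not SvType.BND:
            raise ValueError(
                f"{self.id}: interchromosomal records must be BND, got {self.svtype}"
            )
        if self.chrom1 == self.chrom2:
            if self.pos2 < self.pos1:
                raise ValueError(f"{self.id}: pos2 < pos1 on {self.chrom1}")
            if self.size != self.pos2 - self.pos1:
                # normalize rather than reject: size is derived, not free
                # (an insertion's pos2 is defined as pos1 + inserted length)
                self.size = self.pos2 - self.pos1
        if self.support < 0:
            raise ValueError(f"{self.id}: negative read support")

    @property
    def interchromosomal(self) -> bool:
        return self.chrom1 != self.chrom2

    @property
    def chrom_pair(self) -> tuple[str, str]:
        return (self.chrom1, self.chrom2)

    def with_(self, **kwargs) -> "SvRecord":
        return replace(self, **kwargs)


@dataclass
class Callset:
    """An ordered collection of SV calls from one caller on one dataset."""

    name: str
    caller: str
    technology: Technology
    mean_depth: float
    records: list[SvRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if isinstance(self.technology, str):
            self.technology = Technology(self.technology)
        if self.mean_depth <= 0:
            raise ValueError(f"callset {self.name}: mean_depth must be > 0")
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"callset {self.name}: duplicate record ids")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


class Consequence(str, enum.Enum):
    LOF = "LOF"
    NMD = "NMD"
    OTHER = "other"


@dataclass
class SnvRecord:
    """A single-nucleotide variant with allele depths and optional impact
    annotation (predicted loss of function / nonsense-mediated decay and
    the fraction of the gene's transcripts affected)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_depth: int
    population_af: Optional[float] = None
    consequence: Optional[Consequence] = None
    affected_transcript_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if isinstance(self.consequence, str):
            self.consequence = Consequence(self.consequence)
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError(
                f"{self.chrom}:{self.pos}: alt_depth {self.alt_depth} "
                f"outside [0, depth={self.depth}]"
            )

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.depth
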