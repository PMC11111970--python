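"""Fusion-gene candidate normalization and tiered filtering.

RNA-seq fusion callers emit candidate tables in per-tool dialects; these
are normalized into :class:`FusionCandidate` records keyed by the ordered
(5', 3') gene pair, merged across callers.  Screening then follows two
steps used when no matched normal is available:

* **panel subtraction** — candidates whose (unordered) gene pair was also
  called in a non-leukemic reference sample (a panel of normals, e.g.
  GM12878) are removed as shared artifacts;
* **tiered filtering** — a candidate with distinct partner genes is kept
  if it satisfies any of: (T1) it involves a known leukemia-associated
  gene and has >= 5 supporting reads in total; (T2) it was called by at
  least one short-read and one long-read tool; (T3) by >= 3 short-read
  tools; or (T4) it has >= 10 supporting long reads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .records import Technology


@dataclass
class FusionCandidate:
    """A 5'->3' fusion-gene candidate with per-class read support."""

    gene5: str
    gene3: str
    callers: set[tuple[str, Technology]] = field(default_factory=set)
    sr_reads: int = 0
    lr_reads: int = 0
    breakpoint5: Optional[tuple[str, int]] = None
    breakpoint3: Optional[tuple[str, int]] = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)

    @property
    def unordered_pair(self) -> frozenset[str]:
        return frozenset((self.gene5, self.gene3))

    @property
    def total_reads(self) -> int:
        return self.sr_reads + self.lr_reads

    def caller_count(self, cls: Technology) -> int:
        return sum(1 for _, c in self.callers if c is cls)


class FusionPanel:
    """Unordered gene pairs seen in a panel-of-normals sample."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._pairs: set[frozenset[str]] = {frozenset(p) for p in pairs}

    def __contains__(self, pair) -> bool:
        if isinstance(pair, FusionCandidate):
            return pair.unordered_pair in self._pairs
        return frozenset(pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FusionPanel":
        pairs = []
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                pairs.append((row[0], row[1]))
        return cls(pairs)


def default_all_gene_list() -> set[str]:
    """Bundled list of genes recurrently altered in B-cell acute
    lymphoblastic leukemia; replaceable by any user-supplied list."""
    text = resources.files("svkaryo").joinpath("data/all_genes.txt").read_text()
    return {ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")}


@dataclass
class FusionFilterConfig:
    all_genes: set[str] = field(default_factory=default_all_gene_list)
    min_reads_tier1: int = 5
    min_sr_callers_tier3: int = 3
    min_lr_reads_tier4: int = 10


def subtract_panel(
    candidates: list[FusionCandidate], panel: FusionPanel
) -> tuple[list[FusionCandidate], int]:
    """Remove candidates whose unordered gene pair appears in the panel."""
    retained = [c for c in candidates if c not in panel]
    return retained, len(candidates) - len(retained)


TIERS = ("T1", "T2", "T3", "T4")


def satisfied_tiers(c: FusionCandidate, cfg: FusionFilterConfig) -> list[str]:
    tiers = []
    if (set(c.pair) & cfg.all_genes) and c.total_reads >= cfg.min_reads_tier1:
        tiers.append("T1")
    if c.caller_count(Technology.SHORT_READ) >= 1 and c.caller_count(Technology.LONG_READ) >= 1:
        tiers.append("T2")
    if c.caller_count(Technology.SHORT_READ) >= cfg.min_sr_callers_tier3:
        tiers.append("T3")
    if c.lr_reads >= cfg.min_lr_reads_tier4:
        tiers.append("T4")
    return tiers


def tiered_filter(
    candidates: list[FusionCandidate], cfg: FusionFilterConfig | None = None
) -> tuple[list[tuple[FusionCandidate, list[str]]], int, int]:
    """Apply the four-tier filter after panel subtraction.

    Returns (retained candidates with their satisfied-tier labels,
    n_dropped_self_pair, n_dropped_no_tier).  Adding reads or callers to
    a retained candidate can only add tiers, never drop it.
    """
    cfg = cfg or FusionFilterConfig()
    retained: list[tuple[FusionCandidate, list[str]]] = []
    n_self = 0
    n_no_tier = 0
    for c in candidates:
        if c.gene5 == c.gene3:
            n_self += 1
            continue
        tiers = satisfied_tiers(c, cfg)
        if tiers:
            retained.append((c, tiers))
        else:
            n_no_tier += 1
    return retained, n_self, n_no_tier


#: default column maps for caller table dialects; "generic" fits the
#: simulator's output and any pre-normalized table
DEFAULT_COLUMN_MAPS: dict[str, dict[str, str]] = {
    "generic": {"gene5": "gene5", "gene3": "gene3", "reads": "reads"},
    "arriba": {"gene5": "#gene1", "gene3": "gene2", "reads": "split_reads1"},
    "starfusion": {"gene5": "LeftGene", "gene3": "RightGene", "reads": "JunctionReadCount"},
}


def normalize_caller_table(
    path: str | Path,
    caller: str,
    cls: Technology | str,
    column_map: dict[str, str] | str | None = None,
) -> list[FusionCandidate]:
    """Read one caller's TSV into candidates, collapsing duplicate gene
    pairs by summing their reads.

    ``column_map`` selects the table dialect: a dict mapping
    gene5/gene3/reads to column names, the name of a bundled dialect
    (e.g. ``"arriba"``), or None for the generic schema.
    """
    cls = Technology(cls)
    if isinstance(column_map, str):
        cmap = DEFAULT_COLUMN_MAPS[column_map]
    else:
        cmap = column_map or DEFAULT_COLUMN_MAPS["generic"]
    merged: dict[tuple[str, str], FusionCandidate] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [col for col in cmap.values() if col not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing mapped column(s) {missing}")
        for row in reader:
            pair = (row[cmap["gene5"]], row[cmap["gene3"]])
            reads = int(float(row[cmap["reads"]] or 0))
            if pair not in merged:
                merged[pair] = FusionCandidate(gene5=pair[0], gene3=pair[1])
            cand = merged[pair]
            cand.callers.add((caller, cls))
            if cls is Technology.SHORT_READ:
                cand.sr_reads += reads
            else:
                cand.lr_reads += reads
    return list(merged.values())


def combine_candidates(per_caller: Iterable[list[FusionCandidate]]) -> list[FusionCandidate]:
    """Merge per-caller candidate lists on the ordered gene pair, pooling
    caller flags and read support."""
    merged: dict[tuple[str, str], FusionCandidate] = {}
    for candidates in per_caller:
        for c in candidates:
            if c.pair not in merged:
                merged[c.pair] = FusionCandidate(gene5=c.gene5, gene3=c.gene3)
            m = merged[c.pair]
            m.callers |= c.callers
            m.sr_reads += c.sr_reads
            m.lr_reads += c.lr_reads
            m.breakpoint5 = m.breakpoint5 or c.breakpoint5
            m.breakpoint3 = m.breakpoint3 or c.breakpoint3
    return list(merged.values())


def write_candidates_tsv(
    retained: list[tuple[FusionCandidate, list[str]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene5\tgene3\tsr_reads\tlr_reads\tcallers\ttiers\n")
        for c, tiers in retained:
            callers = ",".join(sorted(f"{n}:{cls.value}" for n, cls in c.callers))
            fh.write(
                f"{c.gene5}\t{c.gene3}\t{c.sr_reads}\t{c.lr_reads}\t"
                f"{callers}\t{','.join(tiers)}\n"
            )
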