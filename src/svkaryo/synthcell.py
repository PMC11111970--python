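"""Synthetic cell-line generator.

Produces a truth karyotype (structural variants, translocations, copy
states, LOH segments, fusion genes) and caller-like observations of it,
with the statistical structure the downstream analysis assumes:

* per-technology SV callsets with configurable sensitivity, Poisson
  false-positive load, Gaussian breakpoint jitter, and Poisson read
  support scaled to the dataset's depth of coverage;
* SNVs whose heterozygous allele fractions are binomial around 0.5 under
  disomy, around 1/3 or 2/3 on trisomic chromosomes, and collapse to
  homozygosity inside LOH segments;
* per-caller fusion candidate tables with shared-artifact (panel)
  contamination.

The default configuration emulates the sequencing regime of a
three-technology cell-line characterization study — mean depths 34
(short-read), 18 and 15 (long-read), a ~100-Mb toy genome with one
trisomic and one monosomic chromosome, a copy-neutral LOH segment, ~500
truth SVs, and seven nominal fusion callers (five short-read, two
long-read).  All randomness flows from a single seeded generator, so a
given seed reproduces the run exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fusionscreen import FusionCandidate, FusionPanel
from .karyoprofile import DepthTable, LohKind
from .records import Callset, SnvRecord, SvRecord, SvType, Technology

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class TechProfile:
    """Observation model of one sequencing technology + SV caller."""

    name: str
    technology: Technology
    mean_depth: float
    sensitivity: float = 0.95       # P(truth SV is called)
    fp_rate: float = 1.0            # expected false positives per Mb
    jitter_sd: float = 30.0         # breakpoint perturbation, bp
    support_model: float = 0.6      # mean support as a fraction of depth
    quality_fail_rate: float = 0.02

    def __post_init__(self) -> None:
        self.technology = Technology(self.technology)
        for p in (self.sensitivity, self.quality_fail_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"profile {self.name}: probability outside [0,1]")
        if self.jitter_sd < 0:
            raise ValueError(f"profile {self.name}: negative jitter_sd")


@dataclass
class FusionCallerProfile:
    """Observation model of one fusion-detection tool."""

    name: str
    technology: Technology
    sensitivity: float = 0.5
    fp_count_mean: float = 20.0
    panel_contamination_rate: float = 0.3
    mean_reads: float = 20.0

    def __post_init__(self) -> None:
        self.technology = Technology(self.technology)


def default_tech_profiles() -> list[TechProfile]:
    """Three profiles mimicking a 34x short-read / 18x + 15x long-read
    WGS regime, with the long-read callers more sensitive and the
    short-read caller carrying the heaviest false-positive load."""
    return [
        TechProfile(
            name="illumina",
            technology=Technology.SHORT_READ,
            mean_depth=34.0,
            sensitivity=0.91,
            fp_rate=15.0,
            jitter_sd=100.0,
            support_model=0.47,
        ),
        TechProfile(
            name="ont",
            technology=Technology.LONG_READ,
            mean_depth=18.0,
            sensitivity=0.96,
            fp_rate=1.3,
            jitter_sd=30.0,
            support_model=0.62,
        ),
        TechProfile(
            name="pacbio",
            technology=Technology.LONG_READ,
            mean_depth=15.0,
            sensitivity=0.91,
            fp_rate=6.0,
            jitter_sd=30.0,
            support_model=0.64,
        ),
    ]


def default_caller_profiles() -> list[FusionCallerProfile]:
    sr = Technology.SHORT_READ
    lr = Technology.LONG_READ
    return [
        FusionCallerProfile("arriba", sr, sensitivity=1.0, fp_count_mean=23.0),
        FusionCallerProfile("starfusion", sr, sensitivity=0.43, fp_count_mean=3.0),
        FusionCallerProfile("fusioncatcher", sr, sensitivity=0.43, fp_count_mean=60.0),
        FusionCallerProfile("squid", sr, sensitivity=0.14, fp_count_mean=300.0),
        FusionCallerProfile("pizzly", sr, sensitivity=0.43, fp_count_mean=400.0),
        FusionCallerProfile("cupcake", lr, sensitivity=0.43, fp_count_mean=80.0),
        FusionCallerProfile("jaffal", lr, sensitivity=0.43, fp_count_mean=300.0),
    ]


def default_chromosomes() -> list[tuple[str, int]]:
    return [(f"chr{i}", 10_000_000) for i in range(1, 11)]


@dataclass
class SimConfig:
    seed: int = 0
    chromosomes: list[tuple[str, int]] = field(default_factory=default_chromosomes)
    diploid_depth: float = 34.0
    # one trisomy and one monosomy, echoing a +16 / -X karyotype
    copy_states: dict[str, int] = field(
        default_factory=lambda: {"chr8": 3, "chr10": 1}
    )
    # one ~4-Mb copy-neutral LOH segment, echoing a chr9p event
    loh_segments: list[tuple[str, int, int, str]] = field(
        default_factory=lambda: [("chr9", 1_000_001, 5_000_000, "cnLOH")]
    )
    n_truth_sv: dict[str, int] = field(
        default_factory=lambda: {"DEL": 200, "DUP": 100, "INV": 100, "INS": 60}
    )
    sv_size_range: tuple[int, int] = (150, 500_000)   # log-uniform, bp
    ins_size_range: tuple[int, int] = (150, 5_000)
    n_translocations: int = 40
    het_sv_fraction: float = 0.67     # remainder homozygous
    tech_profiles: list[TechProfile] = field(default_factory=default_tech_profiles)
    snv_per_mb: float = 200.0
    het_snv_fraction: float = 0.67
    depth_noise: float = 0.02         # sd of per-chromosome depth, as a fraction
    n_truth_fusions: int = 7
    caller_profiles: list[FusionCallerProfile] = field(
        default_factory=default_caller_profiles
    )
    n_panel_pairs: int = 30
    n_gene_symbols: int = 2000
    fp_truth_clearance: int = 2000    # FP breakpoints keep this far from truth

    def __post_init__(self) -> None:
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be > 0")
        lengths = dict(self.chromosomes)
        for chrom, start, end, _ in self.loh_segments:
            if chrom not in lengths or not (1 <= start < end <= lengths[chrom]):
                raise ValueError(f"LOH segment out of bounds: {chrom}:{start}-{end}")

    @property
    def genome_mb(self) -> float:
        return sum(length for _, length in self.chromosomes) / 1e6

    def copy_state(self, chrom: str) -> int:
        return self.copy_states.get(chrom, 2)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------


@dataclass
class Truth:
    svs: list[SvRecord]
    zygosity: dict[str, str]               # record id -> "het" | "hom"
    fusions: list[tuple[str, str]]
    gene_pool: list[str]
    config: SimConfig


def _log_uniform(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def make_truth(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> Truth:
    """Place non-overlapping truth SVs, translocations, and fusion genes.

    Deterministic given ``cfg.seed``.  Raises if placement fails after
    bounded retries (genome too crowded for the requested counts).
    """
    rng = rng if rng is not None else cfg.rng()
    lengths = dict(cfg.chromosomes)
    chrom_names = [c for c, _ in cfg.chromosomes]
    weights = np.array([lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def overlaps(chrom: str, start: int, end: int) -> bool:
        return any(s <= end and start <= e for s, e in occupied[chrom])

    svs: list[SvRecord] = []
    zygosity: dict[str, str] = {}
    counter = 0

    def place(svtype: SvType, size: int) -> SvRecord:
        nonlocal counter
        for _ in range(200):
            chrom = str(rng.choice(chrom_names, p=weights))
            if lengths[chrom] <= size + 2:
                continue
            pos1 = int(rng.integers(1, lengths[chrom] - size))
            pos2 = pos1 + size
            span = size if svtype is not SvType.INS else 1
            if overlaps(chrom, pos1, pos1 + span):
                continue
            occupied[chrom].append((pos1, pos1 + span))
            counter += 1
            strand = "NA" if svtype in (SvType.DEL, SvType.DUP, SvType.INS) else "++"
            return SvRecord(
                id=f"truth_{counter}",
                caller="truth",
                technology=Technology.LONG_READ,
                svtype=svtype,
                chrom1=chrom,
                pos1=pos1,
                chrom2=chrom,
                pos2=pos2,
                strand_pair=strand,
                size=size,
            )
        raise RuntimeError(f"could not place a {svtype.value} of {size} bp")

    for type_name, n in cfg.n_truth_sv.items():
        svtype = SvType(type_name)
        lo, hi = cfg.ins_size_range if svtype is SvType.INS else cfg.sv_size_range
        for _ in range(n):
            rec = place(svtype, _log_uniform(rng, lo, hi))
            zygosity[rec.id] = "het" if rng.random() < cfg.het_sv_fraction else "hom"
            svs.append(rec)

    for _ in range(cfg.n_translocations):
        ca, cb = rng.choice(len(chrom_names), size=2, replace=False)
        ca, cb = chrom_names[int(ca)], chrom_names[int(cb)]
        pa = int(rng.integers(1, lengths[ca]))
        pb = int(rng.integers(1, lengths[cb]))
        (c1, p1), (c2, p2) = sorted([(ca, pa), (cb, pb)])
        counter += 1
        rec = SvRecord(
            id=f"truth_{counter}",
            caller="truth",
            technology=Technology.LONG_READ,
            svtype=SvType.BND,
            chrom1=c1,
            pos1=p1,
            chrom2=c2,
            pos2=p2,
            strand_pair="+-",
            size=0,
        )
        zygosity[rec.id] = "het"
        svs.append(rec)

    gene_pool = [f"G{i:04d}" for i in range(cfg.n_gene_symbols)]
    from .fusionscreen import default_all_gene_list

    all_genes = sorted(default_all_gene_list())
    fusions: list[tuple[str, str]] = []
    for i in range(cfg.n_truth_fusions):
        # anchor roughly half the truth fusions in known disease genes so
        # the gene-list tier is exercised
        if i % 2 == 0 and len(all_genes) >= 2:
            g5 = all_genes[int(rng.integers(len(all_genes)))]
        else:
            g5 = gene_pool[int(rng.integers(len(gene_pool)))]
        g3 = gene_pool[int(rng.integers(len(gene_pool)))]
        while g3 == g5:
            g3 = gene_pool[int(rng.integers(len(gene_pool)))]
        fusions.append((g5, g3))
    return Truth(svs=svs, zygosity=zygosity, fusions=fusions, gene_pool=gene_pool, config=cfg)


# ---------------------------------------------------------------------------
# SV callset simulation
# ---------------------------------------------------------------------------


def simulate_sv_callset(
    truth: Truth,
    profile: TechProfile,
    rng: Optional[np.random.Generator] = None,
) -> Callset:
    """Observe the truth through one technology profile.

    Each truth SV is emitted with probability ``sensitivity``; emitted
    breakpoints get rounded Gaussian jitter truncated to chromosome
    bounds; support is Poisson with mean ``support_model x mean_depth``
    (floor 1).  False positives arrive as a Poisson count proportional to
    genome size and are rejection-sampled away from truth breakpoints so
    TP/FP labels stay unambiguous.
    """
    cfg = truth.config
    rng = rng if rng is not None else cfg.rng()
    lengths = dict(cfg.chromosomes)
    chrom_names = [c for c, _ in cfg.chromosomes]

    truth_breakpoints: dict[str, list[int]] = {c: [] for c in chrom_names}
    for t in truth.svs:
        truth_breakpoints[t.chrom1].append(t.pos1)
        truth_breakpoints[t.chrom2].append(t.pos2)
    for v in truth_breakpoints.values():
        v.sort()

    def near_truth(chrom: str, pos: int) -> bool:
        arr = truth_breakpoints[chrom]
        i = np.searchsorted(arr, pos)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(arr[j] - pos) < cfg.fp_truth_clearance:
                return True
        return False

    def jitter(chrom: str, pos: int) -> int:
        if profile.jitter_sd == 0:
            return pos
        p = pos + int(round(rng.normal(0.0, profile.jitter_sd)))
        return min(max(p, 1), lengths[chrom])

    def draw_support() -> int:
        return max(1, int(rng.poisson(profile.support_model * profile.mean_depth)))

    def draw_coverage(chrom: str) -> float:
        base = profile.mean_depth * cfg.copy_state(chrom) / 2.0
        return float(max(1.0, rng.normal(base, 0.1 * base)))

    def draw_af(zyg: str, coverage: float) -> float:
        n = max(4, int(round(coverage)))
        p = 0.5 if zyg == "het" else 0.98
        return float(rng.binomial(n, p)) / n

    records: list[SvRecord] = []
    n = 0
    for t in truth.svs:
        if rng.random() >= profile.sensitivity:
            continue
        n += 1
        pos1 = jitter(t.chrom1, t.pos1)
        pos2 = jitter(t.chrom2, t.pos2)
        if t.chrom1 == t.chrom2 and t.svtype is not SvType.BND:
            if t.svtype is SvType.INS:
                pos2 = pos1 + t.size
            elif pos2 <= pos1:
                pos2 = pos1 + 1
        coverage = draw_coverage(t.chrom1)
        records.append(
            SvRecord(
                id=f"{profile.name}_{n}",
                caller=profile.name,
                technology=profile.technology,
                svtype=t.svtype,
                chrom1=t.chrom1,
                pos1=pos1,
                chrom2=t.chrom2,
                pos2=pos2,
                strand_pair=t.strand_pair,
                size=t.size if t.svtype is SvType.INS else max(0, pos2 - pos1)
                if t.chrom1 == t.chrom2
                else 0,
                support=draw_support(),
                quality_pass=bool(rng.random() >= profile.quality_fail_rate),
                position_coverage=coverage,
                allele_fraction=draw_af(truth.zygosity[t.id], coverage),
            )
        )

    n_fp = int(rng.poisson(profile.fp_rate * cfg.genome_mb))
    fp_types = [SvType.DEL, SvType.DUP, SvType.INV, SvType.INS]
    for _ in range(n_fp):
        for _ in range(100):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            svtype = fp_types[int(rng.integers(len(fp_types)))]
            lo, hi = (
                cfg.ins_size_range if svtype is SvType.INS else cfg.sv_size_range
            )
            size = _log_uniform(rng, lo, hi)
            if lengths[chrom] <= size + 2:
                continue
            pos1 = int(rng.integers(1, lengths[chrom] - size))
            if near_truth(chrom, pos1) or near_truth(chrom, pos1 + size):
                continue
            n += 1
            coverage = draw_coverage(chrom)
            records.append(
                SvRecord(
                    id=f"{profile.name}_{n}",
                    caller=profile.name,
                    technology=profile.technology,
                    svtype=svtype,
                    chrom1=chrom,
                    pos1=pos1,
                    chrom2=chrom,
                    pos2=pos1 + size,
                    strand_pair="NA" if svtype is not SvType.INV else "++",
                    size=size,
                    support=draw_support(),
                    quality_pass=bool(rng.random() >= profile.quality_fail_rate),
                    position_coverage=coverage,
                    allele_fraction=draw_af("het", coverage),
                )
            )
            break

    return Callset(
        name=profile.name,
        caller=profile.name,
        technology=profile.technology,
        mean_depth=profile.mean_depth,
        records=records,
    )


# ---------------------------------------------------------------------------
# SNVs and depth
# ---------------------------------------------------------------------------


def _loh_kind_at(cfg: SimConfig, chrom: str, pos: int) -> Optional[LohKind]:
    for c, start, end, kind in cfg.loh_segments:
        if c == chrom and start <= pos <= end:
            return LohKind(kind)
    return None


def simulate_snvs(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> list[SnvRecord]:
    """Germline-like SNVs with binomial allele depths.

    Heterozygous alt depth is Binomial(depth, 1/2) on disomic regions and
    Binomial(depth, 1/3 or 2/3) on trisomic chromosomes; inside LOH
    segments heterozygous sites become homozygous.  Per-site depth is
    Poisson around the chromosome's copy-scaled mean (halved again inside
    deletion-driven LOH).
    """
    rng = rng if rng is not None else cfg.rng()
    bases = ("A", "C", "G", "T")
    out: list[SnvRecord] = []
    for chrom, length in cfg.chromosomes:
        n_sites = int(round(cfg.snv_per_mb * length / 1e6))
        positions = np.sort(rng.choice(length - 1, size=n_sites, replace=False)) + 1
        copy = cfg.copy_state(chrom)
        for pos in positions:
            pos = int(pos)
            loh = _loh_kind_at(cfg, chrom, pos)
            mean_depth = cfg.diploid_depth * copy / 2.0
            if loh is LohKind.LOH:
                mean_depth *= 0.5
            depth = max(1, int(rng.poisson(mean_depth)))
            het = rng.random() < cfg.het_snv_fraction and loh is None
            if het:
                if copy == 3:
                    p = 1.0 / 3.0 if rng.random() < 0.5 else 2.0 / 3.0
                else:
                    p = 0.5
            else:
                p = 0.98
            alt_depth = int(rng.binomial(depth, p))
            ref, alt = rng.choice(4, size=2, replace=False)
            out.append(
                SnvRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=bases[int(ref)],
                    alt=bases[int(alt)],
                    depth=depth,
                    alt_depth=alt_depth,
                )
            )
    return out


def simulate_depth_table(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> DepthTable:
    """Per-chromosome mean depth scaled by copy state, with configurable
    relative sampling noise."""
    rng = rng if rng is not None else cfg.rng()
    per_chrom = {}
    for chrom, _ in cfg.chromosomes:
        base = cfg.diploid_depth * cfg.copy_state(chrom) / 2.0
        noisy = rng.normal(base, cfg.depth_noise * base) if cfg.depth_noise else base
        per_chrom[chrom] = float(max(0.1, noisy))
    return DepthTable(per_chrom=per_chrom)


# ---------------------------------------------------------------------------
# fusions
# ---------------------------------------------------------------------------


def make_panel(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> FusionPanel:
    """A panel of normals: artifact gene pairs shared with a non-tumor
    reference sample."""
    rng = rng if rng is not None else cfg.rng()
    pool = [f"G{i:04d}" for i in range(cfg.n_gene_symbols)]
    pairs = []
    for _ in range(cfg.n_panel_pairs):
        a, b = rng.choice(len(pool), size=2, replace=False)
        pairs.append((pool[int(a)], pool[int(b)]))
    return FusionPanel(pairs)


def simulate_fusion_callsets(
    truth: Truth,
    profiles: Optional[Sequence[FusionCallerProfile]] = None,
    panel: Optional[FusionPanel] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, list[FusionCandidate]]:
    """Per-caller candidate tables: detected truths, Poisson false
    fusions between random gene symbols, and injected panel pairs."""
    cfg = truth.config
    rng = rng if rng is not None else cfg.rng()
    profiles = list(profiles) if profiles is not None else cfg.caller_profiles
    panel_pairs: list[tuple[str, str]] = []
    if panel is not None:
        panel_pairs = [tuple(sorted(p)) for p in getattr(panel, "_pairs", [])]
    truth_set = set(truth.fusions)
    pool = truth.gene_pool

    out: dict[str, list[FusionCandidate]] = {}
    for prof in profiles:
        cands: dict[tuple[str, str], FusionCandidate] = {}

        def add(pair: tuple[str, str], reads: int) -> None:
            if pair not in cands:
                cands[pair] = FusionCandidate(gene5=pair[0], gene3=pair[1])
            c = cands[pair]
            c.callers.add((prof.name, prof.technology))
            if prof.technology is Technology.SHORT_READ:
                c.sr_reads += reads
            else:
                c.lr_reads += reads

        for pair in truth.fusions:
            if rng.random() < prof.sensitivity:
                add(pair, 1 + int(rng.poisson(prof.mean_reads)))
        n_fp = int(rng.poisson(prof.fp_count_mean))
        for _ in range(n_fp):
            while True:
                a, b = rng.choice(len(pool), size=2, replace=False)
                pair = (pool[int(a)], pool[int(b)])
                if pair not in truth_set:
                    break
            add(pair, 1 + int(rng.poisson(5.0)))
        for pair in panel_pairs:
            if rng.random() < prof.panel_contamination_rate:
                add(pair, 1 + int(rng.poisson(5.0)))
        out[prof.name] = list(cands.values())
    return out


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------


@dataclass
class SimOutput:
    truth: Truth
    callsets: list[Callset]
    snvs: list[SnvRecord]
    depth_table: DepthTable
    fusion_tables: dict[str, list[FusionCandidate]]
    panel: FusionPanel


def simulate_all(cfg: SimConfig) -> SimOutput:
    """Run every generator stage off one seeded stream."""
    rng = cfg.rng()
    truth = make_truth(cfg, rng)
    callsets = [simulate_sv_callset(truth, p, rng) for p in cfg.tech_profiles]
    snvs = simulate_snvs(cfg, rng)
    depth = simulate_depth_table(cfg, rng)
    panel = make_panel(cfg, rng)
    fusion_tables = simulate_fusion_callsets(truth, cfg.caller_profiles, panel, rng)
    return SimOutput(
        truth=truth,
        callsets=callsets,
        snvs=snvs,
        depth_table=depth,
        fusion_tables=fusion_tables,
        panel=panel,
    )
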