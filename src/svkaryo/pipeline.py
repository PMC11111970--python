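"""End-to-end cell-line characterization workflow.

Chains the stages — I/O normalization, consensus merging, large-SV
filtering, karyotype profiling, fusion screening, evaluation — into one
run and emits a machine-readable report.  Every count in the report is
the corresponding module's own output; nothing is recomputed here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .consensus import (
    ConsensusConfig,
    combination_counts,
    consensus_subset,
    merge_callsets,
    sv_allele_fractions,
)
from .evalmetrics import compute_sv_metrics, match_sv_truth
from .filters import (
    FilterConfig,
    heatmap_bins,
    prefilter_large,
    stratify_sizes,
    support_coverage_filter,
)
from .fusionscreen import (
    FusionFilterConfig,
    FusionPanel,
    combine_candidates,
    normalize_caller_table,
    subtract_panel,
    tiered_filter,
)
from .karyoprofile import (
    call_copy_states,
    detect_loh,
    load_depth_table,
    vaf_windows,
)
from .records import Callset, SvType
from .svio import load_blacklist, load_gene_list, parse_snv_vcf, parse_sv_vcf


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run (YAML-serializable)."""

    sv_callsets: list[dict] = field(default_factory=list)
    snv_vcf: Optional[str] = None
    depth_table: Optional[str] = None
    fusion_tables: list[dict] = field(default_factory=list)
    panel: Optional[str] = None
    gene_list: Optional[str] = None
    blacklist: Optional[str] = None
    truth_vcf: Optional[str] = None
    consensus: dict = field(default_factory=dict)
    filters: dict = field(default_factory=dict)
    heatmap_window: int = 1_000_000
    vaf_window: int = 1_000_000
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_callsets(cfg: PipelineConfig) -> list[Callset]:
    return [
        parse_sv_vcf(
            spec["path"],
            caller=spec.get("caller", "generic"),
            technology=spec.get("technology", "long_read"),
            mean_depth=float(spec.get("mean_depth", 30.0)),
            name=spec.get("name"),
        )
        for spec in cfg.sv_callsets
    ]


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run all configured stages and return the report dict.

    Stages whose inputs are not configured are skipped and appear as
    ``null`` sections; empty inputs produce a valid empty report.
    """
    report: dict[str, Any] = {
        "provenance": {"version": __version__, "config_digest": cfg.digest()},
        "warnings": [],
    }

    callsets = _load_callsets(cfg)
    blacklist = load_blacklist(cfg.blacklist) if cfg.blacklist else None
    ccfg = ConsensusConfig(blacklist=blacklist, **cfg.consensus)
    fcfg = FilterConfig(**cfg.filters)

    # consensus
    groups, merge_stats = merge_callsets(callsets, ccfg)
    combos = combination_counts(groups)
    report["consensus"] = {
        "n_input_records": merge_stats.n_input,
        "excluded_min_size": merge_stats.excluded_min_size,
        "excluded_blacklist": merge_stats.excluded_blacklist,
        "n_groups": len(groups),
        "combination_counts": {
            "+".join(sorted(k)): v for k, v in sorted(combos.items(), key=lambda kv: sorted(kv[0]))
        },
    }
    afs, af_skipped = sv_allele_fractions(groups)
    report["consensus"]["n_groups_with_af"] = len(afs)
    report["consensus"]["n_groups_without_af"] = af_skipped

    names = [cs.name for cs in callsets]
    if len(names) >= 2:
        lr_names = [cs.name for cs in callsets if cs.technology.value == "long_read"]
        subsets = {}
        if len(lr_names) >= 2:
            subsets["long_read_consensus"] = len(consensus_subset(groups, lr_names[:2]))
        subsets["all_consensus"] = len(consensus_subset(groups, names))
        report["consensus"]["subset_sizes"] = subsets

    # size strata and heatmap over all grouped, non-BND records
    grouped_records = [r for g in groups for r in g.all_records()]
    non_bnd = [r for r in grouped_records if r.svtype is not SvType.BND]
    strata, _, below = stratify_sizes(non_bnd, fcfg)
    report["size_strata"] = {**strata, "below_min": below}
    bins = heatmap_bins(grouped_records, cfg.heatmap_window)
    report["heatmap"] = {
        "window": cfg.heatmap_window,
        "total_breakpoints": sum(bins.values()),
        "n_bins": len(bins),
    }

    # large-SV filter cascade per callset
    cascade = {}
    filtered_callsets = {}
    for cs in callsets:
        pre, n_small = prefilter_large(cs, fcfg)
        kept, rejected = support_coverage_filter(pre, fcfg)
        reasons: dict[str, int] = {}
        for _, reason in rejected:
            reasons[reason] = reasons.get(reason, 0) + 1
        cascade[cs.name] = {
            "n_input": len(cs),
            "discarded_prefilter": n_small,
            "retained": len(kept),
            "rejected_by_reason": reasons,
        }
        filtered_callsets[cs.name] = kept
    report["large_sv_filter"] = cascade

    # karyotype profiling
    if cfg.depth_table:
        dt = load_depth_table(cfg.depth_table)
        states = call_copy_states(dt)
        karyo: dict[str, Any] = {
            "copy_states": [
                {"chrom": s.chrom, "ratio": round(s.ratio, 3), "state": s.state.value}
                for s in states
            ]
        }
        if cfg.snv_vcf:
            snvs = parse_snv_vcf(cfg.snv_vcf)
            windows = vaf_windows(snvs, window=cfg.vaf_window)
            segments = detect_loh(windows, dt)
            karyo["n_snv"] = len(snvs)
            karyo["n_vaf_windows"] = len(windows)
            karyo["loh_segments"] = [
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "kind": s.kind.value,
                    "depth_ratio": round(s.mean_depth_ratio, 3),
                }
                for s in segments
            ]
        report["karyotype"] = karyo
    else:
        report["karyotype"] = None

    # fusion screening
    if cfg.fusion_tables:
        per_caller = [
            normalize_caller_table(
                spec["path"],
                caller=spec.get("caller", "generic"),
                cls=spec.get("technology", "short_read"),
                column_map=spec.get("column_map"),
            )
            for spec in cfg.fusion_tables
        ]
        candidates = combine_candidates(per_caller)
        panel = FusionPanel.from_tsv(cfg.panel) if cfg.panel else FusionPanel()
        ffcfg = FusionFilterConfig()
        if cfg.gene_list:
            ffcfg.all_genes = load_gene_list(cfg.gene_list)
        non_panel, n_removed = subtract_panel(candidates, panel)
        retained, n_self, n_no_tier = tiered_filter(non_panel, ffcfg)
        report["fusions"] = {
            "n_candidates": len(candidates),
            "removed_panel": n_removed,
            "dropped_self_pair": n_self,
            "dropped_no_tier": n_no_tier,
            "retained": [
                {
                    "gene5": c.gene5,
                    "gene3": c.gene3,
                    "sr_reads": c.sr_reads,
                    "lr_reads": c.lr_reads,
                    "tiers": tiers,
                }
                for c, tiers in sorted(retained, key=lambda ct: ct[0].pair)
            ],
        }
    else:
        report["fusions"] = None

    # evaluation against a truth VCF
    if cfg.truth_vcf:
        truth_cs = parse_sv_vcf(
            cfg.truth_vcf, caller="truth", technology="long_read", mean_depth=30.0
        )
        # candidates were prefiltered to large/interchromosomal events, so
        # the truth set is restricted the same way before matching
        truth = prefilter_large(truth_cs, fcfg)[0].records
        evals = {}
        for name, kept in filtered_callsets.items():
            labels = match_sv_truth(kept.records, truth, tolerance=ccfg.max_distance)
            evals[name] = compute_sv_metrics(labels, caller=name).as_dict()
        report["evaluation"] = evals
    else:
        report["evaluation"] = None

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "summary.txt").write_text(render_summary(report))
    return report


def render_summary(report: dict[str, Any]) -> str:
    """Deterministic human-readable summary of a report."""
    lines: list[str] = ["cell-line characterization summary", "=" * 36]
    cons = report.get("consensus")
    if not cons or cons["n_groups"] == 0:
        lines.append("no variants")
    else:
        lines.append(f"consensus groups: {cons['n_groups']} "
                     f"(from {cons['n_input_records']} input records)")
        for combo, count in cons["combination_counts"].items():
            lines.append(f"  {combo}: {count}")
        strata = report.get("size_strata") or {}
        for name in ("Small", "Medium", "Large"):
            if name in strata:
                lines.append(f"size {name}: {strata[name]}")
    karyo = report.get("karyotype")
    if karyo:
        aberrant = [c for c in karyo["copy_states"] if c["state"] != "disomy"]
        lines.append(f"aneuploid chromosomes: {len(aberrant)}")
        for c in aberrant:
            lines.append(f"  {c['chrom']}: ratio {c['ratio']:.2f} -> {c['state']}")
        for s in karyo.get("loh_segments", []):
            lines.append(
                f"  {s['kind']} {s['chrom']}:{s['start']}-{s['end']} "
                f"(depth ratio {s['depth_ratio']:.2f})"
            )
    fus = report.get("fusions")
    if fus:
        lines.append(f"retained fusion candidates: {len(fus['retained'])}")
        for c in fus["retained"]:
            lines.append(
                f"  {c['gene5']}::{c['gene3']} "
                f"[{','.join(c['tiers'])}] sr={c['sr_reads']} lr={c['lr_reads']}"
            )
    ev = report.get("evaluation")
    if ev:
        for name in sorted(ev):
            r = ev[name]
            lines.append(
                f"eval {name}: tp={r['tp']} fp={r['fp']} fn={r['fn']} "
                f"sens={r['sensitivity']}% fpr={r['fpr']}%"
            )
    return "\n".join(lines) + "\n"
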