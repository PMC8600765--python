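"""End-to-end pipeline: inputs -> candidates -> filters -> panel -> report.

The stages mirror the method's four-module workflow: argument/input
preparation, per-target primer design and filtration, multiplex clustering
(greedy seeding at budget 0, relaxation at the configured budget, overlap
collapse), and report emission.  The pipeline is deterministic for a fixed
configuration; randomness exists only in the fixture generator.
"""

from __future__ import annotations

import dataclasses
import json
import os
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import __version__, clustering, genome_io, pair_filters
from .candidates import PrimerPair, attach_tags, enumerate_candidate_pairs
from .clustering import MultiplexCluster, OverlapMap
from .genome_io import GenomeReference, MaskTrack, TargetRegion
from .oligo_align import build_oligo_index
from .params import (DEFAULT_TAG_FORWARD, DEFAULT_TAG_REVERSE,
                     DesignParameters, FailureRecord)
from .thermo import ThermoConditions

OUTCOMES = ("design_failed", "filtered", "clustered", "covered_by_overlap",
            "uncovered")


@dataclass
class RunConfig:
    genome_path: str | None = None
    targets_path: str | None = None
    sites_path: str | None = None
    areas_path: str | None = None
    output_dir: str | None = None
    params: DesignParameters = field(default_factory=DesignParameters)
    conditions: ThermoConditions = field(default_factory=ThermoConditions)
    tag_forward: str = DEFAULT_TAG_FORWARD
    tag_reverse: str = DEFAULT_TAG_REVERSE
    seed: int = 0
    # stage toggles: clustering implies the earlier stages
    run_clustering: bool = True
    run_collapse: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        params = DesignParameters(**d.pop("params", {}))
        conditions = ThermoConditions(**d.pop("conditions", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"params", "conditions"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(params=params, conditions=conditions, **d)

    def echo(self) -> dict:
        return {
            "version": __version__,
            "seed": self.seed,
            "paths": {"genome": self.genome_path, "targets": self.targets_path,
                      "sites": self.sites_path, "areas": self.areas_path,
                      "output_dir": self.output_dir},
            "params": dataclasses.asdict(self.params),
            "conditions": dataclasses.asdict(self.conditions),
            "tags": {"forward": self.tag_forward, "reverse": self.tag_reverse},
            "stages": {"clustering": self.run_clustering,
                       "collapse": self.run_collapse},
        }


@dataclass
class DesignReport:
    """Per-target outcomes plus the clustered panel and the failure ledger.

    Outcome partition invariants (checked at construction): every target has
    exactly one outcome; design_failed + filtered + clustered +
    covered_by_overlap + uncovered == total targets.
    """

    outcomes: dict[str, str]
    failures: list[FailureRecord]
    pairs_by_target: dict[str, list[PrimerPair]]
    kept_by_target: dict[str, list[PrimerPair]]
    cluster: MultiplexCluster
    overlap: OverlapMap
    targets: list[TargetRegion]
    config_echo: dict

    def __post_init__(self):
        if set(self.outcomes) != {t.target_id for t in self.targets}:
            raise ValueError("outcome partition does not cover the targets")
        bad = set(self.outcomes.values()) - set(OUTCOMES)
        if bad:
            raise ValueError(f"unknown outcomes {bad}")

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(self.outcomes.values())
        return {k: c.get(k, 0) for k in OUTCOMES} | {"total": len(self.outcomes)}

    @property
    def plexity(self) -> int:
        """Targets read out by the final panel (members + overlap-covered)."""
        return sum(1 for o in self.outcomes.values()
                   if o in ("clustered", "covered_by_overlap"))

    def filter_stage_counts(self) -> dict[str, int]:
        """Target-level failure stages (one stage per fully filtered target)."""
        c: Counter = Counter()
        failed = {tid for tid, o in self.outcomes.items() if o == "filtered"}
        for rec in self.failures:
            if rec.pair_id is None and rec.target_id in failed:
                c[rec.stage] += 1
        return dict(c)

    def summary(self) -> str:
        counts = self.counts
        lines = [
            f"plexdesign {self.config_echo['version']} design summary",
            f"targets: {counts['total']}",
            f"  design failed:      {counts['design_failed']}",
            f"  filtered out:       {counts['filtered']}",
            f"  clustered:          {counts['clustered']}",
            f"  covered by overlap: {counts['covered_by_overlap']}",
            f"  uncovered:          {counts['uncovered']}",
            f"panel: {len(self.cluster.members)} primer pairs covering "
            f"{self.plexity} targets "
            f"(budget {self.config_echo['params']['allowed_cross_false_alignments']})",
        ]
        stages = self.filter_stage_counts()
        if stages:
            lines.append("filtration stages (targets): "
                         + ", ".join(f"{k}={v}" for k, v in sorted(stages.items())))
        return "\n".join(lines)


def run_design(genome: GenomeReference, targets: list[TargetRegion],
               masks: MaskTrack, params: DesignParameters,
               conditions: ThermoConditions | None = None,
               tag_forward: str = DEFAULT_TAG_FORWARD,
               tag_reverse: str = DEFAULT_TAG_REVERSE,
               config_echo: dict | None = None,
               run_clustering: bool = True,
               run_collapse: bool = True) -> DesignReport:
    """The full in-memory pipeline (all file handling stays in run_pipeline)."""
    conditions = conditions or ThermoConditions()
    outcomes: dict[str, str] = {}
    failures: list[FailureRecord] = []
    pairs_by_target: dict[str, list[PrimerPair]] = {}

    for target in targets:
        window = genome_io.extract_design_window(genome, target, params.product_max)
        result = enumerate_candidate_pairs(window, params, conditions)
        if isinstance(result, FailureRecord):
            failures.append(result)
            outcomes[target.target_id] = "design_failed"
        else:
            pairs_by_target[target.target_id] = [
                attach_tags(p, tag_forward, tag_reverse) for p in result]

    index = build_oligo_index(genome, params.seed_k)
    kept, filter_failures = pair_filters.apply_single_pair_filters(
        pairs_by_target, masks, index, genome, params, conditions, targets)
    failures.extend(filter_failures)
    for tid in pairs_by_target:
        if tid not in kept:
            outcomes[tid] = "filtered"

    if run_clustering:
        cluster = clustering.greedy_seed_cluster(kept, params, conditions, targets)
        budget = params.allowed_cross_false_alignments
        if budget > 0:
            leftovers = {rec.target_id: kept.get(rec.target_id, [])
                         for rec in cluster.uncovered}
            cluster = clustering.relax_cluster(cluster, leftovers, budget,
                                               params, conditions, targets)
    else:
        # every filtered-through target keeps its best pair, untested mutually
        cluster = MultiplexCluster({tid: ps[0] for tid, ps in kept.items()},
                                   [ps[0].pair_id for _, ps in sorted(kept.items())],
                                   {ps[0].pair_id: 0 for ps in kept.values()}, [])
    if run_collapse:
        omap, final = clustering.collapse_overlaps(cluster, targets)
    else:
        omap = OverlapMap({p.pair_id: [tid] for tid, p in cluster.members.items()},
                          {tid: p.pair_id for tid, p in cluster.members.items()})
        final = cluster
    failures.extend(final.uncovered)

    filtered_ok = set(kept)
    for tid in filtered_ok:
        if tid in final.members:
            outcomes[tid] = "clustered"
        elif tid in omap.covering:
            outcomes[tid] = "covered_by_overlap"
        else:
            outcomes[tid] = "uncovered"

    return DesignReport(outcomes, failures, pairs_by_target, kept, final,
                        omap, targets, config_echo or {"version": __version__,
                                                       "params": dataclasses.asdict(params)})


def run_pipeline(config: RunConfig) -> DesignReport:
    """File-based entry point: load inputs, run the design, return the report."""
    if not config.genome_path or not config.targets_path:
        raise ValueError("genome_path and targets_path are required")
    genome = genome_io.load_genome(config.genome_path)
    targets = genome_io.parse_targets(config.targets_path, genome)
    masks = genome_io.parse_masks(config.sites_path, config.areas_path, genome)
    report = run_design(genome, targets, masks, config.params, config.conditions,
                        config.tag_forward, config.tag_reverse, config.echo(),
                        run_clustering=config.run_clustering,
                        run_collapse=config.run_collapse)
    if config.output_dir:
        write_outputs(report, config.output_dir)
    return report


_PANEL_COLUMNS = ["pair_id", "target_id", "chrom", "forward_seq", "reverse_seq",
                  "forward_start", "forward_end", "reverse_start", "reverse_end",
                  "forward_tm", "reverse_tm", "forward_gc", "reverse_gc",
                  "product_length", "penalty", "tagged_forward", "tagged_reverse"]


def panel_frame(report: DesignReport) -> pd.DataFrame:
    rows = []
    for tid in sorted(report.cluster.members):
        p = report.cluster.members[tid]
        rows.append({
            "pair_id": p.pair_id, "target_id": p.target_id, "chrom": p.chrom,
            "forward_seq": p.forward.sequence, "reverse_seq": p.reverse.sequence,
            "forward_start": p.forward.genome_start, "forward_end": p.forward.genome_end,
            "reverse_start": p.reverse.genome_start, "reverse_end": p.reverse.genome_end,
            "forward_tm": round(p.forward.tm_C, 2), "reverse_tm": round(p.reverse.tm_C, 2),
            "forward_gc": round(p.forward.gc_percent, 1),
            "reverse_gc": round(p.reverse.gc_percent, 1),
            "product_length": p.product_length, "penalty": round(p.penalty, 4),
            "tagged_forward": p.tagged_forward or "",
            "tagged_reverse": p.tagged_reverse or "",
        })
    return pd.DataFrame(rows, columns=_PANEL_COLUMNS)


def failure_frame(report: DesignReport) -> pd.DataFrame:
    rows = [{"target_id": r.target_id, "pair_id": r.pair_id or "",
             "stage": r.stage, "reason": r.reason,
             "detail": json.dumps(r.detail, default=str, sort_keys=True)}
            for r in report.failures]
    return pd.DataFrame(rows, columns=["target_id", "pair_id", "stage",
                                       "reason", "detail"])


def write_outputs(report: DesignReport, outdir) -> dict:
    """Write panel TSV, amplicon BED, failure ledger, cluster JSON, summary."""
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, name) for name in
             ("panel.tsv", "amplicons.bed", "failures.tsv", "cluster.json",
              "summary.txt", "config.json")}
    panel_frame(report).to_csv(paths["panel.tsv"], sep="\t", index=False)
    failure_frame(report).to_csv(paths["failures.tsv"], sep="\t", index=False)
    with open(paths["amplicons.bed"], "w") as fh:
        for tid in sorted(report.cluster.members):
            p = report.cluster.members[tid]
            covered = report.overlap.amplicon_to_targets.get(p.pair_id, [tid])
            fh.write(f"{p.chrom}\t{p.product_start}\t{p.product_end}"
                     f"\t{p.pair_id}\t{len(covered)}\t+\n")
    cluster_doc = {
        "members": {tid: p.pair_id for tid, p in sorted(report.cluster.members.items())},
        "seed_order": report.cluster.seed_order,
        "budget_used": report.cluster.budget_used,
        "overlap": {k: sorted(v) for k, v in
                    sorted(report.overlap.amplicon_to_targets.items())},
        "uncovered": [{"target_id": r.target_id, "reason": r.reason,
                       "detail": r.detail} for r in report.cluster.uncovered],
        "outcomes": report.outcomes,
        "counts": report.counts,
    }
    with open(paths["cluster.json"], "w") as fh:
        json.dump(cluster_doc, fh, indent=2, sort_keys=True, default=str)
    with open(paths["summary.txt"], "w") as fh:
        fh.write(report.summary() + "\n")
    with open(paths["config.json"], "w") as fh:
        json.dump(report.config_echo, fh, indent=2, sort_keys=True)
    return paths
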