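"""End-to-end orchestration: filter -> consensus -> arbitrate -> CNVR ->
population structure, with YAML configuration and reproducible seeding.

All logic lives in the stage modules; this module sequences them, selects
depth-validation reference samples, writes plain-file outputs so any stage
can be re-run standalone, and emits a machine-readable run summary with
per-stage counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import arbitration as arb
from . import cnvr as cnvr_mod
from . import consensus as cons
from . import popstruct as pop
from .core_io import (
    AGREED,
    ARBITRATED,
    CALLER_A,
    CALLER_B,
    Cnvr,
    CnvCall,
    ConsensusCnv,
    DepthTrack,
    GeneRecord,
    SampleMetadata,
    read_caller_a,
    read_caller_b,
    read_chrom_lengths,
    read_depth_bedgraph,
    read_genes,
    read_metadata,
    sort_key,
    write_bed,
    write_consensus,
)
from .simulate import Cohort, SimConfig, simulate_all

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class InputPaths:
    caller_a: str = ""
    caller_b: str = ""
    depth_dir: str = ""
    chrom_lengths: str = ""
    genes: str = ""
    metadata: str = ""


@dataclass
class PopstructOptions:
    min_share: int = 2
    distance: str = "correlation"
    bootstraps: int = 10_000
    scales: Tuple[float, ...] = pop.DEFAULT_SCALES
    run_bootstrap: bool = True


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results"
    log_level: str = "INFO"
    window_size: int = 100
    exclude_sex_chroms: bool = True
    outlier_mad_k: float = 10.0
    simulate: Optional[SimConfig] = None
    inputs: Optional[InputPaths] = None
    filters: cons.FilterConfig = field(default_factory=cons.FilterConfig)
    arbitration: arb.ArbitrationConfig = field(default_factory=arb.ArbitrationConfig)
    popstruct: PopstructOptions = field(default_factory=PopstructOptions)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        def build(klass, payload, where):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(payload) - names
            if unknown:
                raise ValueError(f"unknown config key(s) in {where}: {', '.join(sorted(unknown))}")
            return payload

        payload = dict(build(cls, raw, "pipeline"))
        for key, klass in (
            ("simulate", SimConfig),
            ("inputs", InputPaths),
            ("filters", cons.FilterConfig),
            ("arbitration", arb.ArbitrationConfig),
            ("popstruct", PopstructOptions),
        ):
            if key in payload and payload[key] is not None and not isinstance(payload[key], klass):
                sub = dict(build(klass, payload[key], key))
                for name in ("normal_band", "cnvr_length_range", "home_freq_beta",
                             "away_freq_beta", "scales"):
                    if name in sub and isinstance(sub[name], list):
                        sub[name] = tuple(sub[name])
                payload[key] = klass(**sub)
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    """All artifacts of one pipeline run (in memory)."""

    config: PipelineConfig
    metadata: List[SampleMetadata]
    chrom_lengths: Dict[str, int]
    outliers: set
    calls_a_raw: int
    calls_b_raw: int
    filtered_a: List[CnvCall]
    filtered_b: List[CnvCall]
    consensus: List[ConsensusCnv]
    arbitrated: List[ConsensusCnv]
    arbitration_report: List[dict]
    validated_calls: List[ConsensusCnv]
    cnvrs: List[Cnvr]
    stats: cnvr_mod.CnvrStats
    gene_map: Dict
    breed_private: "object"
    matrix: Optional[pop.ScoringMatrix] = None
    tree: Optional[pop.ClusterTree] = None
    au: Optional[pop.AuResult] = None
    pca: Optional[pop.PcaResult] = None
    cohort: Optional[Cohort] = None
    summary: dict = field(default_factory=dict)


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate is not None:
        sim = dataclasses.replace(cfg.simulate, seed=cfg.simulate.seed or cfg.seed)
        cohort = simulate_all(sim)
        return (cohort.calls_a, cohort.calls_b, cohort.tracks, cohort.chrom_lengths,
                cohort.genes, cohort.metadata, cohort)
    if cfg.inputs is None:
        raise PipelineError("inputs: neither simulate nor input paths configured")
    p = cfg.inputs
    chrom_lengths = read_chrom_lengths(p.chrom_lengths, exclude_sex=cfg.exclude_sex_chroms)
    calls_a = read_caller_a(p.caller_a, chrom_lengths)
    calls_b = read_caller_b(p.caller_b, chrom_lengths)
    metadata = read_metadata(p.metadata)
    genes = read_genes(p.genes, chrom_lengths) if p.genes else []
    depth_dir = Path(p.depth_dir)
    tracks: Dict[str, DepthTrack] = {}
    for m in metadata:
        bg = depth_dir / f"{m.sample}.bedGraph"
        if not bg.exists():
            raise PipelineError(f"arbitrate: missing depth file for sample {m.sample}: {bg}")
        tracks[m.sample] = read_depth_bedgraph(bg, cfg.window_size, chrom_lengths, m.sample)
    return calls_a, calls_b, tracks, chrom_lengths, genes, metadata, None


def _exclusion_map(calls: Sequence[ConsensusCnv]) -> Dict[str, List]:
    by_sample: Dict[str, List] = {}
    for c in calls:
        by_sample.setdefault(c.sample, []).append(c.interval)
    return by_sample


def stage_arbitrate(
    consensus_calls: Sequence[ConsensusCnv],
    tracks: Mapping[str, DepthTrack],
    acfg: arb.ArbitrationConfig,
) -> Tuple[List[ConsensusCnv], List[dict]]:
    """Resolve disagreed states from depth, then refine all boundaries."""
    exclusions = _exclusion_map(consensus_calls)
    report: List[dict] = []
    kept: List[ConsensusCnv] = []
    for c in consensus_calls:
        if c.sample not in tracks:
            raise PipelineError(f"arbitrate: no depth track for sample {c.sample}")
        track = tracks[c.sample]
        others = [iv for iv in exclusions.get(c.sample, []) if iv != c.interval]
        state = c.state
        if c.state_source == ARBITRATED:
            try:
                verdict = arb.assign_state(track, c.interval, acfg, others)
            except arb.FlankUnavailable:
                verdict = arb.INVALID
            report.append({
                "chrom": c.interval.chrom, "start": c.interval.start, "end": c.interval.end,
                "sample": c.sample, "action": "state_assignment", "result": verdict,
            })
            if verdict == arb.INVALID:
                continue
            state = verdict
        refined, did = arb.refine_boundaries(track, c.interval, state, acfg, others)
        if did and refined != c.interval:
            report.append({
                "chrom": c.interval.chrom, "start": c.interval.start, "end": c.interval.end,
                "sample": c.sample, "action": "boundary_refinement",
                "result": f"{refined.start}-{refined.end}",
            })
        kept.append(ConsensusCnv(refined, c.sample, state, c.state_source,
                                 c.support_fraction, validated=False))
    return kept, report


def stage_validate(
    calls: Sequence[ConsensusCnv],
    tracks: Mapping[str, DepthTrack],
    acfg: arb.ArbitrationConfig,
    sample_order: Sequence[str],
) -> Tuple[List[ConsensusCnv], List[Cnvr], List[dict]]:
    """Merge to candidate CNVRs, depth-validate each, drop failing carriers,
    and rebuild final CNVRs from surviving calls."""
    candidates = cnvr_mod.merge_to_cnvrs(calls)
    members = cnvr_mod.assign_calls_to_cnvrs(calls, candidates)
    exclusions = _exclusion_map(calls)
    report: List[dict] = []
    surviving: List[ConsensusCnv] = []
    for i, region in enumerate(candidates):
        carrier_samples = region.samples
        carriers = [(tracks[s], st) for s, st in sorted(region.members)]
        # references: samples with no call overlapping the region, preferring
        # ones whose in-region depth looks normal (the comparison cats)
        eligible = [
            s for s in sample_order
            if s not in carrier_samples and s in tracks
            and not any(iv.overlaps(region.interval) for iv in exclusions.get(s, []))
        ]
        lo, hi = acfg.normal_band
        normal_refs, fallback_refs = [], []
        for s in eligible:
            if len(normal_refs) >= 2:
                break
            try:
                ratio = arb.region_ratio(tracks[s], region.interval, acfg)
            except arb.FlankUnavailable:
                ratio = None
            if ratio is not None and lo <= ratio <= hi:
                normal_refs.append(tracks[s])
            else:
                fallback_refs.append(tracks[s])
        refs = normal_refs if len(normal_refs) >= 2 else (normal_refs + fallback_refs)[:2]
        res = arb.validate_region(carriers, refs, region.interval, acfg, exclusions)
        for (sample, st), ok in sorted(res.carrier_pass.items()):
            if not ok:
                report.append({
                    "chrom": region.interval.chrom, "start": region.interval.start,
                    "end": region.interval.end, "sample": sample, "action": "carrier_removed",
                    "result": st,
                })
        if not res.verdict:
            report.append({
                "chrom": region.interval.chrom, "start": region.interval.start,
                "end": region.interval.end, "sample": ".", "action": "region_discarded",
                "result": region.state,
            })
            continue
        for call in members[i]:
            if res.carrier_pass.get((call.sample, call.state), False):
                surviving.append(ConsensusCnv(call.interval, call.sample, call.state,
                                              call.state_source, call.support_fraction,
                                              validated=True))
    final = cnvr_mod.merge_to_cnvrs(surviving)
    return surviving, final, report


def run_all(cfg: PipelineConfig, write_outputs: bool = True) -> RunResult:
    """Execute every stage; returns all artifacts plus a summary dict."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    logger.info("run_all: thresholds %s | %s", cfg.filters, cfg.arbitration)

    calls_a, calls_b, tracks, chrom_lengths, genes, metadata, cohort = _load_inputs(cfg)
    sample_order = [m.sample for m in metadata]

    # outlier exclusion on raw per-sample counts, either caller
    counts_a = {s: 0 for s in sample_order}
    counts_b = {s: 0 for s in sample_order}
    for c in calls_a:
        counts_a[c.sample] = counts_a.get(c.sample, 0) + 1
    for c in calls_b:
        counts_b[c.sample] = counts_b.get(c.sample, 0) + 1
    outliers = cons.flag_sample_outliers(counts_a, cfg.outlier_mad_k) | cons.flag_sample_outliers(
        counts_b, cfg.outlier_mad_k
    )
    if outliers:
        logger.info("excluding outlier sample(s): %s", sorted(outliers))
        calls_a = [c for c in calls_a if c.sample not in outliers]
        calls_b = [c for c in calls_b if c.sample not in outliers]
        metadata = [m for m in metadata if m.sample not in outliers]
        sample_order = [m.sample for m in metadata]

    filtered_a = cons.filter_caller_a(calls_a, cfg.filters)
    filtered_b = cons.filter_caller_b(calls_b, cfg.filters)
    consensus_calls = cons.find_consensus(filtered_a, filtered_b, cfg.filters)

    arbitrated, report = stage_arbitrate(consensus_calls, tracks, cfg.arbitration)
    validated, cnvrs, vreport = stage_validate(arbitrated, tracks, cfg.arbitration, sample_order)
    report.extend(vreport)

    stats = cnvr_mod.compute_stats(cnvrs, chrom_lengths)
    gene_map = cnvr_mod.annotate_genes(cnvrs, genes)
    breed_private = cnvr_mod.breed_private_report(cnvrs, metadata, gene_map)

    matrix = tree = au = pca_res = None
    popcfg = cfg.popstruct
    matrix = pop.build_matrix(cnvrs, sample_order, popcfg.min_share)
    if matrix.n_rows >= 2 and len(sample_order) >= 2:
        if popcfg.run_bootstrap and popcfg.bootstraps > 0:
            boot = pop.multiscale_bootstrap(
                matrix, popcfg.scales, popcfg.bootstraps, seed=cfg.seed, method=popcfg.distance
            )
            au = pop.au_pvalues(boot)
            tree = pop.attach_support(boot.tree, au)
        else:
            tree = pop.upgma(pop.sample_distance(matrix, popcfg.distance), matrix.samples)
        pca_res = pop.pca(matrix)
    else:
        logger.warning("popstruct skipped: matrix too small (%d rows)", matrix.n_rows)

    summary = {
        "n_samples": len(sample_order),
        "outliers_excluded": sorted(outliers),
        "caller_a_raw": len(calls_a),
        "caller_b_raw": len(calls_b),
        "caller_a_filtered": len(filtered_a),
        "caller_b_filtered": len(filtered_b),
        "consensus": len(consensus_calls),
        "consensus_agreed": sum(1 for c in consensus_calls if c.state_source == AGREED),
        "consensus_arbitrated": sum(1 for c in consensus_calls if c.state_source == ARBITRATED),
        "arbitration_kept": len(arbitrated),
        "arbitration_dropped": len(consensus_calls) - len(arbitrated),
        "validated_calls": len(validated),
        "cnvrs": stats.to_dict(),
        "scoring_matrix_rows": matrix.n_rows if matrix is not None else 0,
        "pca_variance_fractions": (
            [float(f) for f in pca_res.variance_fraction[:5]] if pca_res is not None else []
        ),
    }

    result = RunResult(
        config=cfg, metadata=metadata, chrom_lengths=chrom_lengths, outliers=outliers,
        calls_a_raw=len(calls_a), calls_b_raw=len(calls_b),
        filtered_a=filtered_a, filtered_b=filtered_b, consensus=consensus_calls,
        arbitrated=arbitrated, arbitration_report=report, validated_calls=validated,
        cnvrs=cnvrs, stats=stats, gene_map=gene_map, breed_private=breed_private,
        matrix=matrix, tree=tree, au=au, pca=pca_res, cohort=cohort, summary=summary,
    )
    if write_outputs:
        _write_outputs(result)
    return result


def _write_outputs(res: RunResult) -> None:
    import csv

    outdir = Path(res.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom_order = list(res.chrom_lengths)

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(res.config.to_dict(), fh, sort_keys=True)

    write_consensus(res.consensus, outdir / "consensus.tsv")
    write_consensus(res.validated_calls, outdir / "validated_calls.tsv")
    write_bed(res.cnvrs, outdir / "cnvr.bed", chrom_order)

    with open(outdir / "arbitration_report.tsv", "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=["chrom", "start", "end", "sample", "action", "result"],
                            delimiter="\t", lineterminator="\n")
        wr.writeheader()
        wr.writerows(res.arbitration_report)

    key = sort_key(chrom_order)
    with open(outdir / "cnvr_members.tsv", "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t", lineterminator="\n")
        wr.writerow(["chrom", "start", "end", "state", "singleton", "sample", "member_state"])
        for r in sorted(res.cnvrs, key=lambda r: key(r.interval)):
            for sample, st in sorted(r.members):
                wr.writerow([r.interval.chrom, r.interval.start, r.interval.end,
                             r.state, int(r.singleton), sample, st])

    (outdir / "stats.json").write_text(json.dumps(res.stats.to_dict(), indent=1, sort_keys=True))
    res.breed_private.to_csv(outdir / "breed_private.tsv", sep="\t", index=False)

    with open(outdir / "gene_annotation.tsv", "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t", lineterminator="\n")
        wr.writerow(["chrom", "start", "end", "state", "genes"])
        for r in sorted(res.gene_map, key=lambda r: key(r.interval)):
            wr.writerow([r.interval.chrom, r.interval.start, r.interval.end, r.state,
                         ",".join(res.gene_map[r])])

    if res.matrix is not None:
        res.matrix.to_frame().to_csv(outdir / "matrix.tsv", sep="\t")
    if res.tree is not None:
        (outdir / "tree.nwk").write_text(res.tree.to_newick() + "\n")
    if res.pca is not None:
        import pandas as pd

        pd.DataFrame(res.pca.scores, index=res.pca.samples).to_csv(
            outdir / "pca_scores.tsv", sep="\t"
        )
        pd.DataFrame({"variance_fraction": res.pca.variance_fraction}).to_csv(
            outdir / "pca_variance.tsv", sep="\t", index_label="component"
        )

    (outdir / "summary.json").write_text(json.dumps(res.summary, indent=1, sort_keys=True))
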