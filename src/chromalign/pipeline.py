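"""End-to-end orchestration: tracks -> regions -> alignments -> clusters.

All stages are callable on their own; this module wires them together with
one configuration object, one seed, and standard-format outputs.  All
randomness (null-pair sampling) descends from ``RunConfig.seed`` through
per-group seed sequences keyed by the group's position in sorted order, so
a rerun with the same inputs and configuration is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .alignment import AlignParams, AlignmentResult, align_pair, island_peaks
from .clustering import (
    DistanceMatrix,
    SignatureCluster,
    build_distance_matrix,
    cluster_tree,
    consensus_profile,
    cut_tree,
    linkage_to_newick,
    member_footprints,
)
from .enrichment import FeatureSet, enrichment_table
from .nullstats import (
    EVDParams,
    alignment_pvalue,
    choose_island_threshold,
    fit_evd,
    trim_related_pairs,
)
from .nullstats import _sample_pairs
from .profiles import (
    ScoreTrack,
    SmoothingParams,
    TagTrack,
    TransformParams,
    smooth_track,
    transform_track,
)
from .regions import GenomicRegion, GroupKey, call_regions, group_regions, slice_profile
from . import io as cio

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "transform_tracks"]

logger = logging.getLogger("chromalign")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with printed defaults where they exist."""

    bin_size: int = 200
    smoothing_variance: float = 1.0
    smoothing_radius: int = 4
    transform_a: float = 9.0
    transform_b: float = 2.19
    high_threshold: float = 0.5
    merge_distance: int = 1000
    key_marks: List[str] = field(default_factory=list)
    small_max_bp: int = 5000
    large_min_bp: int = 10000
    gamma_small: float = 2.0
    gamma_medium_large: float = 1.5
    beta: float = 0.3
    delta_small: float = 0.5
    delta_medium_large: float = 0.3
    null_n_pairs: int = 1000
    null_outlier_fence: float = 3.0
    island_threshold_quantile: float = 0.5
    island_threshold_absolute: Optional[float] = None
    min_null_islands: int = 50
    p_threshold: float = 0.05
    min_cluster_size: int = 3
    fe_threshold: float = 3.0
    seed: int = 0

    def align_params(self, size_class: str) -> AlignParams:
        if size_class == "small":
            return AlignParams(gamma=self.gamma_small, beta=self.beta,
                               delta=self.delta_small)
        return AlignParams(gamma=self.gamma_medium_large, beta=self.beta,
                           delta=self.delta_medium_large)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class ClusterRecord:
    """One signature cluster with genomic coordinates attached."""

    cluster_id: int
    group_key: GroupKey
    members: List[GenomicRegion]
    medoid: GenomicRegion
    footprints_bp: List[Tuple[str, int, int]]
    consensus: np.ndarray
    marks: Tuple[str, ...]


@dataclass
class PipelineResult:
    score_tracks: List[ScoreTrack]
    regions: List[GenomicRegion]
    groups: Dict[GroupKey, List[GenomicRegion]]
    clusters: List[ClusterRecord]
    labels: Dict[GenomicRegion, int]  # region -> cluster id (clustered only)
    evd: Dict[GroupKey, EVDParams]
    pvalues: Dict[GroupKey, DistanceMatrix]
    alignments: Dict[GroupKey, Dict[Tuple[GenomicRegion, GenomicRegion], AlignmentResult]]
    linkages: Dict[GroupKey, np.ndarray]
    skipped: Dict[GroupKey, str]
    enrichment: Optional[pd.DataFrame]
    counts: Dict[str, int]
    message: str = ""


def transform_tracks(
    tag_tracks: Sequence[TagTrack], config: RunConfig
) -> List[ScoreTrack]:
    """Smooth raw tag tracks and transform them to score tracks."""
    sp = SmoothingParams(variance=config.smoothing_variance,
                         truncation_radius=config.smoothing_radius)
    tp = TransformParams(a=config.transform_a, b=config.transform_b)
    return [transform_track(smooth_track(t, sp), tp) for t in tag_tracks]


def _empty_result(score_tracks, message: str) -> PipelineResult:
    logger.warning(message)
    return PipelineResult(
        score_tracks=score_tracks, regions=[], groups={}, clusters=[],
        labels={}, evd={}, pvalues={}, alignments={}, linkages={}, skipped={},
        enrichment=None, counts={"regions": 0, "groups": 0, "pairs": 0,
                                 "islands": 0, "clusters": 0},
        message=message,
    )


def run_pipeline(
    tag_tracks: Sequence[TagTrack],
    config: RunConfig = RunConfig(),
    features: Sequence[FeatureSet] = (),
    outdir=None,
) -> PipelineResult:
    """Run every stage on raw tag tracks; optionally write all outputs.

    Groups too small to align or to calibrate a null are reported in
    ``result.skipped`` rather than aborting the run.
    """
    score_tracks = transform_tracks(tag_tracks, config)
    binning = score_tracks[0].binning
    regions = call_regions(score_tracks, config.high_threshold, config.merge_distance)
    if not regions:
        return _empty_result(score_tracks, "no regions called; nothing to align")
    groups = group_regions(
        regions, score_tracks, config.key_marks, config.high_threshold,
        config.small_max_bp, config.large_min_bp,
    )
    logger.info("called %d regions in %d groups", len(regions), len(groups))

    clusters: List[ClusterRecord] = []
    labels: Dict[GenomicRegion, int] = {}
    evds: Dict[GroupKey, EVDParams] = {}
    pmats: Dict[GroupKey, DistanceMatrix] = {}
    all_aligns: Dict[GroupKey, Dict] = {}
    linkages: Dict[GroupKey, np.ndarray] = {}
    skipped: Dict[GroupKey, str] = {}
    n_pairs_total = 0
    n_islands_total = 0
    next_cluster = 0

    for group_index, key in enumerate(sorted(groups)):
        regs = sorted(groups[key])
        if len(regs) < max(2, config.min_cluster_size):
            skipped[key] = f"only {len(regs)} region(s); too few to cluster"
            continue
        params = config.align_params(key.size_class)
        profiles = {r: slice_profile(r, score_tracks) for r in regs}

        # all within-group pairwise alignments
        aligns: Dict[Tuple[GenomicRegion, GenomicRegion], AlignmentResult] = {}
        for a in range(len(regs)):
            for b in range(a + 1, len(regs)):
                aligns[(regs[a], regs[b])] = align_pair(
                    profiles[regs[a]], profiles[regs[b]], params
                )
        n_pairs_total += len(aligns)
        all_aligns[key] = aligns

        # null calibration on randomly sampled pairs
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(group_index,))
        )
        pair_idx = _sample_pairs(len(regs), config.null_n_pairs, rng)
        per_pair_scores, areas = [], []
        for i, j in pair_idx:
            x, y = profiles[regs[i]], profiles[regs[j]]
            per_pair_scores.append(island_peaks(x, y, params, 0.0))
            areas.append(float(x.n_bins * y.n_bins))
        try:
            keep = trim_related_pairs(per_pair_scores, config.null_outlier_fence)
            kept_scores = [per_pair_scores[i] for i in keep]
            area = float(sum(areas[i] for i in keep))
            if config.island_threshold_absolute is not None:
                t_island = float(config.island_threshold_absolute)
            else:
                t_island = choose_island_threshold(
                    kept_scores, config.island_threshold_quantile
                )
            pooled = np.concatenate(kept_scores) if kept_scores else np.empty(0)
            evd = fit_evd(pooled, t_island, area,
                          min_islands=config.min_null_islands, group_key=key)
        except ValueError as err:
            skipped[key] = f"null calibration failed: {err}"
            continue
        evds[key] = evd
        n_islands_total += evd.n_islands

        pv = {
            pair: alignment_pvalue(res.score, evd, pair[0].n_bins, pair[1].n_bins)
            for pair, res in aligns.items()
        }
        dist = build_distance_matrix(regs, pv)
        pmats[key] = dist
        linkage = cluster_tree(dist)
        linkages[key] = linkage
        memberships, _ = cut_tree(
            linkage, config.p_threshold, len(regs), config.min_cluster_size
        )
        for leaves in memberships:
            members = [regs[l] for l in leaves]
            medoid, _, consensus = consensus_profile(members, profiles, dist, aligns)
            fps = member_footprints(
                members, aligns, {r: r.n_bins for r in members}
            )
            fps_bp = [
                (
                    r.chrom,
                    (r.start_bin + fps[r][0]) * binning.bin_size,
                    (r.start_bin + fps[r][1]) * binning.bin_size,
                )
                for r in members
            ]
            clusters.append(
                ClusterRecord(
                    cluster_id=next_cluster,
                    group_key=key,
                    members=members,
                    medoid=medoid,
                    footprints_bp=fps_bp,
                    consensus=consensus,
                    marks=profiles[medoid].marks,
                )
            )
            for r in members:
                labels[r] = next_cluster
            next_cluster += 1

    enr = None
    if features and clusters:
        enr = enrichment_table(
            {c.cluster_id: c.footprints_bp for c in clusters},
            list(features),
            config.fe_threshold,
        )

    counts = {
        "regions": len(regions),
        "groups": len(groups),
        "pairs": n_pairs_total,
        "islands": n_islands_total,
        "clusters": len(clusters),
    }
    logger.info("pipeline counts: %s", counts)
    result = PipelineResult(
        score_tracks=score_tracks, regions=regions, groups=groups,
        clusters=clusters, labels=labels, evd=evds, pvalues=pmats,
        alignments=all_aligns, linkages=linkages, skipped=skipped,
        enrichment=enr, counts=counts,
    )
    if outdir is not None:
        write_outputs(result, config, outdir)
    return result


def write_outputs(result: PipelineResult, config: RunConfig, outdir) -> None:
    """Write every stage's outputs under ``outdir`` (created if needed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    if not result.score_tracks:
        return
    binning = result.score_tracks[0].binning
    bs = binning.bin_size

    cio.write_regions_bed(
        (
            (r.chrom, r.start_bin * bs, min(r.end_bin * bs, binning.chrom_sizes[r.chrom]),
             f"region_{i:05d}")
            for i, r in enumerate(result.regions)
        ),
        outdir / "regions.bed",
    )

    cluster_rows = []
    for c in result.clusters:
        for (chrom, start, end), member in zip(c.footprints_bp, c.members):
            cluster_rows.append((chrom, start, end, f"cluster_{c.cluster_id:04d}"))
        np.savetxt(
            outdir / f"consensus_{c.cluster_id:04d}.tsv",
            c.consensus,
            delimiter="\t",
            fmt="%.6f",
            header="\t".join(c.marks),
            comments="# marks: ",
        )
    cio.write_regions_bed(cluster_rows, outdir / "clusters.bed")

    with open(outdir / "evd_params.tsv", "w") as fh:
        fh.write("group\tlambda\tK\tthreshold\tn_islands\n")
        for key in sorted(result.evd):
            e = result.evd[key]
            presence = "".join("1" if p else "0" for p in key.presence)
            fh.write(
                f"{presence or '-'}:{key.size_class}\t{e.lam:.6g}\t{e.k:.6g}"
                f"\t{e.threshold:.6g}\t{e.n_islands}\n"
            )

    for gi, key in enumerate(sorted(result.linkages)):
        regs = sorted(result.groups[key])
        names = [f"{r.chrom}_{r.start_bin * bs}_{r.end_bin * bs}" for r in regs]
        with open(outdir / f"dendrogram_{gi:03d}.newick", "w") as fh:
            fh.write(linkage_to_newick(result.linkages[key], names) + "\n")

    if result.enrichment is not None:
        result.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                                 float_format="%.6g")
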