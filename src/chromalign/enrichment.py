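"""Fold-enrichment annotation of signature clusters over genomic features.

A cluster of signature instances is compared against an annotated feature
set (TSS windows, p300 sites, DNase hypersensitive sites, ...) with the
fold-enrichment ratio FE = f_p / f_g, where f_p is the fraction of
instances overlapping the merged feature intervals by at least 1 bp and
f_g is the fraction of the genome the merged features cover.  FE strictly
greater than 3 flags a signature as enriched for the feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["FeatureSet", "EnrichmentResult", "fold_enrichment", "enrichment_table"]

Interval = Tuple[str, int, int]


def _merge_intervals(intervals: Sequence[Interval]) -> Dict[str, np.ndarray]:
    """Merge overlapping/adjacent intervals per chromosome; (n, 2) arrays."""
    per_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"empty feature interval: {(chrom, start, end)!r}")
        per_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


@dataclass
class FeatureSet:
    """A named set of genomic intervals, merged on construction."""

    name: str
    intervals: Sequence[Interval]
    genome_size: int
    merged: Dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome size must be positive")
        if not self.intervals:
            raise ValueError(f"feature set {self.name!r} is empty")
        self.merged = _merge_intervals(self.intervals)

    @property
    def total_bp(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.merged.values()))

    @property
    def genome_fraction(self) -> float:
        return min(1.0, self.total_bp / self.genome_size)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) intersects the merged features by >= 1 bp."""
        arr = self.merged.get(chrom)
        if arr is None:
            return False
        i = int(np.searchsorted(arr[:, 0], end))  # features starting before `end`
        return i > 0 and arr[i - 1, 1] > start


@dataclass(frozen=True)
class EnrichmentResult:
    cluster_id: object
    feature: str
    f_p: float
    f_g: float
    fold_enrichment: float
    enriched: bool


def fold_enrichment(
    footprints: Sequence[Interval],
    features: FeatureSet,
    cluster_id: object = None,
    fe_threshold: float = 3.0,
) -> EnrichmentResult:
    """Fold enrichment of a cluster's instance footprints over one feature set.

    f_p counts instances (not base pairs): the fraction of footprints with
    any overlap of the merged features.  Enrichment is strict: FE > threshold.
    """
    if not footprints:
        raise ValueError("cluster has no footprints")
    f_g = features.genome_fraction
    if f_g <= 0:
        raise ValueError(f"feature set {features.name!r} covers no sequence")
    hits = sum(features.overlaps(c, s, e) for c, s, e in footprints)
    f_p = hits / len(footprints)
    fe = f_p / f_g
    return EnrichmentResult(
        cluster_id=cluster_id,
        feature=features.name,
        f_p=f_p,
        f_g=f_g,
        fold_enrichment=fe,
        enriched=bool(fe > fe_threshold),
    )


def enrichment_table(
    clusters: Mapping[object, Sequence[Interval]],
    feature_sets: Sequence[FeatureSet],
    fe_threshold: float = 3.0,
) -> pd.DataFrame:
    """All cluster x feature fold enrichments as a tidy table."""
    rows = []
    for cid, footprints in clusters.items():
        for fs in feature_sets:
            r = fold_enrichment(footprints, fs, cluster_id=cid, fe_threshold=fe_threshold)
            rows.append(
                {
                    "cluster": cid,
                    "feature": r.feature,
                    "f_p": r.f_p,
                    "f_g": r.f_g,
                    "fold_enrichment": r.fold_enrichment,
                    "enriched": r.enriched,
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster", "feature", "f_p", "f_g", "fold_enrichment", "enriched"]
    )
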