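"""Candidate-region delineation, profile slicing and pre-grouping.

Contiguous runs of bins in which *any* modification scores at or above the
high-signal threshold become candidate regions; nearby regions (< 1 kb
apart by default) are merged.  No size limit is applied, so signatures of
any extent — including large multi-segment domains — remain discoverable.
Regions are then pre-grouped by (i) presence/absence of a user-chosen set
of key modifications and (ii) genomic size class, which bounds the number
of pairwise alignments and keeps scoring regimes comparable within a group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .profiles import GenomeBinning, ScoreTrack

__all__ = [
    "GenomicRegion",
    "ProfileMatrix",
    "GroupKey",
    "SMALL_MAX_BP",
    "LARGE_MIN_BP",
    "call_regions",
    "group_regions",
    "slice_profile",
    "size_class",
]

#: size-class boundaries in bp: small <= 5 kb, 5 kb < medium < 10 kb, large >= 10 kb
SMALL_MAX_BP = 5000
LARGE_MIN_BP = 10000


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """Half-open run of bins [start_bin, end_bin) on one chromosome."""

    chrom: str
    start_bin: int
    end_bin: int

    def __post_init__(self) -> None:
        if self.end_bin <= self.start_bin:
            raise ValueError(f"empty region: {self}")

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin

    def length_bp(self, binning: GenomeBinning) -> int:
        """Region length in bp (last bin possibly truncated at the chromosome end)."""
        start = self.start_bin * binning.bin_size
        end = min(self.end_bin * binning.bin_size, binning.chrom_sizes[self.chrom])
        return end - start


@dataclass(frozen=True)
class ProfileMatrix:
    """M modifications x L bins of transformed scores for one region."""

    region: GenomicRegion
    marks: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.marks), self.region.n_bins):
            raise ValueError(
                f"profile shape {values.shape} does not match "
                f"{len(self.marks)} marks x {self.region.n_bins} bins"
            )
        if values.size and (values.min() < 0.0 or values.max() > 1.0):
            raise ValueError("profile entries must lie in [0, 1]")
        object.__setattr__(self, "values", values)

    @property
    def n_marks(self) -> int:
        return len(self.marks)

    @property
    def n_bins(self) -> int:
        return self.region.n_bins


@dataclass(frozen=True, order=True)
class GroupKey:
    """Key-mark presence vector plus size class; the pre-grouping label."""

    presence: Tuple[bool, ...]
    size_class: str


def size_class(
    length_bp: int, small_max_bp: int = SMALL_MAX_BP, large_min_bp: int = LARGE_MIN_BP
) -> str:
    if length_bp <= small_max_bp:
        return "small"
    if length_bp >= large_min_bp:
        return "large"
    return "medium"


def _check_common_binning(score_tracks: Sequence[ScoreTrack]) -> GenomeBinning:
    if not score_tracks:
        raise ValueError("at least one score track is required")
    binning = score_tracks[0].binning
    for track in score_tracks[1:]:
        if track.binning != binning:
            raise ValueError(
                f"track {track.mark!r} uses a different genome binning"
            )
    return binning


def call_regions(
    score_tracks: Sequence[ScoreTrack],
    high_threshold: float = 0.5,
    merge_distance: int = 1000,
) -> List[GenomicRegion]:
    """Delineate contiguous high-signal regions and merge nearby ones.

    A bin is *high* if any modification's score is >= ``high_threshold``
    (0.5 is the score of twice the genomic median).  Maximal runs of high
    bins form regions regardless of which mark is high in each bin, so
    spatially shifted marks merge into one region.  Regions on the same
    chromosome separated by less than ``merge_distance`` bp are merged.
    No size threshold is applied.
    """
    binning = _check_common_binning(score_tracks)
    regions: List[GenomicRegion] = []
    for chrom in binning.chroms:
        high = np.zeros(binning.n_bins(chrom), dtype=bool)
        for track in score_tracks:
            high |= track.data[chrom] >= high_threshold
        if not high.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], high.view(np.int8), [0]))))
        starts, ends = edges[::2], edges[1::2]
        merged = [(int(starts[0]), int(ends[0]))]
        for s, e in zip(starts[1:], ends[1:]):
            gap_bp = (int(s) - merged[-1][1]) * binning.bin_size
            if gap_bp < merge_distance:
                merged[-1] = (merged[-1][0], int(e))
            else:
                merged.append((int(s), int(e)))
        regions.extend(GenomicRegion(chrom, s, e) for s, e in merged)
    return regions


def group_regions(
    regions: Sequence[GenomicRegion],
    score_tracks: Sequence[ScoreTrack],
    key_marks: Sequence[str],
    high_threshold: float = 0.5,
    small_max_bp: int = SMALL_MAX_BP,
    large_min_bp: int = LARGE_MIN_BP,
) -> Dict[GroupKey, List[GenomicRegion]]:
    """Assign each region a key-mark presence vector and size class.

    A key mark is *present* in a region when at least one of the region's
    bins has that mark's score >= ``high_threshold`` (the same cutoff used
    for region calling, so presence needs no extra parameter).
    """
    binning = _check_common_binning(score_tracks)
    by_mark = {t.mark: t for t in score_tracks}
    for mark in key_marks:
        if mark not in by_mark:
            raise KeyError(f"unknown key mark {mark!r}")
    groups: Dict[GroupKey, List[GenomicRegion]] = {}
    for region in regions:
        presence = tuple(
            bool(
                np.any(
                    by_mark[mark].data[region.chrom][region.start_bin : region.end_bin]
                    >= high_threshold
                )
            )
            for mark in key_marks
        )
        key = GroupKey(presence, size_class(region.length_bp(binning), small_max_bp, large_min_bp))
        groups.setdefault(key, []).append(region)
    return groups


def slice_profile(
    region: GenomicRegion, score_tracks: Sequence[ScoreTrack]
) -> ProfileMatrix:
    """Extract the M x L score matrix of a region (row order = track order)."""
    binning = _check_common_binning(score_tracks)
    if region.chrom not in binning.chrom_sizes:
        raise ValueError(f"region on unknown chromosome: {region}")
    if region.end_bin > binning.n_bins(region.chrom) or region.start_bin < 0:
        raise ValueError(f"region out of track bounds: {region}")
    values = np.vstack(
        [t.data[region.chrom][region.start_bin : region.end_bin] for t in score_tracks]
    )
    return ProfileMatrix(
        region=region, marks=tuple(t.mark for t in score_tracks), values=values
    )
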