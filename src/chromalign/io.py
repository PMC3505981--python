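"""Readers and writers for the plain-text genomics formats the tool speaks.

All coordinates on disk are 0-based half-open (BED/bedGraph convention);
internally everything is bin-index space, converted at these boundaries.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .profiles import GenomeBinning, TagTrack, _BinnedTrack

__all__ = [
    "read_chrom_sizes",
    "read_bedgraph",
    "read_bed_positions",
    "read_bed_intervals",
    "write_bedgraph",
    "write_regions_bed",
]


def read_chrom_sizes(path) -> Dict[str, int]:
    """Two-column whitespace-separated chromosome-sizes table."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "size"],
                     dtype={"chrom": str, "size": np.int64}, comment="#")
    return dict(zip(df["chrom"], df["size"]))


def read_bedgraph(path, binning: GenomeBinning, mark: str = "") -> TagTrack:
    """Load a 4-column bedGraph of per-interval tag counts onto the binning.

    Interval values are distributed over bins in proportion to bp overlap,
    so bedGraphs already aligned to the binning round-trip exactly.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    data = {c: np.zeros(binning.n_bins(c)) for c in binning.chroms}
    bs = binning.bin_size
    for chrom, start, end, value in df.itertuples(index=False):
        if chrom not in data:
            raise ValueError(f"bedGraph record on unknown chromosome {chrom!r}")
        if end <= start or start < 0 or end > binning.chrom_sizes[chrom]:
            raise ValueError(f"bad bedGraph interval {(chrom, start, end)!r}")
        density = value / (end - start)
        first, last = start // bs, (end - 1) // bs
        for b in range(first, last + 1):
            lo, hi = max(start, b * bs), min(end, (b + 1) * bs)
            data[chrom][b] += density * (hi - lo)
    return TagTrack(mark=mark, binning=binning, data=data)


def read_bed_positions(path) -> List[Tuple[str, int]]:
    """Tag positions from a BED file; each interval's midpoint is the tag."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    return [(c, int((s + e) // 2)) for c, s, e in df.itertuples(index=False)]


def read_bed_intervals(path) -> List[Tuple[str, int, int]]:
    """Plain genomic intervals from the first three BED columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    return [(c, int(s), int(e)) for c, s, e in df.itertuples(index=False)]


def write_bedgraph(track: _BinnedTrack, path) -> None:
    """Serialize a tag or score track as bedGraph (one record per bin)."""
    bs = track.binning.bin_size
    with open(path, "w") as fh:
        for chrom in track.binning.chroms:
            size = track.binning.chrom_sizes[chrom]
            for b, v in enumerate(track.data[chrom]):
                fh.write(f"{chrom}\t{b * bs}\t{min((b + 1) * bs, size)}\t{v:.6g}\n")


def write_regions_bed(
    records: Iterable[Tuple[str, int, int, str]], path, scores: Sequence = None
) -> None:
    """Write (chrom, start_bp, end_bp, name) records as 6-column BED."""
    records = list(records)
    if scores is None:
        scores = [0] * len(records)
    with open(path, "w") as fh:
        for (chrom, start, end, name), score in zip(records, scores):
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t+\n")
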