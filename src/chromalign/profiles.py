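"""Score-track construction from raw ChIP-seq tag counts.

Raw per-modification tag counts are laid on a fixed non-overlapping genomic
binning (200 bp by default), smoothed with a truncated Gaussian kernel to
suppress spurious single-bin tags, and transformed to scores in (0, 1) with
a logistic curve anchored on the genome-wide median tag count of each
modification: a bin at the median scores 0.1, a bin at twice the median
scores ~0.5.  The median anchoring makes the score scale comparable across
modifications with very different sequencing depths, and the saturating
transform damps differences among already-high tag counts so that the
downstream alignment is driven by pattern shape rather than raw coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np

__all__ = [
    "GenomeBinning",
    "TagTrack",
    "ScoreTrack",
    "SmoothingParams",
    "TransformParams",
    "bin_counts",
    "genomic_median",
    "smooth_track",
    "transform_track",
    "transform_value",
    "gaussian_kernel",
]


@dataclass(frozen=True)
class GenomeBinning:
    """Non-overlapping 0-based half-open bins of fixed width over a genome.

    The last bin of each chromosome may be truncated at the chromosome end.
    """

    chrom_sizes: Mapping[str, int]
    bin_size: int = 200

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
        # freeze to a plain dict so equality/hash semantics are predictable
        object.__setattr__(self, "chrom_sizes", dict(self.chrom_sizes))

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)  # ceil division

    def bin_of(self, pos: int) -> int:
        return pos // self.bin_size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeBinning):
            return NotImplemented
        return self.bin_size == other.bin_size and dict(self.chrom_sizes) == dict(
            other.chrom_sizes
        )

    def __hash__(self) -> int:
        return hash((self.bin_size, tuple(sorted(self.chrom_sizes.items()))))


@dataclass
class _BinnedTrack:
    """Per-chromosome arrays of per-bin values for one modification."""

    mark: str
    binning: GenomeBinning
    data: Dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            expected = self.binning.n_bins(chrom)
            if arr.shape != (expected,):
                raise ValueError(
                    f"{self.mark}/{chrom}: expected {expected} bins, got {arr.shape}"
                )
            self.data[chrom] = arr

    def values(self) -> np.ndarray:
        """All bin values genome-wide, concatenated in binning chromosome order."""
        return np.concatenate([self.data[c] for c in self.binning.chroms])


class TagTrack(_BinnedTrack):
    """Tag counts per bin (integers before smoothing, non-negative reals after)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        for chrom, arr in self.data.items():
            if np.any(arr < 0):
                raise ValueError(f"{self.mark}/{chrom}: negative tag counts")


class ScoreTrack(_BinnedTrack):
    """Transformed scores per bin, each in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        for chrom, arr in self.data.items():
            if np.any((arr < 0.0) | (arr > 1.0)):
                raise ValueError(f"{self.mark}/{chrom}: scores outside [0, 1]")


@dataclass(frozen=True)
class SmoothingParams:
    """Gaussian smoothing kernel parameters (units of bins)."""

    variance: float = 1.0
    truncation_radius: int = 4

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("smoothing variance must be positive")
        if self.truncation_radius < 1:
            raise ValueError("truncation radius must be >= 1")


@dataclass(frozen=True)
class TransformParams:
    """Parameters of the logistic score transform.

    ``a`` and ``b`` fix the shape so that the genomic median maps to 0.1 and
    twice the median to ~0.5; ``median`` is the per-modification genomic
    median of the smoothed track (computed from the track when omitted).
    """

    a: float = 9.0
    b: float = 2.19
    median: float | None = None

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("transform constants must be positive")
        if self.median is not None and self.median <= 0:
            raise ValueError("median must be positive when given")


def gaussian_kernel(params: SmoothingParams = SmoothingParams()) -> np.ndarray:
    """Truncated, renormalized discrete Gaussian kernel (sums to 1)."""
    r = params.truncation_radius
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-0.5 * x * x / params.variance)
    return k / k.sum()


def bin_counts(
    tag_positions: Iterable[Tuple[str, int]],
    binning: GenomeBinning,
    mark: str = "",
) -> TagTrack:
    """Count tags per bin; each tag position increments exactly one bin.

    Raises ``ValueError`` identifying the first record outside its
    chromosome bounds (or on an unknown chromosome).
    """
    per_chrom: Dict[str, list] = {c: [] for c in binning.chroms}
    for record in tag_positions:
        chrom, pos = record
        if chrom not in binning.chrom_sizes:
            raise ValueError(f"tag on unknown chromosome: {record!r}")
        if not (0 <= pos < binning.chrom_sizes[chrom]):
            raise ValueError(f"tag position out of chromosome bounds: {record!r}")
        per_chrom[chrom].append(pos // binning.bin_size)
    data = {}
    for chrom in binning.chroms:
        n = binning.n_bins(chrom)
        idx = np.asarray(per_chrom[chrom], dtype=np.intp)
        data[chrom] = np.bincount(idx, minlength=n).astype(float)
    return TagTrack(mark=mark, binning=binning, data=data)


def genomic_median(track: _BinnedTrack) -> float:
    """Lower median of all genome-wide bin values.

    The lower-median convention (element at index ``(n-1)//2`` of the sorted
    values) is deterministic and always returns an actual bin value.
    """
    values = track.values()
    if values.size == 0:
        raise ValueError("cannot take the median of an empty track")
    return float(np.partition(values, (values.size - 1) // 2)[(values.size - 1) // 2])


def smooth_track(track: TagTrack, params: SmoothingParams = SmoothingParams()) -> TagTrack:
    """Convolve each chromosome with the truncated Gaussian kernel.

    Chromosome ends are zero-padded; the kernel is renormalized to sum 1 so
    interior mass is conserved.
    """
    kernel = gaussian_kernel(params)
    data = {
        chrom: np.convolve(arr, kernel, mode="same")
        for chrom, arr in track.data.items()
    }
    return TagTrack(mark=track.mark, binning=track.binning, data=data)


def _resolve_median(track: _BinnedTrack, params: TransformParams) -> float:
    if params.median is not None:
        return params.median
    m = genomic_median(track)
    if m <= 0:
        positive = track.values()
        positive = positive[positive > 0]
        if positive.size == 0:
            raise ValueError(
                f"track {track.mark!r} is identically zero; score transform undefined"
            )
        m = float(positive.min())
        warnings.warn(
            f"track {track.mark!r}: genomic median is 0; using smallest positive "
            f"bin value {m!r} as the normalization anchor",
            stacklevel=3,
        )
    return m


def transform_value(t, params: TransformParams, median: float | None = None):
    """Logistic score transform sc(t) = 1 / (1 + a * exp(-b * (t/m - 1))).

    Strictly increasing in ``t`` with range (0, 1); sc(m) = 1/(1+a) which is
    exactly 0.1 at the default a = 9, and sc(2m) ~= 0.5 at the default
    b = 2.19 (~ln 9).
    """
    m = median if median is not None else params.median
    if m is None or m <= 0:
        raise ValueError("a positive median is required to evaluate the transform")
    t = np.asarray(t, dtype=float)
    out = 1.0 / (1.0 + params.a * np.exp(-params.b * (t / m - 1.0)))
    return float(out) if out.ndim == 0 else out


def transform_track(
    track: TagTrack, params: TransformParams = TransformParams()
) -> ScoreTrack:
    """Transform a (smoothed) tag track to a score track in [0, 1].

    The genomic median is taken from ``params`` if set, otherwise computed
    from ``track`` itself — so the same smoothed track should be passed that
    the median is meant to describe.
    """
    m = _resolve_median(track, params)
    data = {
        chrom: transform_value(arr, params, median=m)
        for chrom, arr in track.data.items()
    }
    return ScoreTrack(mark=track.mark, binning=track.binning, data=data)
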