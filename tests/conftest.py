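"""Shared fixtures: tiny genomes, toy tracks, and random profile matrices."""

import numpy as np
import pytest

from chromalign import GenomeBinning, ScoreTrack, TagTrack


@pytest.fixture
def small_binning():
    return GenomeBinning({"chr1": 4000, "chr2": 2000}, bin_size=200)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_score_track(mark, binning, arrays):
    """Build a ScoreTrack from explicit per-chromosome arrays (padded with 0)."""
    data = {}
    for chrom in binning.chroms:
        n = binning.n_bins(chrom)
        arr = np.zeros(n)
        if chrom in arrays:
            vals = np.asarray(arrays[chrom], dtype=float)
            arr[: len(vals)] = vals
        data[chrom] = arr
    return ScoreTrack(mark=mark, binning=binning, data=data)


def make_tag_track(mark, binning, arrays):
    data = {}
    for chrom in binning.chroms:
        n = binning.n_bins(chrom)
        arr = np.zeros(n)
        if chrom in arrays:
            vals = np.asarray(arrays[chrom], dtype=float)
            arr[: len(vals)] = vals
        data[chrom] = arr
    return TagTrack(mark=mark, binning=binning, data=data)


def noise_profile(rng, n_marks=6, n_bins=25):
    """A profile matrix resembling a called region with no planted signature:

    low background scores everywhere plus a few random strongly marked bins.
    """
    base = rng.uniform(0.05, 0.2, size=(n_marks, n_bins))
    k = int(rng.integers(3, 8))
    cols = rng.choice(n_bins, size=k, replace=False)
    marks = rng.integers(0, n_marks, size=k)
    base[marks, cols] = rng.uniform(0.5, 1.0, size=k)
    return base
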