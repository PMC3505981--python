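# Methods

This note records the model implemented by `chromalign`, the reasoning
behind every tunable default, what the synthetic generator does and does
not emulate, and the numerical choices a maintainer needs to know.

## Score transformation

Tag counts are accumulated in 200 bp non-overlapping, 0-based half-open
bins (the last bin of a chromosome may be truncated). Each modification is
smoothed independently per chromosome by discrete convolution with a
Gaussian kernel of variance 1 bin², truncated at ±4 bins and renormalized
to sum 1; chromosome ends are zero-padded. Smoothing precedes the median
computation, so the transform anchor describes the same signal it rescales.

The transform is logistic in the median-normalized count,
`sc(t) = 1 / (1 + A exp(-B (t/m - 1)))` with A = 9 and B = 2.19 (≈ ln 9).
Two anchors pin it down: a bin at the genomic median scores exactly
1/(1+A) = 0.1, and a bin at twice the median scores ≈ 0.498. The logistic
form is the minimal monotone (0, 1) curve satisfying both; it is isolated
behind `TransformParams` so an alternative satisfying the same anchors can
be swapped in. The two purposes of the transform: background bins (1–2
tags) are pushed toward 0 so they cannot accumulate alignment score, and
differences among already-high counts (100 vs 150 tags) are damped so
alignment responds to pattern shape, not depth.

Conventions: the *lower* median (index ⌊(n−1)/2⌋ of the sorted values) —
deterministic, and always an actual bin value, which the acceptance script
exploits. If more than half the genome is empty (median 0), the smallest
positive bin value is used as the anchor with a warning; an identically
zero track is an error.

## Region calling and grouping

A bin is *high* when any modification scores ≥ 0.5 — the transformed value
of twice the genomic median, the only printed score anchor that reads as an
enrichment floor; it is configurable. Maximal runs of high bins become
regions regardless of which mark is high in each bin (so spatially shifted
marks merge), regions < 1 kb apart merge, and no size limit is applied.
Regions never span chromosomes.

Pre-grouping bounds the O(n²) alignment stage and keeps scoring regimes
comparable: regions are keyed by (i) presence of each user-chosen key mark
(presence = any bin ≥ the same 0.5 threshold — one fewer free parameter)
and (ii) size class: small ≤ 5 kb, 5 kb < medium < 10 kb, large ≥ 10 kb.

## Local profile alignment

A region's profile matrix is a string of per-bin column vectors in [0,1]^M.
The column score between u and v is

    s = cos(min(gamma * theta, pi)),    theta = angle(u, v)
    w = nbar / (nbar + beta),           nbar = min(||u||, ||v||) / sqrt(M)
    score = s * w

`gamma` (≥ 1) amplifies angles so that moderately different mark
combinations score negative — 2 for small-region comparisons, 1.5 for
medium/large, where the longer matched stretches make per-column stringency
less critical. `beta` = 0.3 shrinks the weight of low-coverage columns so
background cannot build score even when directions agree by chance. The
clamp at π keeps the score monotone decreasing in the angle. Columns with
norm below `epsilon` = 1e-9 score 0 and cost no gap.

Gap penalties are `delta * ||u|| / sqrt(M)` — proportional to the skipped
column's norm (skipping strong signal is expensive, skipping background is
nearly free), normalized by sqrt(M) so `delta` is comparable across runs
with different mark counts. `delta` is 0.5 for small and 0.3 for
medium/large comparisons, respecting the small-stricter ordering. Because
empty bins are free to match (score 0) or skip (cost 0), one signature can
span alternating conserved and variant segments; the flip side is that two
motifs joined only by empty bins belong to a single alignment island.

The recurrence is `H(i,j) = max(0, diag + score, up - gap, left - gap)`
with zero borders; the result is the maximum cell traced back to the first
zero. Determinism: ties break diagonal > up > left, and the first maximal
cell in row-major order wins. Every pair is aligned in both orientations
(signatures recur on either strand); opposite-orientation coordinates are
mapped back to the forward frame, and the same orientation wins exact ties.
The inner fill loop is numba-compiled; everything else is vectorized numpy.

## Island-method significance

For each group, up to `null_n_pairs` = 1000 distinct pairs are sampled
without replacement (seeded). Alignment *islands* — maximal sets of
positive cells sharing traceback ancestry — are collected from both
orientations; island peaks above a threshold T are modelled as exponential
with rate λ, fitted by maximum likelihood `λ = 1/mean(S_i − T)`, with
density `K = (n/area) e^{λT}` per unit of L1·L2 search area (the area is
counted once per pair; the two-orientation search is absorbed into K,
matching its downstream use on two-orientation best scores). The best
score of an observed pair then has

    P = 1 − exp(−K · L1 · L2 · e^{−λS})

Pairs with best score ≤ 0 receive P = 1. Altschul-style edge-length
corrections are omitted as second-order at these region sizes.

Two empirical facts, measured on this package's own simulations, set the
calibration policy:

* **The null sample is contaminated.** At realistic desk scale a random
  sample of pairs contains a substantial minority of genuinely related
  pairs, and one related pair floods the pool with dozens of high islands
  (measured: 15% of pairs contributed 51% of pooled islands). The unit of
  decontamination is therefore the *pair*: pairs whose best island exceeds
  Q3 + 3·IQR of the per-pair maxima are discarded wholesale
  (`null_outlier_fence`). On clean data this removes ≲ 1% of pairs.
* **The island-height bulk is not exponential.** Most islands are one- or
  two-cell fragments; fitting λ from a low threshold misstates the far
  tail badly (measured λ ≈ 1.0 from the pooled-peak q75 vs ≈ 2.9 implied
  by the distribution of per-pair maxima, i.e. P-values off by an order of
  magnitude). T is therefore placed at the *median of the positive
  per-pair maximum island scores* (`island_threshold_quantile` = 0.5) —
  the scale at which P-values are actually evaluated, and robust to
  residual contamination. An absolute T can be supplied instead.

With this policy the empirical fraction of truly unrelated pairs at
P ≤ 0.05 is 0.03–0.05 across seeds (the test suite asserts the band
[0.02, 0.10]). Fitting requires ≥ `min_null_islands` = 50 islands; groups
that cannot be calibrated (too few regions or no positive islands) are
reported as skipped rather than aborting the run.

## Clustering and consensus

Pairwise P-values form a symmetric distance matrix (diagonal 0; missing
pairs = 1). Average linkage (UPGMA) is used: reading branch lengths as
approximate P-values among sub-groups fits the average of pairwise
distances better than the single/complete-linkage extremes. The tree is cut
so that clusters are maximal subtrees with all internal merge heights
strictly below `p_threshold` = 0.05; groups smaller than
`min_cluster_size` = 3 are left unclustered — fewer than three instances
is not a *recurrent* signature.

A cluster's consensus lives in the frame of its medoid (member with the
smallest summed P-value distance; ties break on matrix order). Each other
member's columns are projected onto the medoid through the diagonal steps
of its stored pairwise alignment (orientation already normalized);
the consensus is the per-column, per-mark mean over observed values, gap
columns contributing nothing. A member's footprint is the union of its
aligned sub-intervals with its co-members; the medoid's footprint defines
the consensus length.

## Enrichment

FE = f_p / f_g, where f_p is the fraction of cluster *instances* (not base
pairs — matching the fraction-of-patterns reading) overlapping the merged
feature intervals by ≥ 1 bp, and f_g is the merged feature fraction of the
genome. Enrichment is strict: FE > 3. Intervals are merged per chromosome
and queried by binary search.

## Synthetic data

The generator emulates exactly what the pipeline consumes: integer Poisson
tag counts per bin per mark (background rate 5 — low enough to be sparse,
high enough that the 2×-median calling threshold is ~4σ above smoothed
background, so background false calls are rare but present), with planted
instances where the mean is raised to `rate · (1 + amplitude · shape)`;
the median of a Poisson track equals its rate, so amplitudes read as
multiples of the background median. Shapes cover the morphology classes
the method claims to tell apart: mono-modal domes, bi-modal twin bumps,
flat blocks, and shifted bumps; instances can be planted reversed.
Placement is non-overlapping with a 20-bin margin so ground truth is
unambiguous, and everything derives from one seed.

The reference design (`example_spec`) plants three families of 20 on a
10 Mb, six-mark genome plus 20 random decoys: a mono-modal
H3K4me3+H3K27ac dome; a bi-modal signature of the *same* two marks with
the constituents shifted to opposite ends (so the two families differ only
in shape — and in the column directions that shape induces); and an
asymmetric gene-body-like pattern (punctate H3K4me1 at one end over an
H3K36me3 block), half of them reversed. Amplitudes are 5–6× the background
median and lengths 20 bins, within the regime where ≥ 90% of instances are
called.

What the generator does **not** emulate: mappability and fragment-length
artifacts, input/control structure, replicate variation, copy-number
bias, or correlated backgrounds between marks. Passing tests therefore
demonstrate the statistical machinery — calling, alignment, calibration,
clustering — under idealized count noise, not robustness to real ChIP-seq
artifacts.

Evaluation convention: recovery is scored by adjusted Rand index over the
regions overlapping planted *family* instances (predicted label = cluster
id, unclustered = singleton). Decoys and background-noise regions act as
confounders but carry no truth class: randomly drawn decoys genuinely do
share mark combinations at times, and the algorithm is right to group
them; forcing each decoy to be its own class would penalize correct
behaviour.

## Numerical choices and degenerate inputs

* Bin arithmetic is exact integer; bp only at I/O boundaries (BED/bedGraph
  0-based half-open).
* The smoothing kernel is renormalized after truncation, so constant runs
  are exactly invariant in their interior.
* DP tie-breaks (diagonal > up > left; first maximum row-major) make paths
  and all downstream outputs reproducible; rerunning with the same seed
  yields byte-identical files (asserted in tests).
* Empty matrices or all-background regions align with score 0 and P = 1.
* All randomness descends from `RunConfig.seed` through per-group seed
  sequences keyed by sorted group order.

## Known limitations

* P-values for very short regions (1–3 bins) are only roughly calibrated:
  the Gumbel approximation is asymptotic in the search area, and tiny
  areas make modest scores look significant. The minimum cluster size
  absorbs most of the effect; a floor on region length would be a
  reasonable extension.
* The null is fitted per group; groups with fewer than ~15 regions rarely
  yield the 50 islands required and are skipped.
* λ is fitted from sampled pairs of the *observed* regions, so systematic
  genome-wide correlations between marks would shift the null rather than
  be detected as signal.
* `cluster` (CLI) resumes from the pairwise P-value table and reproduces
  memberships; consensus profiles require the alignment paths and are
  produced by `run-all`.
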