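# Methods

This note documents the statistical model behind `topotest`, the choices
made where the procedure admits more than one reasonable reading, the
synthetic data used to exercise it, and the package's known limits.

## Topographical correlation

Two pattern volumes on a shared grid are flattened plane-by-plane (third
array axis slowest, then rows, then columns) over the voxels that are
in-mask **and nonzero in both** volumes, and compared by Pearson's r. The
intersection rule guarantees that every paired entry is a meaningful weight
in both patterns; voxels supported by only one pattern are dropped, not
zero-filled. Any consistent flattening order yields the same r — the order
is pinned only so voxel indices are reproducible. No resampling is
performed: inputs must already share a grid (enforced by shape equality),
and voxel spacing is carried as metadata only.

## Windowed local Moran's I

Spatial autocorrelation of a volume is summarized by the mask-average of a
windowed local Moran statistic. For in-mask voxel *i* of a 2D slice:

    I_i = (x_i − x̄)/s² · (1/|N_i|) Σ_{j∈N_i} (x_j − x̄)

Choices that the classical literature leaves open, pinned here:

- **Per-slice moments.** x̄ and s² (population variance) are computed over
  each slice's in-mask voxels, matching the slice-wise decomposition of the
  computation. Whole-brain moments would mix slices with different means
  into every local value.
- **Row-standardized binary weights.** Each in-window, in-mask neighbour
  (center excluded) gets weight 1/|N_i|. Row standardization keeps every
  local value on a common scale so the mask-average is a bounded index
  comparable across mask geometries and window sizes; it also makes the
  mask-average equal the classical weight-matrix form of Moran's I
  (verified against a brute-force double loop to 1e-10 in the tests).
- **Truncation.** Windows are clipped at slice borders and mask boundaries;
  a voxel with no neighbours gets NaN and is excluded from the average.
  Zero-variance slices are skipped (logged) rather than poisoning the
  volume average.
- **2D only.** The statistic is computed within slices along a configurable
  axis (default the third). Autocorrelation along the slice axis is
  invisible to it — the price of speed on wide windows — so surrogates
  matched with this index can slightly *under*-represent true 3D
  autocorrelation, making the adjusted p-values anti-conservative at the
  margin. This is an inherent limit of the index, not of the
  implementation.

The default window is W = 51, the value selected by the calibration study
at full scale; any odd W ≥ 3 can be configured. Under white noise the index
is ≈ −1/(n−1) per slice, indistinguishable from 0 at realistic mask sizes.

## Phantom surrogates and Moran matching

Surrogate volumes emulate region-structured brain maps: a parcellation of
K ≈ 116 contiguous regions; one Normal(0, 1) draw per region; independent
Normal(0, 0.05²) voxel noise; box smoothing with odd kernels (candidate
list 3, 7, 11, 15, 19, 23). Instead of shipping an atlas, the package
builds a seeded Voronoi parcellation inside an ellipsoidal mask (convex
cells ⇒ contiguous regions); a real parcellation NIfTI can be substituted
anywhere.

Matching a surrogate ensemble to an observed pattern works on the mean:
`n_probe` pilot phantoms (default 20) are smoothed at every candidate
kernel, and the kernel whose mean global Moran's I is closest to the
pattern's observed value is fixed for all simulated pairs. Each member of a
pair is matched separately to its own pattern. If the target exceeds every
candidate's reach, the largest kernel is used and a warning notes that the
resulting p-value errs anti-conservative. Note that a *single* volume's
global Moran's I scatters substantially around the ensemble mean (sd ≈ 0.04
at W=27 on the 40×48×40 grid), and the observed pattern is itself one
realization — matching is approximate by nature.

Smoothing is applied to the full zero-padded array before the mask is
re-imposed, so background bleeds into the mask edge exactly as it does when
real zero-padded pattern volumes are smoothed. Box smoothing truncates at
volume borders (mean over available voxels); kernel 1 is the identity.

**Null degrees of freedom.** Because both members of a surrogate pair share
the parcellation, the unsmoothed null correlation is effectively a
size-weighted correlation of K region draws: E[r²] ≈ 1/(K−1), orders of
magnitude larger than the voxel-count value 1/(m−1). The tests assert this
against an independent region-level Monte-Carlo oracle. This is exactly why
naive voxel-count p-values are wrong for region-structured maps.

## Empirical p-value

p = (number of null r² strictly exceeding the observed r²) / N. The
convention is plain k/N, not (k+1)/(N+1): 459 of 1,000 exceedances gives
p = 0.459 exactly. Ties count as not exceeding (measure-zero in practice).
An observed value above every null value is reported as "p < 1/N" rather
than p = 0. Bonferroni handling is the threshold form (compare p to α/m;
α = 0.05, m = 3 → 0.0167, m = 6 → 0.00833), with min(1, m·p) also reported.

All randomness in the pipeline flows from one integer seed through
`numpy.random.SeedSequence` spawning; a (config, seed) pair reproduces any
null distribution bit-for-bit. The kernel→member assignment inside the pair
simulation is canonicalized (smaller kernel to the first draw), which makes
comparing A-to-B and B-to-A identical under a shared seed.

## Window-size calibration

The calibration study regresses, for each candidate window W, the absolute
topographical correlation of smoothed phantom pairs on the pairs'
autocorrelation:

    |r| = MI·b1 + Z·B

with one observation per (pair, kernel), MI = the pair mean of the two
members' global Moran's I at W, and Z a block of per-pair indicator dummies
(fixed effects; they absorb the intercept and pair-specific baselines). The
fit is ordinary least squares; a single-kernel design is rejected as
singular since MI is then constant within pairs. AIC is the Gaussian form
n·ln(RSS/n) + 2(k+1) — constants dropped, valid for within-run comparison
because the response vector is identical across W. The minimum-AIC window
is selected.

The full-scale design (300 pairs × 6 kernels, 10 windows, 91×109×91 grid)
is the method's reference configuration but needs dozens of CPU-hours; the
package's default configuration is a scaled-down design — 30 pairs, kernels
{1, 7, 15}, windows {3, 15, 27}, 40×48×40 grid, K = 116 — which shows the
same qualitative behaviour in seconds: |r| and Moran's I both rise strictly
with kernel size, b1 > 0 with p < 0.05 at the largest window, and the AIC
minimum sits at the widest window tested. Printed coefficients of any
single run are one stochastic realization, not reference values.

## Regional difference maps

Two patterns derived the same way from two cohorts are subtracted after
z-scoring each over the common mask; the reported difference map is itself
z-scored (display convention). Voxel-wise reliability comes from subject
swapping: pool the cohorts, reassign subjects at random to groups of the
original sizes, re-derive both patterns, and rank the observed per-voxel
difference two-tailed in the permuted differences,

    p = 2·min(#{perm ≥ obs}, #{perm ≤ obs})/n_perm, capped at 1,

so a difference ranked 20th from the top of 1,000 permutations gets
p = 0.04, and the smallest attainable p is 2/n_perm.

Two numerical points matter here:

- **The null ranks unstandardized differences** of standardized patterns.
  Re-scaling every permuted difference map to unit variance would erase the
  amplitude information the test needs — an imbalanced permutation split
  partially reproduces the group structure and then matches the observed
  *shape* at normalized amplitude, driving power to zero (verified
  empirically). The observed map is z-scored only for reporting.
- **Sign alignment.** A principal-axis pattern is defined up to sign; every
  re-derived pattern is flipped, if needed, to correlate positively with
  the pooled-cohort pattern before differencing.

Pattern derivation is a pluggable callable. The shipped default is a
minimal covariance-pattern estimator: log-transform (with an automatic
logged offset if values are non-positive), double centering of the
subjects × voxels matrix, first right singular vector as the voxel-weight
map, deterministic sign convention. It is a deliberately simple stand-in
for the full scaled-subprofile modelling pipeline, adequate for method
validation; substitute the real derivation for substantive use.

## Synthetic cohorts

`generate_cohort` produces scans `baseline + s_i·pattern + ε` with subject
loading s_i ~ Normal(1.0, 0.5²) by default, voxel noise ε ~ Normal(0, 0.25²)
and baseline 50 (arbitrary scanner counts; positive so the log transform is
safe). This is the minimal generative model under which pattern derivation
and group comparison are well-posed. The defaults put first-PC derivation
in its stable regime (planted patterns recovered at |r| > 0.9 with ≥ 8
subjects), mirroring real metabolic-network cohorts where patterns
replicate across samples.

The permutation test's power for a planted group difference depends
strongly on the loading coefficient of variation: the tilt of a permuted
group's principal axis along the effect direction is driven by the
within-group covariance of squared loadings, so narrow loading spreads make
group differences in covariance structure nearly unidentifiable at small n.
The planted-effect validation therefore uses cohorts of 18 and 16 subjects
with loading sd 0.8 (a wide severity spread, as in patient cohorts) and an
effect of +1 region-sd in 3 of 30 regions; under these conditions all three
regions are recovered in essentially every replicate, while null cohorts
reject at the nominal 5% rate.

What the synthetic data does **not** emulate: real scan intensity
distributions, inter-subject anatomical variability, scanner effects,
non-Gaussian physiological noise, and genuinely 3D autocorrelation
structure beyond box smoothing. Passing tests demonstrate the statistical
machinery is calibrated and sensitive under its stated model, not that any
particular real pattern pair is (dis)similar.

## Problem sizes and degenerate inputs

Default test/validation scales are 40×48×40 (calibration study) and
20×24×20 with K = 30 (pipeline-level simulations); production-scale grids
(91×109×91, K = 116, W = 51, 1,000 pairs) are plain configuration changes.
Degenerate inputs fail loudly rather than silently: empty masks, zero
in-slice variance, even windows/kernels, singular regression designs,
identical patterns in the difference map, and degenerate cohort covariance
all raise with a message naming the cause.
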