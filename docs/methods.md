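# Methods

## The generative model

The simulator produces depth-resolved percent-BOLD time courses in four
stages.

**Neuronal drive.** Each stimulus block contributes a boxcar of unit
height over its presentation interval. The sub-second on/off
microstructure of a flickering stimulus is not modelled: it lies below
the 1.3 s analysis grid and is irrelevant to the additivity statistic,
which compares second-scale response shapes.

**Local hemodynamic response.** At depth *y* the drive is convolved with
a double-gamma HRF and scaled by a local amplitude `a_y` (percent BOLD at
the response peak). Two kernels are provided:

| kernel | peak | undershoot | ratio | support | onset lag |
|---|---|---|---|---|---|
| canonical (default) | 6 s | 16 s | 6 | 32 s | 0 s |
| compact (`compact_hrf`) | 6.5 s | 10.4 s | 6 | 13 s | 2.6 s |

The compact kernel's support fits inside a single epoch window
(shortest window: 2.6 + 15.6 s; minimum realized inter-block gap:
13.0 s after jitter), so noise-free simulations are temporally additive
to machine precision — the reference regime for exactness tests. The
canonical kernel is more realistic but its undershoot tail necessarily
overlaps neighboring epochs (see *Known limitations*). An optional
per-depth peak delay models depth-varying hemodynamic timing.

**Draining.** Blood pooling toward the surface is discretized from the
continuous depth integral with source-depth weighting, recursing from
the gray/white border upward:

    H[0] = L[0]
    H[i] = L[i] + Δy · Σ_{j<i} w[j] · H[j],   Δy = 1/n_depths.

Whether the weight belongs to the source or the destination depth is not
determined by the continuous form; the source-depth reading is adopted
(each depth's contribution is attenuated once, where the blood leaves).
With the default profile (`a_y = 0.25 + 0.35·y`, `w = 0.5`) peak
amplitudes rise from ≈1.3% (deep) to ≈3.4% (superficial) for 10.4 s
blocks — the familiar superficial amplification of gradient-echo BOLD.
A useful property of this recursion: when the local response is
pointwise non-decreasing with depth (true of the defaults), pooled peaks
are non-decreasing in depth index; with an arbitrary profile (e.g. zero
local response superficially and small Δy·w) this need not hold.

**Noise and rendering.** Raw signal = 100·(1 + H/100) + polynomial drift
(degree ≤ 4 over normalized run time, raw units) + AR(1) noise
(innovation σ = 0.6 raw units ≈ 0.6% BOLD per voxel, lag-1 r = 0.35;
stationary sd σ/√(1−ar1²)). Voxels within a depth bin share the bin's
response and receive independent noise; their depth-map values are drawn
uniformly inside the bin's interval, so quantile binning recovers the
generating bins exactly. Volumes are sampled at the 2.6 s TR and written
as NIfTI.

**Built-in violations.** Three switches create known additivity
failures: *saturation* compresses the response as x/(1+s·|x|);
*adaptation* decays the drive as exp(−s·t) within each block;
*duration-dependent draining* (`drain_weights_alt`) drains the
long-duration stream with different weights than the short ones — the
case where the pooled response to a compound stimulus differs from the
pooled responses to its parts.

## Study-design defaults

8 runs × 102 volumes at TR 2.6 s (265.2 s). Twelve blocks per run, four
each of 2.6/5.2/10.4 s, in a seeded counterbalanced order; each run opens
with a 15.6 s rest. Half the blocks — stratified within duration — have
their onset delayed by 1.3 s. A nominal 265.2 s run cannot hold twelve
blocks with uniform 15.6 s rests *and* a final 15.6 s post-stimulus
window (that needs 275.6 s), so the inter-block rests are filled from the
remaining budget on the 1.3 s grid (14.3–15.6 s, averaging ≈14.6 s): rest
periods vary around their mean, as in any jittered block design. The
design validates that every block's window (duration + 15.6 s) fits
before the last acquired sample.

## The analysis pipeline

1. **Conditioning**, per run and per voxel, in fixed order: despike →
   percent scaling (100·x/mean − 100, zero temporal mean) → polynomial
   detrend (degree ≤ 4) → linear resampling to 1.3 s (the jitter step, so
   all onsets land on the grid). Spikes are samples whose rolling-median
   residual (window 5) exceeds `z = 5` robust standard deviations
   (1.4826·MAD of the residuals); they are replaced by the mean of the
   nearest clean neighbor on each side. The rolling median tracks smooth
   signal while exposing single-point excursions — a polynomial residual
   would retain the block response and misflag genuine peaks on low-noise
   data. When the MAD collapses to zero (locally flat series) any nonzero
   residual counts as a spike.
2. **Depth sampling**: per ROI, in-mask voxels are split into 5
   equal-count bins of normalized depth (quantile edges computed within
   each ROI; boundary-valued voxels join the deeper bin) and averaged,
   with the per-bin mean depth retained as the trend regressor.
3. **Epoching**: one trial per block over [onset, onset + duration +
   15.6 s); same-duration trials are averaged with a Student-t 95% CI of
   the between-block variability. No per-block baseline re-zeroing is
   applied (runs are already zero-mean from scaling/detrending).
4. **Additivity**: for each of the 70 ordered 4+4 splits, the training
   half's mean short response is shift-and-summed into a long-duration
   prediction and correlated (Pearson, full window) with the test half's
   mean observed response; the median over splits is reported per (ROI,
   bin, condition), alongside the noise ceiling (median split-half r of
   the observed response). Splits with a zero-variance vector are
   excluded with a warning. Pearson r is scale-invariant, so the metric
   tests response *shape*, not amplitude.
5. **Depth trend**: OLS of r on mean bin depth per ROI, pooling
   conditions × bins (and subjects when aggregated); two-sided t-tests on
   slope and intercept with df = n − 2, reported from the data actually
   fit. Verdict: `consistent-with-additivity` iff p(slope) ≥ α (0.05);
   the intercept test describes overall fit quality and never enters the
   verdict. No multiple-testing correction across ROIs. Per-condition
   medians are computed first and only then averaged or pooled.

Numerically perfect trend fits (zero residual, e.g. all correlations
exactly 1 on noise-free data) make the coefficient t-statistics 0/0;
they are special-cased: a coefficient below 1e−8 (relative) gets t = 0,
p = 1, otherwise t = ±∞, p = 0. Zero-variance correlations, empty bins,
degenerate quantiles, off-grid onsets and overflowing windows raise
explicit errors naming the offending voxel/bin/block.

## Validation scenarios

`lamadd.scenarios` pins the conditions used by the package's own
experiments. The *linear* scenario (compact HRF, uniform weights) is
additive by construction: every cross-validated correlation, the noise
ceiling, and the depth-trend slope are exact (1, 1, 0) to ≤1e−9. The
*violation* scenario drains the 10.4 s stream with weight 2.0 instead of
0.5 and adds an HRF peak-delay gradient of 2.6 s across depth. The
gradient is essential: with a depth-uniform HRF shape, every depth's time
course is a scaled copy of the same shape, and since Pearson r ignores
scale, a weight-only violation is provably invisible — shape
heterogeneity across depth is what lets differing drain weights produce
differing *blends* of shapes. Under uniform weights the delay gradient
alone is perfectly linear and harmless (verified by test).

Bin-level noise in these scenarios is AR(1) (σ = 0.15% per bin, r = 0.3)
scaled per depth in proportion to the linear-case signal amplitude,
keeping SNR flat across depth. Without this, the depth-increasing
amplitude profile alone induces a depth trend in correlation (deeper
bins are noisier relative to signal) that has nothing to do with
additivity — a caveat equally relevant to real data, where the noise
ceiling serves as the reference. At these settings the horizontality
test flags the violation in ≳90% of replicates while flagging the
matched linear case at ≈ the nominal 5% rate.

## What the simulator does and does not emulate

It emulates: block timing with jitter, depth-dependent amplitudes with
venous pooling, serially correlated noise with slow drift, percent-scale
units, equal-count depth binning, and session structure (runs, volumes,
TR). It does not emulate: spatial point-spread or voxel covariance,
motion and distortion, physiological (cardiac/respiratory) noise,
between-subject variability in HRF shape, or vascular biophysics beyond
the weighted-pooling recursion (no balloon/oxygen-transport model).
Passing tests therefore show that the *statistics* behave correctly
under their stated assumptions, not that real laminar data satisfy those
assumptions.

## Known limitations

* **Pedestal bias of shift-and-sum on conditioned data.** Percent
  scaling and detrending force each run to zero mean, so epochs sit on a
  negative pedestal (−mean response level). A constant offset common to
  prediction and observation is invisible to Pearson r, but zero-padding
  the source response before shifting turns the pedestal into a staircase
  ramp in the prediction, lowering absolute r — most for the 2.6→10.4
  condition (k = 4), least for 2.6→5.2. The effect is proportional to
  response amplitude at every depth, so it cancels from the depth
  comparison (the question the pipeline answers); absolute correlations
  should be read against the noise ceiling, not against 1.
* **HRF-tail truncation.** With the canonical 32 s kernel, responses
  overlap adjacent epochs and extend past the correlation window; on
  noise-free data this caps cross-validated r around 0.99 rather than 1.
  The compact kernel removes the effect and is used wherever exactness
  is asserted.
* **Trend-test points are not independent.** The OLS pools conditions
  (and subjects) as exchangeable points; correlations sharing data are
  mildly dependent, so the nominal slope p-value is approximate. The
  permutation cross-check bounds the discrepancy on synthetic tables.
* The depth map is consumed, not constructed: cortical segmentation and
  equivolume depth estimation are upstream of this package, as are
  motion/distortion correction and registration.
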