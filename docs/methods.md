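# Methods

This note documents the models and numerical choices behind `capiflow`,
the defaults that matter, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Kymograph velocimetry

A kymograph for a vessel segment is built by resampling each frame's
intensities at unit-spaced arc-length positions along the centreline
polyline (bilinear interpolation; left = upstream), one row per frame.
A cell moving at v µm/s advances v/(p·f) space-pixels per time-pixel
(p: µm/px, f: fps), so its streak is declined θ = arctan(p·f/v) from the
horizontal axis and

    v = p · f / tan θ.

θ is estimated from the directionality of the kymograph:

1. mean subtraction and a separable Hann window (suppresses FFT edge
   leakage);
2. 2-D FFT power spectrum, with frequencies expressed in cycles/pixel on
   both axes so non-square kymographs do not distort angles;
3. power binned by the polar angle of the frequency vector, rotated by
   90° (a line structure at orientation θ concentrates spectral energy
   along θ + 90°); the DC term and the three lowest frequency rings are
   excluded as illumination/vignetting energy;
4. a natural cubic smoothing spline (smoothing parameter by generalised
   cross-validation) fitted to the histogram after circular padding with
   period 180°, evaluated on a 0.1° grid restricted to
   [θ_min, 180° − θ_min]; the argmax is θ*, ties break to the smallest
   angle.

θ* is folded into (0°, 90°] before conversion (streak direction modulo
180° carries no sign; speed is a magnitude).  θ* = 90° means vertical
streaks — stationary cells — and is reported as speed 0 with a
`stationary` flag.  A histogram whose maximum is below twice its median
(evaluated on a 2° aggregation, so the verdict does not depend on bin
resolution) carries no oriented structure and yields a `low_structure`
flag instead of a speed.

Defaults and why:

* **n_bins = 360 (0.5° bins).**  At shallow declinations tan θ changes
  quickly: a 2° bin at θ ≈ 4° spans speeds 2700–4100 µm/s.  With 2° bins
  the spline peak quantises near the bin centre and biases speeds of
  ~4000 µm/s low by 10–20%; with 0.5° bins the recovery error of the
  full pipeline on synthetic movies is ≤ ~2% (median) across
  500–4000 µm/s.  The value is configurable.
* **θ_min = 1°.**  tan θ → 0 blow-up guard; at the default calibration
  this caps measurable speed at ≈ 16.4 mm/s, well above retinal
  capillary speeds.  Angles at or below the floor raise an error
  ("speed above measurable range").
* **Windows: floor(window_s · f) frames**, consecutive, non-overlapping,
  final partial window dropped, numbered from 1; a whole-series
  measurement is appended with window index 0.  Flooring (174 frames for
  3 s at 58.25 fps) fits ten windows into a 30-s acquisition, the T1–T10
  layout used in practice; rounding up would fit only nine.
* An optional exclusion band around 90° (off by default) lets the peak
  search ignore stationary-streak artefacts when they are known to
  contaminate a segment.

Limits: the method reports one dominant speed per window (no per-cell
tracking, no flow-direction sign).  Very fast motion undersamples the
streak (many pixels per frame step), which both thins the spectral ridge
and aliases part of its energy; the per-window estimate then becomes
noisier — visible as occasional ±15% outliers at 4000 µm/s in the
recovery tests, while the median stays within a few percent.

## Spot detection and counting

Frames of the cell channel are filtered with a negated, scale-normalised
Laplacian of Gaussian with σ = (d/p)/(2√2) for a target blob diameter
d = 6.5 µm (the diameter of a rat RBC): at that σ the response of a
matching Gaussian blob is maximal at its centre, and larger structures
respond more weakly.  The sampled-Gaussian derivative kernel does not
sum exactly to zero at the small σ this implies (≈ 0.47 px at
4.93 µm/px), so the kernel's constant response is subtracted; flat
regions map exactly to zero.  A warning is emitted below σ = 0.5 px.

Candidates are strict local maxima whose *local prominence* — the
filtered value minus the minimum filtered value within a blob-sized
neighbourhood — reaches a threshold, and whose mean raw intensity in a
disc of radius d/2 reaches a second threshold.  The two thresholds are
the deterministic counterpart of interactive spot selection on the first
frame: they are chosen once (a helper prints the detection count over a
threshold grid) and applied unchanged to every frame.  Raising the
prominence threshold can only remove detections.  Maxima closer than d/2
are merged into the brighter one.

Counts are taken inside a vessel mask (centrelines dilated to their
known or configured diameter, default 8 µm) per frame; the moving
average uses a centred window of round(0.5 s · f) frames with shrinking
edges.  Count maps accumulate detection centres pixel-wise over a time
interval; they are exactly additive over a partition of the interval and
their total equals the number of detections.

## Vessel diametry

Diameter is the FWHM of the intensity profile along a perpendicular line
probe, sampled at 0.25 px spacing with bilinear interpolation.
Background is the mean of the outer 10% of samples at each end; the peak
is the maximum of a 3-sample moving mean (noise guard) and must be
interior; half level = background + (peak − background)/2; crossings are
located by linear interpolation walking outward from the peak.  Profiles
without a crossing on both sides are flagged and skipped.  The rule is
invariant to affine intensity transforms.  In vivo series are measured
on every 100th frame of a 30-s span (per-frame rows plus a mean row
marked window −1, since it is not stated whether per-frame or averaged
values are the right summary); histology mode measures one projection
image.  Optical blur inflates the FWHM of a tube profile, which is why
in vivo diameters systematically exceed histology diameters; the ratio
depends on the data and is not asserted anywhere.

## Registration and projections

Frames are registered to the first frame by translation only, estimated
on the plasma channel by phase correlation with local upsampled
refinement (default 1/20 px).  Inputs are mean-subtracted and
Hann-windowed before correlation: without this the plain FFT
cross-correlation peak is biased toward zero shift by the DC level and
by circular wrap-around of non-periodic content.  The same shift is
removed from every channel (linear interpolation by default, cubic
available; border fill is the channel median to avoid spurious kymograph
edges).  Whole-pixel shifts are recovered and undone exactly; for
sub-pixel shifts the estimate is accurate to well under 0.25 px at
moderate SNR, while pixel-level round-trip fidelity is limited by
interpolation of sharp vessel edges (a few percent of dynamic range),
not by the shift estimate.  Registration of a single straight vessel is
ill-posed along the vessel axis; the network templates used for
validation contain bends and branches, as real fields do.

Temporal projections (std/mean/max) operate on frame windows selected by
start time; the standard-deviation projection is the canonical
visualisation of perfused vessels (moving cells raise temporal variance
along their track).

## Statistics

Speeds are log-transformed; diameters use a Box-Cox transform with
λ = −0.3 (computed via expm1/log1p to remain accurate at small |λ|;
strictly increasing and exactly invertible).  Models are fitted by REML
with statsmodels' MixedLM:

* speed ~ layer + vessel type, random intercept per rat;
* diameter ~ method + layer + vessel type, vessel type nested in rat as
  variance components.

A residual Shapiro–Wilk p-value is recorded as an assumption check.
Singular fits (a variance component collapsing to zero) are flagged,
never hidden.  Model selection among candidate fixed-effect sets uses
AIC under ML (degenerate fits are skipped), with the winner refitted by
REML.

Estimated marginal means per layer average the vessel-type cell
predictions with equal weight per cell on the transformed scale
(unbalanced cell counts do not tilt the mean; empty cells are dropped
from the grid with a warning); standard errors come from the
fixed-effect covariance by the delta method.  Back-transformed point
estimates apply the exact inverse transform with no smearing
correction — a transparent choice; the back-transformed value estimates
the transformed-scale mean's inverse image, not the arithmetic mean.
The layer comparison is one-tailed SL > DL by default (configurable),
using a normal reference for the Wald statistic; with the residual
degrees of freedom of realistic designs (~180) the normal and t
intervals are indistinguishable, and simulated 95% CI coverage of the
layer effect is ~94% over 500 replicates.

Repeated-measures correlation fits a common slope with per-subject
intercepts; r_rm carries the slope's sign and the magnitude
√(SS_x/(SS_x + SS_err)), identically the Pearson correlation of
within-subject-centred x and y; df = N_obs − N_subjects − 1, p from the
t distribution.  It is invariant to adding any subject-specific constant
to either variable.

## Synthetic data

The generator renders what the analysis assumes: polyline vessels with a
Gaussian-blurred top-hat cross-section of known diameter (the analytic
erf profile, so diameter ground truth is exact and sub-pixel); RBC-like
spots as pixel-integrated Gaussians of fixed physical FWHM (default
6.5 µm) advected along the centreline; sinusoidal speed modulation
v(t) = v̄(1 + a·sin 2πt/T) with closed-form arc-length integral, so
per-window true mean speeds are exact; whole-frame translational jitter
applied analytically (the scene is translated before rendering, making
jittered frames exact resamplings of the clean scene); Poisson shot
noise on the scaled signal followed by Gaussian read noise.  Spots
recirculate (respawn at the path origin on exit) at near-equal arc
spacing with a random phase and ±30% per-spot perturbation, so the count
implied by the spawn rate is stationary and the mean spacing is also the
approximate minimum spacing.  Random draws use independent, purpose-keyed
streams (spot layout, jitter, noise), so enabling noise or jitter does
not change the underlying scene for a given seed.

Default calibrations mirror the two acquisition modes of the targeted
protocol: 4.93 µm/px at 58.25 fps (two-channel speed series) and
1.23 µm/px at 15.23 fps (single-channel diameter series).  Default
intensities (background 10, plasma amplitude 60, spot amplitude 120,
Gaussian read noise SD 2, Poisson scale 1) give a peak-pixel spot SNR of
≈ 13, comfortably above the SNR ≥ 5 regime in which the recovery
properties are asserted; no SNR figures are published for the original
movies, so the choice is justified by the worked example succeeding with
a wide margin rather than by matching a measured value.

What the generator does **not** emulate: deformable or non-spherical
cells, axial (z) structure and out-of-focus layers, haemodynamic
partitioning at bifurcations, photobleaching, or non-rigid eye motion.
Passing tests therefore demonstrate that the algorithms recover truth
under the stated image-formation model, not that they are robust to
every artefact of in vivo data.

## Problem sizes used in validation

Speed-recovery checks use single-vessel movies of 48×256 px, 9.1 s
(530 frames), ten seeds per speed at 500/1000/2000/4000 µm/s, analysed
in 3-s windows.  Counting checks use 2-s movies at one spot per
≥ 20 µm of vessel.  Mixed-model checks simulate the realistic design
size — 8 rats × 2 layers × 4 vessel types × 3 vessels — with 20 seeds
for the marginal-mean ratio and 100 replicates for confidence-interval
coverage (the 100-replicate count is itself binomial with SD ≈ 2.4
around the ~94–95% true coverage).

## Known limitations

* One dominant speed per kymograph window; mixtures (e.g. a stationary
  cell plus moving cells) resolve to whichever structure dominates the
  spectrum unless the stationary band is excluded.
* Speeds approaching p·f/tan(θ_min) (≈ 16 mm/s at default calibration)
  are rejected rather than estimated.
* Spot detection at 4.93 µm/px operates below Nyquist for 6.5 µm cells
  (σ ≈ 0.47 px); it works well for separated spots but two cells closer
  than one cell diameter merge.
* Absolute haematocrit is out of reach: only labelled cells are counted
  and the labelled fraction is unknown per vessel.
* The FWHM diameter inherits blur inflation; comparisons between
  methods (in vivo vs histology) should use the method factor in the
  diameter model rather than raw values.
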