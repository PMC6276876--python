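# Methods

This note documents the models behind the synthetic-data generator, the
estimators in each analysis stage, the numerical choices that were
genuinely open, and what the test suite does and does not demonstrate.

## Synthetic tissue

Cells sit on a rectangular grid (one cell per footprint tile) and are
rendered as generalized frusta: the cross-section area interpolates
linearly in z between the apical and basal values of a per-frame *shape
program* (apical area, basal area, length).  z index 0 is the apical-most
slice and increases basally; all outputs are in physical units through
`pixel_size` and `dz`.  When the constant-volume flag is set, each frame's
slice areas are rescaled so the discrete volume Σ area·dz equals the first
frame's — volume conservation then holds exactly in the truth table, and
the <0.1% figure quoted on the generator is a bound, not an estimate.

Rendering rounds each slice's rectangle width and height separately
(height = round(area/width)), which keeps the rasterized pixel count
within ~1% of the target area at 0.2 μm pixels; this is what makes the
volume-conservation pass-through test (<3% measured CV over time)
achievable, since naive square-side rounding quantizes areas in ~3% steps.
The membrane channel is the set of label boundaries convolved with a 2D
Gaussian PSF plus additive Gaussian noise.  There is no axial PSF, no
photobleaching, and no embryo curvature (flat sheet); a Poisson noise
option is deliberately omitted because the estimators under test are
means over many pixels, for which additive Gaussian noise is an adequate
model.

The myosin channel adds, on top of a constant background, a basal layer
that is Gaussian in z (configurable FWHM) centered on the basal-most
occupied slice, with a per-region multiplicative amplitude time-course:
exponential decay by a fold f over a duration (the developmental loss of
the basal pool — ~5-fold in mesoderm, ~3-fold in ectoderm), or a
saturating rise to a fold r (optogenetic recruitment, ~1.6-fold in 6 min).
In-plane the amplitude is uniform within a region; the generator does not
emulate per-ring myosin texture in these stacks, which is irrelevant to
z-profile estimation but means the basal projections of *tissue* stacks
are not ring-detection targets (ring fields are generated separately).

## Ring fields

Rings are placed on a grid whose phase is randomized per seed (wrapped
inside the seeded box) and then jittered; with a rigid lattice the number
of rings inside a fixed analysis disk is deterministic and can be biased
by several percent by lattice-boundary alignment, which would corrupt
density-ratio truth.  Each ring is an annulus with a Gaussian radial
profile (σ = `ring_width`); diameters change linearly per frame
(radius0·(1 + slope·frame)).

Lateral compaction is modelled as a radial pull-in about the analyzed
disk's center: points within R·√f of the center are scaled by 1/√f (f =
areal density factor), a transition annulus up to 1.3·R·√f interpolates
linearly to the identity, and points beyond are untouched.  Measured
inside the disk and outside the transition annulus (both restricted to the
seeded box), the truth density ratio equals f exactly in expectation.
This is a phenomenological stand-in for tissue compaction, not a
mechanical model.

## Pulse traces

The study describes pulsatile behavior phenomenologically, so the waveform
is a documented stand-in: between consecutive peak times (spacing drawn
from N(period, jitter)), the area follows a linear ramp between the peak
areas minus a sin² dip of the configured pulse amplitude.  Non-ratchet
traces have equal peak areas (the cell relaxes to baseline); ratchet
traces drop each successive peak by the lock-in increment, clamped at a
small positive floor.  Peak times are anchored by a virtual pre-start
peak, so the first visible ratchet peak already sits one lock-in below
baseline — only differences between successive peaks carry signal.  An
alternative "constrict-then-hold" stair shape was rejected because a hold
phase leaves no local maximum for the peak detector at the next peak time,
making the generated truth unmeasurable by the very analysis it feeds.

## Segmentation and tracking

The bandpass stage is a difference of Gaussians with σ = threshold/2
(thresholds in μm; defaults 2 and 10).  Segmentation is marker-based
watershed on the bandpassed membrane image with h-minima markers
(h = 0.1 of the dynamic range by default); regions with an equivalent
diameter under the 2 μm minimum cell size are discarded.  Linking across
time and across z uses the same rule: regions are linked when
|i ∩ j| / min(|i|, |j|) ≥ 0.4, assigned greedily by descending overlap
fraction, then intersection size, then label ids.  The smaller-region
denominator and the tie-break order are our documented defaults; only the
0.4 threshold itself is prescribed.  Interactive vertex correction is out
of scope — externally curated label volumes can be supplied anywhere
labels are accepted.

## Myosin quantification

The z-profile of an ROI is the area-weighted average of its subregion
profiles (default 4×4 grid; subdivision matters for uneven real tissue and
is harmless on flat synthetic sheets).  The Gaussian fit (offset +
amplitude·exp(−(z−μ)²/2σ²)) is initialized at the basal-half argmax with
μ bounded to the basal half, so a brighter apical peak cannot capture the
fit; "width" is reported as FWHM = 2.355 σ.  A flat profile, or a profile
whose basal half only decays away from the apical peak, raises a
peak-not-found error.

Levels are integrated density per unit ROI area averaged over a 5-slice
window at the fitted peak, with the fitted offset subtracted — the only
background correction in the pipeline.  Without it, relative level changes
are diluted toward 1 by the constant background (a 1.6-fold amplitude rise
over a 0.1 background reads as ~1.52), so offset subtraction is required
for fold-changes to be comparable across conditions.  Fold-changes default
to first-frame baselines (configurable by the caller simply by choosing
the reference level).  Apical per-cell levels integrate 3 slices at the
apical peak (found by the same fit on the flipped stack) and are
normalized by the combined-population mean, making 1.0 the population
reference.

## Ring detection and kinetics

Detection is a circular Hough transform over an integer pixel radius
range.  Three measurement-design choices matter:

* **Ridge voting.** The transform votes on bright ring pixels (above half
  the robust intensity range) rather than canny edges: an annulus has two
  gradient contours, and edge voting yields duplicate detections at
  radius ± ring width.  Canny remains available for dark-ring or filled
  imagery.
* **Sub-pixel radius refinement before suppression.** Each candidate's
  radius is re-estimated as the intensity-weighted mean distance in an
  annulus around the accumulator radius.  Refinement runs before
  non-maximum suppression so that side-peaks of one ring collapse onto a
  single radius and are removed, while genuinely concentric rings (radii
  more than one pixel apart) both survive.  Refinement is also what makes
  population-mean diameters resolve slopes of ~0.03 μm/frame at 0.2 μm
  pixels, where raw integer-pixel radii quantize to zero slope.
* **Validation.** Candidates must score at least 0.6 of the maximum
  accumulator value and have ≥ 80% of their perimeter samples on bright
  ridge pixels.  On rendered fields, true rings score ≥ 0.96 and support
  1.0 even at 10% noise, while phantom circles threading between
  neighboring or concentric rings score ≤ ~0.55 and support ≤ ~0.67, so
  both cuts sit in wide separations rather than on distribution tails.

Constriction speed is an ordinary least-squares line through diameters
pooled per frame and normalized to the population mean of frame 0 (the
per-ring tracked variant is available via `track_rings`; pooled is the
default).  Ring density is the count of detected centers inside a mask per
mask area.

## Shape features

Length is occupied-slice count × dz — a deliberate, simple convention for
near-columnar cells, not a centroid-path length.  Apical/basal areas are
means over 3-slice caps (resistant to per-slice segmentation noise;
single-slice mode available), and the A/B ratio is the ratio of cap
volumes, mirroring the 3-slice apical myosin window.  On a linear wedge
the 3-slice basal cap mean underestimates the extreme-slice area by one
slice-step (e.g. ~58.8 vs 60 μm² on a 26-slice, 30→60 μm² wedge); this is
an understood property of the cap convention, within the tolerance of all
checks, and single-slice mode removes it when wanted.  Cells with a z-gap
longer than one slice are flagged incomplete and excluded from statistics;
single-slice gaps are linearly interpolated.  The volume filter keeps
cells within ±25% (CV) of the mean volume, computed in a single pass.
Anisotropy is the major/minor axis ratio of the second-moment ellipse,
computed in closed form for polygons and from raster moments for masks —
a documented stand-in, since the source workflow's exact definition is not
restated in its description.

## Pulse analysis

Peaks are local maxima with a prominence threshold; endpoints are never
peaks.  The default threshold is twice a robust noise estimate
(MAD of first differences / √2), which is only valid when the sampling
rate is well above the pulse frequency — at 35 s sampling of ~90 s pulses
the first differences are dominated by the signal itself, so analyses at
study-like sampling must pass the prominence explicitly (the pipeline uses
2× the known noise SD, the same rule with known noise).  The period is the
mean inter-peak interval, pooled across traces by default (per-trace means
are also reported).  Ratchet extent is mean(peakₖ − peakₖ₊₁), positive for
net constriction.  Classification compares the mean of the last two
samples against half the mean of the first two (strictly less than);
two-sample edges resist single-frame noise and are configurable to single
frames.

## Statistics

t-tests are pooled-variance and two-sided; two zero-variance samples with
equal means give p = 1 by convention.  ANOVA uses (k−1, N−k) degrees of
freedom with Tukey HSD p-values from the studentized range distribution.
Cohen's d divides by the *maximal* standard deviation of the analyzed
dataset (pass additional groups via `dataset` when the dataset comprises
several sample pairs); a `/2s` variant exists because the conventional
rendering of the formula is typographically ambiguous in the source
description, and a pooled-SD variant for comparison with the wider
literature.  Box summaries use type-7 (linear interpolation) quartiles,
1.5·IQR outliers with whiskers to the remaining extremes (a
literal-extremes mode is available), and notches at median ± 1.57·IQR/√n.

## Problem sizes and determinism

Benchmark scenarios (`furrowquant.scenarios`) use: two 48-ring fields ×
5 frames for the speed ratio; three replicate 400-ring fields for the
density ratio (pooled, as the source study pooled three embryos); one
6×6-cell tissue imaged at five time points for the myosin fold; 100-trace
cohorts (407 for the classification mixture) sampled every 35 s for 15
min; and 16-cell label volumes for the shape features.  These sizes give
stochastic quantities a seed-to-seed spread comfortably inside their
stated tolerances while keeping every scenario in the seconds range on a
single CPU.  All randomness flows through `numpy.random.default_rng`
seeded from the caller; identical seeds reproduce identical outputs
byte-for-byte, including every CSV and TIFF the pipeline writes.

## What passing tests do and do not show

The generator matches the statistical structure the estimators assume
(Gaussian axial layers, annular rings, stair-step or baseline-returning
pulses, frustum cells) with known truth; recovering the configured effect
sizes therefore validates the estimators' correctness and calibration, not
their robustness to real-microscopy nuisances.  In particular: uneven
illumination and embryo curvature (the motivation for subregion
averaging), z-dependent PSF blur, myosin texture within the basal layer,
ring-shape deviations from circularity, segmentation errors propagating
into traces, and photobleaching are all outside what the synthetic suite
can demonstrate.  The alternative-input paths (external label volumes,
external trace CSVs) exist so the same estimators can be run on real,
curated data.
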