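# Methods

## Overview

gliaquant quantifies where a CB2-receptor signal sits relative to cellular
markers in multi-channel fluorescence images of amyloid-bearing brain
tissue, and how a CB2-targeted radiotracer behaves in dynamic small-animal
PET. Because studies of this kind rarely deposit raw images, validation is
built around synthetic phantoms: the generator plants known geometry,
amplitudes and kinetics, and the test suite and `scripts/acceptance.py`
check that the full measurement chain recovers them.

## Image measurement chain

**Coordinates and units.** Object geometry is specified in micrometers and
converted to pixels only at rasterization. Polygon/ROI vertices use pixel
units with integer coordinates on pixel corners; the pixel at array index
(row r, col c) has its center at (c + 0.5, r + 0.5). Rasterization tests
pixel centers for containment, which tracks the analytic area of convex
polygons ≥ 25 px² to within ~2 px². Default lateral sampling is
11.1 px/μm and axial spacing 0.31 μm, typical of the confocal fields the
pipeline targets.

**Background subtraction** estimates background by rolling a ball under the
intensity surface (`skimage.restoration.rolling_ball`), subtracts it, and
clips at zero; it runs per channel and per z-slice. The ball radius
defaults to 50 px (≈4.5 μm at 11.1 px/μm) — large relative to granules,
process endings and membrane rings, small relative to illumination
gradients. A radius at least the image size degenerates to subtracting the
global minimum (with a warning). The correction is a white top-hat, which
is idempotent only approximately: residual texture is shaved again on a
second pass, so "idempotent within ~1 intensity unit" holds for images
whose features are sparse over a smooth background (the intended regime),
not for dense noise.

**Thresholds.** Marker-positive masks default to the IsoData / iterative
intermeans threshold: iterate t ← (mean below t + mean above t)/2 on a
256-bin histogram from the global mean; the fixed point is reached within
one bin width and the mask keeps strictly-above pixels. The implementation
is cross-checked in the tests against a brute-force fixed-point scan and
against `skimage.filters.threshold_isodata`. "Upper third" voxel surfaces
keep voxels strictly above the 66.67th percentile of the candidate
intensity distribution — a percentile rule (≈1/3 of voxels retained on
continuous data), not max/3, because the quantity thresholded is the
intensity *distribution*.

**Autofluorescence exclusion.** Perinuclear granules (lipofuscin-like
aggregates that bleed across all channels) are detected on the DAPI
channel: IsoData threshold → connected components per z-slice → discard
components touching the nucleus/plaque-core mask → keep components with
area in [0.2, 8] μm². The resulting mask is subtracted from ROIs before
density measurement. Both area bounds and the threshold are exposed.

**Densities.** The density of a channel over a region is the sum of its
intensities over (region \ exclusions) divided by the effective area, in
intensity a.u. per px² (μm² conversion available via the pixel scale).
Stacks are measured per z-slice and averaged across slices, treating
slices as replicates. Group tables summarize per-image records by
(genotype, marker, region class) with SEM over n = images (fields), the
unit at which replicate measurements are actually made; whether fields or
animals are the right inferential unit is left to the caller (see
Statistics).

**Marker partition.** Where several marker masks claim a voxel, a fixed
priority CD68 > GFAP > NeuN applies (microglial signal is the dominant
plaque-associated source in this setting; any fixed, documented rule keeps
the partition a true partition). Background is the complement of the
union, so class areas always sum to the field area.

**Profiles.** Radial profiles pool pixels from the requested z-slices into
1-μm annuli around a plaque center (bin value = mean intensity of pixels
whose center distance falls in [r − w/2, r + w/2)); empty annuli are
omitted, not zero-filled. Box profiles sample bilinearly on a rectangle's
grid (1 px steps), average across the short axis, and work for rotated
boxes. Every profile is normalized per channel to percent of that
channel's maximum (max = 100 exactly), which makes profiles invariant to
per-channel gain.

**Peak analysis.** Peaks are the argmax of a 3-point moving average
(`mode="nearest"`), with ties broken toward the smaller position; channels
that are flat along the box carry no peak. Offsets are reported in μm;
the ordering flag records whether DAPI < CB2 < CD68 along the axis
oriented from the plaque core outward. At 11.1 px/μm the 1-px sampling
bounds peak-position discretization at ~0.09 μm.

**Core radius.** The plaque-core radius estimate is the first position,
outward of the minimum of the 3-bin-smoothed CB2 radial profile, where the
trace exceeds min + 0.2 × (max − min). A profile that never rises from its
interior minimum has no core signature and is an error. With 1-μm bins the
estimator resolves the radius to about one bin; the rise threshold (20 %
of range) is exposed.

**Shared-fluorochrome error rates.** When NeuN and mouse-GFAP share one
fluorochrome, discrimination error is quantified against an independent
rabbit-GFAP stain: (a) neuron-overlap error = |blur(σ = 1 px) → IsoData
mask of rbGFAP ∩ rasterized neuron outlines| / |outlines| × 100; (b)
unconfirmed-mGFAP error = |mGFAP \ rbGFAP| / |mGFAP| × 100, where the
mGFAP mask comes from the shared channel after subtracting the neuron
outlines padded by 2 px (so the blur skirt of bright somata is not misread
as astroglial signal). Both rates are threshold-relative, hence invariant
to intensity scaling; enlarging the rbGFAP support can only lower rate (b).

## PET chain

SUV = (tissue activity concentration / injected dose) × body weight, with
the 1 g/mL tissue-density convention making it dimensionless; the activity
unit of concentration and dose must match. The default dynamic schedule is
20 s × 3, 30 s × 2, 1 min × 2, 2 min × 3, 5 min × 4 (14 frames, 30 min).
Windowed means weight frames by their exact temporal overlap with the
window (deterministic and conservative, rather than midpoint inclusion);
`value_at(t)` returns the value of the frame containing t, with boundary
times assigned to the earlier frame. Regional VOI extraction from image
volumes is out of scope — the module consumes per-region TACs.

## Synthetic phantoms

**What the image generator emulates.** AD-genotype fields contain ≥ 1
DAPI-dense plaque core (a sphere of radius 7–15 μm; slices are circular
cross-sections), CD68⁺ microglia (cytoplasmic annulus around a 2-μm
nucleus, 1-μm-wide process running to the core, plate-like ending hugging
the core), a CB2 halo band between the plate and the core, a CB2 membrane
ring offset δ (default 1.5 μm) outward of the CD68 cytoplasm edge, NeuN⁺
neurons with cytoplasmic CB2 and autofluorescent granules added to *all*
channels, GFAP⁺ astrocytes (star-like branch fans), and per-channel
background neuropil. The dense core displaces neuropil: non-DAPI
background inside the core is suppressed (default ×0.1), making the core
CB2-dark. Process endings carry brighter signal than the cytoplasm
(plate boost 1.4, halo boost 1.5), reflecting the robust staining of
engulfment endings; this gives the peak detector a unique maximum at the
synapse. At the synapse the radial order outward is: core edge → 0.4 μm
gap → 0.7-μm CB2 halo band → CD68 plate centered δ farther out, so the
planted CB2-to-CD68 peak separation equals δ. NTG fields simply contain
no plaques (validated), with neuronal CB2 unchanged.

**Optics and noise.** Each object class is rendered into its own
per-channel component image; components are individually Gaussian-smoothed
(σ = 1 px, a lightweight stand-in for optical blur that gives sub-pixel
peak localization something to estimate) and summed — so the noiseless
phantom equals the sum of its components exactly (a tested conservation
law). Noise is Poisson on the signal (scale 1, i.e. intensities are
photon-like counts) plus additive Gaussian read noise (sd 2 a.u. against
amplitudes of ~60–210). Geometry is a pure function of the spec; the seed
touches only noise, so two seeds share bit-identical ground truth.

**Shared-fluorochrome phantoms** place non-overlapping neurons (24-gon
outlines recorded as ROIs) and astrocyte skeletons with a keep-out margin
around neurons, then plant the two error fractions *exactly at pixel
level*: rbGFAP-positive patches covering `p_neuron` of the rasterized
neuron area (compact disks grown from neuron centers), and unconfirmed
mGFAP stubs detached from the confirmed skeleton totalling
`p_gfap/(1 − p_gfap)` of the confirmed area, kept outside the dilation
reach of the rbGFAP support so coverage arithmetic stays exact. Ground
truth records the realized fractions. Object layout is drawn from a
spec-internal generator (`layout_seed`), so the noise seed again changes
only noise; consequently, across a batch of phantoms the between-image
variability is noise-only, narrower than the field-to-field spread of real
tissue — batch means are the meaningful recovery statistic, not batch SDs.

**TAC phantoms.** A TacSpec defines the true curve by piecewise-linear
interpolation through (time, SUV) control points with value 0 at t = 0;
frames are duration-weighted means of that curve (512-point trapezoid per
frame), plus optional Gaussian frame noise; blockade curves are the base
curve scaled by `blockade_scale` before sampling. Beyond the last control
point the curve continues as the terminal mono-exponential through the
last two control points (never negative). The packaged `ad_baseline`
control points are sampled from a bolus-shaped biexponential calibrated so
the *frame-sampled* curve reproduces the reference kinetics — peak frame
2.29 SUV at 40–60 s, 0.67 SUV in the 8–10 min frame, 0.22 SUV in the frame
containing 20 min. Calibrating to frame values rather than instantaneous
ones matters: measured TAC anchors are themselves frame averages, and a
curve forced through instantaneous anchors overshoots the 10-min frame by
~0.18 SUV because the washout is convex across a 2-min frame. The
`blockade_pair` preset scales this curve so its 2–10 min windowed mean is
exactly 1.8 SUV and applies `blockade_scale = 0.65/1.8` (a 2.77-fold
reduction) for the blocked condition.

**What the generator does not emulate:** optical PSF physics and spectral
bleed-through beyond the granule mechanism, cell-shape irregularity,
field-to-field biological variability, tissue autofluorescence gradients,
PET scanner physics (no sinograms, attenuation or scatter). Passing
recovery tests therefore demonstrates the estimators' correctness and
discretization behavior under realistic amplitudes and noise — not
robustness to every artifact of real tissue.

## Statistics

One-way ANOVA uses the standard between/within decomposition (equal to t²
of the pooled t-test for two groups — a tested identity). The two-way
mixed design takes genotype as the between-subject factor and cell marker
as the repeated measure: the genotype F uses subjects-within-genotype as
error; marker and genotype × marker use the marker × subject-within-
genotype residual. Listwise completeness of the within factor is required;
group sizes may differ (cross-checked against `pingouin.mixed_anova`). No
sphericity correction is applied. Fisher's LSD runs pairwise t-tests on
the omnibus error term with no multiplicity adjustment (that is the LSD),
intended only after a significant omnibus effect at α = 0.05. A
perfectly additive table (zero residual) reports F = ∞, p = 0 for nonzero
effects. The unit of analysis (image/field vs animal) is deliberately the
caller's choice: these routines analyze the table they are handed.

## Problem sizes used by the acceptance script

Three noiseless TACs for the kinetic anchors; one baseline/blockade pair;
20 engulfment phantoms (533 × 400 px × 3 slices) for the peak offset; 5
plaque phantoms (444 × 444 px × 6 slices) for the core radius; 21 and 31
shared-fluorochrome fields (512 × 512 px) for the two error rates. The
full run completes in about a minute on one CPU.

## Known limitations

- The core-radius estimator quantizes to the 1-μm radial bin and reads the
  20 %-rise crossing slightly inside the geometric core edge (≈0.5 μm on
  the default phantom), well within its ±1 μm design tolerance.
- Box-profile peak analysis assumes each channel has a single dominant
  bump along the box; multi-peaked channels report only the global
  (smoothed) maximum.
- Granule exclusion assumes granules are DAPI-bright and within the area
  bounds; dim or oversized aggregates pass through.
- The rolling-ball radius is a global default, not auto-tuned per image.
- `suv` checks unit consistency only lexically (same unit string prefix);
  it does not convert between activity units.
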