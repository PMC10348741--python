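# Methods

This note documents the models, estimators, parameter choices, and
numerical conventions used by `kfiber`, and what the synthetic scenes
do and do not establish about real data.

## Coordinate and unit conventions

Lengths are µm everywhere outside raw pixel I/O; times are minutes;
angles are radians internally (degrees at the CLI). Pixel centers sit
at integer indices, 0-based; the physical coordinate of index *i* is
*i* × pixel size. Default voxel sizes follow the imaging conditions the
pipeline targets: 105 nm (or 65.7 nm) pixels and 0.3 µm (or 1 µm)
z-steps.

## Fiber length

A trace is an ordered planar polyline (plus-end first, at the start of
tubulin intensity next to the chromosome) plus the inclusive span of
z-slices the fiber occupied. The planar arc length is an interpolating
Catmull–Rom spline through the control points (uniform
parameterization, reflected phantom endpoints), integrated by dense
sampling at 0.01 µm; with two control points it is the segment length.
The z-height is the number of slice *intervals* spanned times the
z-step (span 13–19 → 6 × 0.3 µm), and the 3D length is the hypotenuse
of the planar length and the z-height. This slice-span convention was
adopted over (span+1) because the height of the volume a fiber crosses
is the distance between its first and last in-focus planes; the
difference is one z-step (0.3 µm, ~4% of a fiber) and is worth checking
against any externally traced data before pooling.

For fibers terminating at a focused pole, the visible tubulin ends at
the centrosome, so a constant centrosome radius (default 0.97 µm,
configurable) is subtracted. The radius itself is estimated as the
half-width at half-max of a line profile through the pole: background =
profile minimum, crossing positions linearly interpolated, the two
sides averaged. A profile whose maximum sits at an endpoint is rejected
as having no peak. Unfocused and ablated fibers, whose minus-ends are
defined by the farthest visible tubulin, are never corrected.

Cohort statistics use sample SD (ddof = 1) throughout and two-tailed
Welch *t*-tests (Welch–Satterthwaite df) for pooled lengths, per-cell
means, and per-cell SDs. At small group sizes the Welch *p* agrees with
an exact permutation test to within ~0.01 at n = 8–10 per group; below
n ≈ 6 the permutation distribution is too discrete for that agreement
and Welch *p*-values there should be read as approximate.

## Morphometry

Spindle axes: Otsu threshold, largest 8-connected foreground component,
then the major/minor axis lengths of the ellipse with the same
normalized second central moments (for a solid ellipse these equal the
true diameters). Component selection stands in for the manual cropping
that isolates one spindle; one spindle per image is assumed. Whether
axes are measured on a single plane or a max-projection is exposed in
the pipeline config; max-projection is the default.

Wide-line profiles take the *maximum* across the perpendicular band
(width 15 px by default), not the mean: this matches measuring on
max-projections and is robust to a slightly offset trace.

## Spatial coordination

The metaphase-plate axis is the first principal direction of the
plus-end cloud — an orthogonal-distance fit, chosen over y-on-x least
squares because only the orthogonal fit is rotation-invariant (the OLS
variant is still available). The long axis is its perpendicular through
the centroid. Fibers are inner if ≤ 2 µm from the long axis, outer if
≥ 3 µm; the open gap (2, 3) µm is left unclassified and excluded from
comparisons. The alignment score of a fiber is the distance of its
plus-end from the plate, signed by the geometric rule: positive when
both ends lie on the same side of the plate (under-aligned), negative
when the fiber crosses it (over-aligned), with an end exactly on the
plate counting as same-side. Signing from both end positions directly
avoids the miscategorizations a plus-end-only heuristic makes on
severely disorganized spindles.

## Temporal dynamics

Length samples are binned by minute (bin b = samples with ⌊t⌋ = b,
value = mean); empty bins stay missing rather than being interpolated,
because interpolation inflates low-lag autocorrelation. CV is reported
×100.

The per-fiber autocorrelation is exactly

    rho(h) = sum_{i=1}^{n-h} (x_i - xbar)(x_{i+h} - xbar)
             / sum_{i=1}^{n} (x_i - xbar)^2

with the full-series mean and an all-n denominator, so rho(0) = 1 and
|rho(h)| ≤ 1 (Cauchy–Schwarz). Missing bins are dropped pairwise. Note
two finite-sample properties: the all-n denominator tapers the estimate
by (n−h)/n, and the subtracted per-series mean biases it further
downward on series short relative to the correlation time. Per-fiber
values are therefore comparable *between* conditions (the per-lag Welch
test, uncorrected, matching per-lag significance marking) but should
not be compared against a process closed form directly. For that
purpose `ensemble_autocorrelation` pools lagged products across many
fibers around the grand mean, normalizing each lag by its term count;
on Ornstein–Uhlenbeck ensembles it matches exp(−h·Δt/τ) within
Monte-Carlo error.

## Ablation and washout regrowth

Ablated and unablated series share t = 0 at the event. Per-fiber minute
binning precedes across-fiber averaging. The initial growth rate is the
OLS slope over minute bins 0–5 inclusive (six bins — "first five
minutes" reconciled with the eligibility requirement of data through
6 min); fibers missing any bin in 0–6 min are excluded and logged. The
recovery fraction divides the ablated group-mean bin value by the
time-average of the unablated group-mean trace (bin-mean division, the
reading closest to normalizing aggregate curves); per-bin Welch tests
are uncorrected by default with an optional Benjamini–Hochberg flag.
Centrosome correction after pole reincorporation is driven by an
explicit per-frame annotation, never inferred from images. Drug-washout
experiments reuse the same machinery with washout at t = 0 and
before/after window means (t ≤ −10 min, t ≥ +10 min).

## Kymographs and flux

Frames are rigidly registered to the first frame: rotation from phase
correlation of polar-resampled log-FFT magnitudes (180°-symmetric, so
angles are folded into (−90°, 90°]), then translation by upsampled
phase correlation; transforms estimated on the tubulin channel are
applied to all channels. Ablation movies bypass registration, since the
stub genuinely translocates. A kymograph row is the per-column max over
a stationary 5-pixel-high box. The auto-tracker follows the mark as the
intensity dip nearest the previous position (parabolic sub-pixel
refinement) and the minus-end as the distal half-max edge crossing; it
truncates with a flag if the dip merges with the edge. Manual segmented
line tracks ingested from CSV are the reference path for reproducing
manually measured statistics.

Flux is −(OLS slope) of d(t) = minus-end − mark, so a mark approaching
the minus-end is positive (poleward). Regressions always use true
timestamps, so a cadence change mid-movie (12 s frames switching to
1 min) needs no special handling. The group value is the mean of
per-fiber slopes — each trace is one point — not a pooled regression.

## Anaphase

Separation series start the frame before the first observed separation
and end at furrow onset. The velocity is the OLS slope fit to the
across-pair averaged trace (fit-to-average, per the convention of
fitting the condition average), not the average of per-pair fits; on
linear-plus-noise data the two agree in expectation. Chromosome-mass
fractions sum each outline's DNA intensity in the summed z-projection
(computed in-module from the stack) and divide by the total across
outlines; no background subtraction by default, with an optional
constant. Overlapping outlines are an error naming the pair.

## Synthetic scenes and ground truth

The generator exists so every stage can be tested for parameter
recovery; each scene records its planted truth.

- **Lengths**: normal truncated at 0.5 µm, defaults 8.01 ± 1.76 µm
  (focused) and 7.81 ± 2.52 µm (unfocused) — matching the first two
  moments avoids non-physical lengths at these parameter regimes.
- **Geometry**: straight 3D fibers; plus-ends on a disk of radius
  4.5 µm (half the ~9 µm spindle minor axis) around the plate center,
  sisters ±0.5 µm along the normal with 0.4 µm axial scatter; focused
  minus-ends point exactly at their half's pole, unfocused directions
  are scattered away from the plate. Traces store the planar projection
  plus the rounded slice span, as a manual tracer would.
- **Rendering**: fibers as line-integrated intensity convolved with an
  isotropic Gaussian PSF (the pipeline never deconvolves, so PSF
  anisotropy would not change any conclusion), optional centrosome
  point sources, additive Gaussian and scaled-Poisson noise. The
  renderer takes the scene truth alongside the traces because traces
  carry z only as a slice span.
- **Sister dynamics (focused)**: one sister is a sinusoid (amplitude
  1.05 µm, period 4 min, random phase), the other is the conserved sum
  minus the first; independent per-sister noise of 0.6 µm is the only
  term breaking conservation. With zero noise the sum is exactly
  constant. These values reproduce temporal CVs of ~13 and sister-sum
  CVs of ~6 over 15-min windows.
- **Unfocused dynamics**: independent Ornstein–Uhlenbeck processes
  (exact discretization), τ = 5 min, stationary SD 1.6 µm. The OU
  choice is a test harness with an analytically known autocorrelation,
  not a mechanistic claim; finite observation windows underestimate the
  stationary CV, which is why 15-min simulated windows give CV ≈ 15–16
  rather than the stationary 21.
- **Ablation**: baseline → stub at the cut → linear regrowth to
  baseline → plateau, plus Gaussian noise.
- **Kymographs**: in the kinetochore frame the lattice (and mark) moves
  at the plus-end polymerization rate and the minus-end at
  (polymerization − flux), so the mark-to-minus-end distance shrinks at
  exactly the planted flux; the generator refuses scenes where the mark
  would reach the minus-end (real marks are consumed there). Position
  noise jitters the rendered features per frame; truth tracks stay
  exact.
- **Anaphase**: pair distance = v·t plus noise.

A single `numpy` Generator seeded per scene drives all draws; identical
seed and parameters give bit-identical outputs, and the pipeline stamps
every output with a config hash so reruns are verifiably identical.

What passing recovery tests shows — and does not: the estimators are
unbiased and correctly scaled on data whose model is known. Real
spindles add tracing error, out-of-focus loss, anisotropic PSFs,
photobleaching, and biological waveform complexity that these scenes do
not emulate; the synthetic results validate the measurement code, not
the biology.

## Problem sizes

The shipped analyses use cohorts sized like a realistic experiment: 16 cells
per condition (~160/224 fibers), 26/23 sister pairs over 15 min at
0.5 min sampling, 8 ablated fibers per condition, 12/11 kymograph
fibers at 12-s frames, 5/9 separating chromatid pairs, and 10,000 null
simulations for the Welch type-I calibration. These sizes put
Monte-Carlo error comfortably below the tolerances asserted in the
tests while keeping the full suite under a few minutes.

## Known limitations

- No automated fiber tracing from raw images: traces are inputs.
- 2D spatial analysis (projections), no 3D plate-plane fit.
- The exact column layouts of externally deposited per-fiber
  spreadsheets vary; the ingestion schema is a documented best-effort
  adapter over the identifier convention
  (`YYMMDD_NNN_FFh_MAXz1-z2`) and reports malformed rows rather than
  dropping them.
- The registration estimator assumes mostly-rigid motion; strong
  deformation or featureless frames degrade to identity with a warning.
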