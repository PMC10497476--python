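# Methods

## Scope and data model

`petkinetics` analyzes decay-corrected dynamic PET data: a scan is a
contiguous, non-overlapping partition of [0, T) into temporal frames
(half-open intervals), and a frame value is the time-average of the
activity concentration over the frame, attributed to the frame mid-time
for all integration and regression. Schedules and file formats carry time
in seconds; kinetic math uses minutes so that the net influx rate Ki
comes out in mL/min/cm^3 (reports also print the conventional
uL/min/cm^3). Six preset framing protocols are built in, all covering
3600 s, with 100/61/48/29/19/12 frames; the densest (P-100f) serves as
the reference in protocol comparisons.

Whether frame values should be attributed to mid-times or handled by a
more elaborate within-frame model is a genuine convention choice;
mid-time attribution is the standard dynamic-PET one and is used
throughout, consistently on both the tissue and input sides, so the
protocol comparison is not confounded by mixed conventions.

## Patlak analysis

For an irreversible tracer the ratio C_T(t)/C_P(t) is, after the
reversible compartments equilibrate (t >= t*), linear in the "normalized
time" x(t) = int_0^t C_P dtau / C_P(t). The fit is ordinary (unweighted)
least squares over frames with mid-time >= t* (inclusive); duration
weighting is available as an option but off by default. The plasma
integral runs from injection over *all* frames, anchored by a prepended
(0, 0) sample when the first mid-time is positive (activity is zero
before injection). t* defaults to 10 min; the full comparison can be
rerun at t* = 30 min.

Voxelwise maps exploit the fact that x depends only on the input
function: one centered design is shared across the volume, so slope,
intercept, and residual SSE are computed in closed form per voxel. This
vectorized path is held against a naive per-ROI OLS oracle in the tests
and the acceptance script. Both paths are linear in the tissue data, and
the ROI mean commutes with that linearity, so ROI means of voxelwise
parameters agree with fits of ROI-mean TACs to floating-point precision —
the verification criterion (R^2 > 0.9999, mean relative difference
< 0.02%) leaves real room for implementation error, not statistical
noise.

Numerical conventions: frames with non-positive plasma values cannot be
normalized and are dropped with a warning; fewer than two usable frames
is an error; negative Ki values are reported as-is (clipping is an
option); voxels excluded by a mask receive a configurable fill value
(default 0). Plasma is taken equal to whole blood by default
(plasma-to-blood ratio 1.0, adjustable), appropriate for FDG at these
time scales.

## Image-derived input function

The descending aorta runs near-axially, so its ROI is a cylinder: a voxel
belongs to the ROI when its center lies within the centerline's z-range
and its in-plane (x-y) distance to the centerline position at that z
(linear interpolation along z) is at most the radius, 4 mm by default.
Membership is a pure voxel-center test with no partial-volume weighting.
The IDIF is the per-frame unweighted mean over the ROI. By default each
framing protocol gets its own IDIF extracted from its own rebinned data;
a shared-input mode instead resamples one reference IDIF onto every
protocol's mid-times (linear interpolation through the (0,0)-anchored
samples, holding the last value beyond the final mid-time).

Input-function AUC over 0-60 min is the trapezoid over (mid-time, value)
samples with the (0,0) anchor; because sparse protocols end their last
mid-time well before 60 min (55 min for the 12-frame preset), the last
sample is held constant to the window end so that AUCs are compared over
a common support rather than protocol-dependent spans.

## Rebinning

Each target frame value is the overlap-duration-weighted mean of source
frame values. When target frames are unions of source frames this is
exact and conserves time integrals to rounding; misaligned boundaries
fall back to fractional-overlap weights with a warning; a target frame
that would subdivide a single source frame (temporal upsampling) is an
error. Weighting is by duration only — the data are decay-corrected, so
count-based weighting would itself introduce a model; the residual
within-frame bias vanishes on aligned boundaries, which covers all six
presets against the simulation master grid.

Rebinning reconstructed fine-framed data is a surrogate for
reconstructing each protocol independently from raw list-mode data. It
preserves means and time integrals exactly but shares one noise
realization across protocols (real per-protocol reconstructions would be
correlated too, through the shared counts, but not identical).

## Synthetic phantom

The phantom emulates a decay-corrected 0-60 min FDG study; no radioactive
decay, attenuation, scatter, motion, or scanner sensitivity profile is
simulated.

**Arterial input.** A tri-exponential bolus
Cp(t) = (A1 t − A2 − A3)e^{−l1 t} + A2 e^{−l2 t} + A3 e^{−l3 t} with the
widely used FDG population parameter set (A1 = 851.12 kBq/mL/min,
A2 = 21.88, A3 = 20.81 kBq/mL, l1 = 4.134, l2 = 0.0104, l3 = 0.119
/min): a sharp peak inside the first minute and a slowly decaying tail.
These are synthetic defaults, not measured values.

**Tissue kinetics.** Each labeled region follows the two-tissue
irreversible model; the measured curve is
C = (1−Vb)·[Ki ∫Cp + (K1 k2/(k2+k3)) e^{−(k2+k3)t} ⊗ Cp] + Vb·Cp, with
the convolution evaluated by an exponential recursion that is exact for
piecewise-linear Cp (validated against a stiff ODE solver to < 0.1%
beyond 1 min). Degenerate cases follow the continuity conventions
Ki = K1 for pure trapping (k2 = k3 = 0) and Ki = 0 when k3 = 0. The
blood-volume term Vb·Cp adds a constant Vb to C/Cp, so it shifts the
Patlak intercept and scales the recoverable slope to (1−Vb)·Ki; the
ground truth therefore carries three maps — Ki, the asymptotic measured
slope (1−Vb)·Ki, and the asymptotic intercept
(1−Vb)·K1k2/(k2+k3)^2 + Vb.

**Default regions.** A 32×32×48 grid at 4×4×2.886 mm with a straight
2-voxel-radius axial blood cylinder (aorta analog), one spherical lesion,
and eight ellipsoidal organs. Region Ki values are set to typical 60-min
FDG magnitudes — lesion 23.5, gray matter 36.5, white matter 11.6, lung
0.9, liver 3.7, spleen 4.5, bone marrow 9.8, kidney 5.5, muscle 1.6
uL/min/cm^3. The micro-parameters behind each Ki are underdetermined by
Ki alone; K1 and k2 were chosen at physiologically plausible magnitudes
per organ with k2+k3 kept within 0.05-1.5 /min, and k3 follows as
k3 = Ki·k2/(K1−Ki). Blood-volume fractions range from 0.03 (muscle,
white matter) to 0.20 (liver, spleen, kidney).

**Noise.** Gaussian, per voxel and frame, with standard deviation
alpha·sqrt(max(C, C_floor)/dt) — a count-statistics surrogate in which
variance scales with activity and inversely with frame duration
(C_floor = 0.01 kBq/mL guards zero-activity frames; the scale alpha
defaults to 0.5, giving roughly 1% noise on late 120-s frames in
high-uptake regions and 5-20% on the shortest bolus frames). No
published noise calibration for the target scanner's reconstructions is
assumed; alpha is a free configuration parameter. This model is exactly
consistent under duration-weighted rebinning: averaging frames reproduces
the variance a direct simulation at the coarser framing would have.
Optional 3D Gaussian smoothing (FWHM in mm) can be applied per frame;
it is off by default since the analysis does not require it.

**Master grid.** The study workflow simulates once on the coarsest grid
whose frame edges contain every configured preset's edges (124 frames for
all six presets) and rebins from it; this is exact for every preset and
statistically identical to simulating on a uniform 1-s grid, at a
fraction of the cost. A uniform master grid of any step is available as
an option. With the default conditions one replicate (simulate, rebin to
six presets, IDIF, voxelwise Patlak, ROI means) takes about a second, and
the ten-replicate verification study runs in well under a minute.

**What passing tests show.** The phantom exercises the full numerical
pipeline — framing, rebinning, cylinder geometry, input-function
handling, vectorized regression, statistics — under known ground truth.
It does not emulate reconstruction artifacts, partial-volume effects,
motion, plasma-to-blood kinetics, or inter-subject variability, so
phantom results quantify algorithmic fidelity, not expected clinical
accuracy.

## Protocol-comparison statistics

"Subjects" are replicate phantoms with different noise seeds (default
n = 10). For each protocol and ROI the report tabulates mean ± SD of
Ki (uL/min/cm^3) and intercept across replicates, relative differences
(%) versus the reference protocol paired by replicate (reference columns
exactly zero by construction), paired t-tests on Ki replicates versus
the reference, and input-function AUC relative errors. Bland-Altman
agreement uses relative differences (a−b)/b in percent by default, with
limits at the bias ± 1.96 SD. The variance F-test compares each
protocol's pooled relative-difference sample against the first
non-reference protocol's sample: the reference's own differences are
identically zero, so its variance cannot anchor an F-test; the densest
non-reference protocol is the natural yardstick. Raw two-sided p-values
are reported with no multiple-testing correction.

## Known limitations

* Rebinning-based protocol emulation shares noise across protocols (see
  above); between-protocol variance estimates are therefore slightly
  optimistic relative to independent reconstructions.
* The recovered Patlak slope in regions with slow kinetics
  (k2 + k3 below ~0.3 /min) still carries a visible transient at
  t* = 10 min; this is a property of the model, not of the fit, and is
  why the verification compares implementation against oracle rather
  than against the asymptotic truth.
* The cylinder ROI assumes a near-axial vessel (strictly monotone z along
  the centerline); strongly curved vessels are out of scope.
* No partial-volume correction, dispersion/delay correction, or
  metabolite correction is applied anywhere.
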