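# Methods

This note documents the models, parameter choices and numerical
conventions behind `hyperrigid`, and what the synthetic pipeline does and
does not establish about real observers.

## Stimulus geometry

A d-dimensional cube wireframe has vertices at all sign combinations of
±s/2 (s = 100 cm by default) and edges between vertex pairs differing in
exactly one coordinate: 8/12 for the cube, 16/32 for the hypercube.
Irregularity perturbs every vertex by a displacement of *exact* norm
`level × s` (levels 0.12 / 0.18 / 0.24 → 12 / 18 / 24 cm), with direction
uniform on the unit sphere (normalised standard-normal draws, which are
exactly isotropic). For 4D objects the displacement lives in the (x, y, z)
subspace and leaves w untouched; this mirrors the static 3D-level shift of
the original stimuli and is switchable to full-4D (`space="full"`) for
sensitivity studies. The perturbation is applied in the native dimension,
before any projection; whether to perturb before or after 4D→3D projection
is genuinely open, and pre-projection was chosen because it keeps the
object's identity independent of the camera.

## Motion model

Rigid motion composes plane rotations whose angles oscillate as
`θ(t) = A sin(2πft + φ)`, realising repeated rotation over a fixed angular
range. Defaults: A = 30°, f = 0.25 Hz (one half-sweep per 1 s of the 3 s
window), sinusoidal waveform (a triangular waveform is available). In 3D
the object rocks about the x and y axes (phases 0 and π/2); in 4D all
three plane rotations — invariant planes y-z, x-z, x-y, each rotating its
complementary coordinate pair — run simultaneously with staggered phases
(0, 2π/3, 4π/3). The named plane is interpreted as the *invariant* (axis)
plane, the 4D generalisation of a rotation axis; a convention switch is
the rotation operator's argument itself (name the other pair). Rotations
compose in list order; the operators are orthonormal with determinant +1
by construction.

Non-rigid motion starts from the same rigid backbone and adds
(a) per-vertex deformation: a fixed seeded random unit direction per
vertex, magnitude `d·sin(2πf_d t)` with d = 5 cm, f_d = 0.5 Hz; and
(b) shear: the shear-axis coordinate is incremented by
`g·sin(2πf_s t)` times a transverse coordinate, with gain g = 0.2 and
f_s = 0.5 Hz. The transverse coordinate is the next axis in cyclic
x→y→z order — a deterministic, documented choice where any transverse
direction would serve. Deformation (and jitter, below) act on the
(x, y, z) components of 4D objects, extending the 3D-level convention of
the static perturbation. These amplitudes and frequencies are this
package's own defaults, chosen to give clearly visible but non-degenerate
motion within 3 s; they are all surfaced in `MotionSpec`.

A per-vertex, per-frame jitter (default amplitude 0.5 cm, drawn uniformly
inside a ball of that radius) emulates the slight random motion added to
stimuli to enhance stereoscopy. Trajectories sample
`round(duration × frame_rate)` uniform frames (3 s × 90 Hz = 270) and are
bit-reproducible given a seed.

Coordinate convention: x left→right, y up→down, z in→out (towards the
viewer), w the fourth axis.

## Projection

4D→3D projection defaults to perspective: (x, y, z) scaled by
`w_e/(w_e − w)` with the centre of projection at w_e = 250 cm, giving the
nested-cube appearance of a tesseract (orthographic drop-w is a switch).
The viewing distance defaults to 150 cm. Both are configuration-level
unknowns of the original setup, fixed here as defaults.

Stereo imaging uses two pinhole cameras at x = ∓e/2 (e = 63 mm) at the
viewing distance D, with an off-axis (asymmetric-frustum) projection that
shifts each eye's principal point so the fixation point (object centre)
maps to the screen centre — the standard VR arrangement, which produces
zero vertical disparity and horizontal disparity `f·e·(1/Z − 1/D)`:
zero at fixation, positive nearer, negative beyond. Focal length in
pixels derives from the 18 mm pupil-to-lens distance and the pixel pitch
of a 1200 × 1080 screen with 91.4 mm diagonal. Lens distortion is out of
scope.

## Rigidity oracle

A trajectory is classified rigid iff no pairwise inter-vertex distance in
any frame deviates from its frame-0 value by more than a relative
tolerance. The report also carries a per-frame RMSD after optimal
translation-plus-proper-rotation alignment onto frame 0 (Kabsch SVD with
the determinant sign forced to +1; reflections are excluded because
physical motion cannot mirror an object). The default tolerance is
`4 × jitter_amplitude / side_length` (floor 10⁻⁶ when jitter is off): a
pairwise distance between two jittered frames can shift by at most four
per-vertex jitter radii (two vertices in the assessed frame and two in
the jittered reference frame), so 4× is the tight admissibility bound —
at jitter 0.5 cm / side 100 cm the observed maximum deviation ≈ 0.017
exceeds a 3× bound (0.015) but stays below 4× (0.02). For heavily
perturbed objects whose minimum inter-vertex distance falls well below
the side length, the bound is conservative only relative to the side;
the bulk agreement suites therefore run jitter-off, where classification
is exact.

## Experiment design

Sessions cross dimension (3D, 4D) × displacement axis × irregularity
(0.12, 0.18, 0.24): Experiment 1 uses axes x/y/z with 3 repetitions per
cell (54 trials); Experiment 2 removes x and uses 7 repetitions (84
trials). 3D and 4D trials form separate blocks; counterbalancing is
realised as exact equal cell counts with a seeded within-block
permutation (the original counterbalancing scheme is not further
specified). The rigid stimulus's top/bottom position is balanced within
each cell, the odd repetition settled by a seeded coin flip; whether the
original experiment balanced or randomised this is unknown, and balancing
was chosen to remove a nuisance confound. Block order alternates across
sessions (odd sessions 3D-first). Experiment 1's first session is flagged
as training and excluded from analysis by default. Responses beyond the
3000 ms window are recorded as timeouts with no choice/RT/confidence. A
five-subject cohort with two recorded sessions per experiment totals
1380 trials.

## Synthetic observer

The observer is parameterised per (dimension × axis) cell — irregularity
has no configured effect, matching the null irregularity findings — by an
accuracy probability, an RT mean/SD, and a confidence mean/SD. Two
bundles ship as defaults: `table1` (fixed headset) and `table2` (active
headset), transcribed from the reported per-condition means and SDs.
Modeling choices (the source data report only means and SDs):

- **RT**: log-normal with (μ, σ) solved from the configured mean and SD,
  truncated to (0, 3000] ms by resampling (the truncated mass is < 0.3 %
  in the worst cell, so the configured mean is recovered to well within
  sampling error at n = 2000).
- **Confidence**: a latent normal
  `c = m + s(ρ z_rt + √(1−ρ²) ε)` with ρ = −0.52, rounded and clipped to
  {1..5}. Discretisation slightly compresses the mean near the scale
  ends, so recovery tests compare against the closed-form mean of the
  discretised distribution. The pooled sample correlation across cells
  lands near −0.52 without further calibration because the between-cell
  structure (slow cells are low-confidence cells) reinforces the
  within-cell coupling.
- **Timeouts**: Bernoulli per trial at the overall recorded rate
  (63/1380 ≈ 4.6 %).
- **Head pose** (active mode): per axis, a per-trial baseline
  `N(median, 1°)` around preferred viewpoints (10°, 45°, 5°) for
  (x, y, z), plus one slow sinusoidal sweep per 3 s trial whose amplitude
  is `IQR/√2` (the IQR of a uniformly sampled sinusoid is √2 × amplitude;
  default IQR 2°), plus 0.05° sensor noise, sampled at 18 Hz (54
  samples). Fixed mode returns constant front-view angles.

The generator emulates the per-cell mean/SD structure, the
confidence–RT coupling, the timeout rate, and the head-pose summary
statistics. It does **not** emulate sequential effects (learning,
fatigue), per-subject heterogeneity beyond independent seeding,
RT–accuracy interactions within a cell, or any perceptual mechanism —
passing recovery tests shows the analysis chain is correct and
calibrated, not that humans behave this way.

## Analysis

Filtering removes timed-out trials globally and training sessions by
default; the RT view keeps correct trials only. Subject exclusion
formalises the reported outcome (a participant at 54.9 % accuracy with
mean confidence 1.71 was dropped): a subject is excluded when a
two-sided binomial test cannot distinguish their accuracy from 0.5
(p > 0.05) *and* their mean confidence is below 2.0 — accuracy alone
does not exclude, since at-chance-but-confident performance is
informative.

Cell summaries report accuracy as the mean of the per-trial 0/100
indicator with its SD (matching the "98.84 (10.78)" style), RT on
correct trials, and confidence on all retained trials; empty cells are
reported missing, not zero.

The LMM-ANOVA fits a linear mixed model with sum-to-zero-coded fixed
factors (all interaction orders) and a random intercept per subject
(statsmodels `MixedLM`, REML; the response is standardised internally for
conditioning — Wald F statistics are invariant to affine rescaling).
Each term gets a Wald F test; the denominator df use the residual
(containment) approximation `n − rank(X) − (g − 1)`, recorded in the
result metadata. This is deliberately simpler than Satterthwaite-type
fractional dfs; with the trial counts used here the test is calibrated
(null-simulation type-I error ≈ 0.05, checked over 1000 replicates of
5 subjects × 2 levels × 20 trials). Accuracy can be fitted on trial-level
0/100 outcomes (default) or on per-subject cell percentages
(`aggregate=True`); both modes are provided because the original choice
is unstated. Constant responses are flagged degenerate with F = 0 rather
than erroring.

Head-movement statistics compute, per trial and axis, the median and the
percentile range Q3 − Q1 of the 54-sample series, using linear quantile
interpolation (numpy's default rule; the original interpolation rule is
unstated). When raw poses are supplied, per-axis angles between the
viewing direction and the head-to-object vector are computed as signed
angles between the projections of the two vectors onto the plane
perpendicular to each axis (collinear vectors → 0 on all axes).

## Problem sizes and tolerances

Rigid-motion distance conservation is asserted at 10⁻⁹ relative (jitter
off); rotation-operator orthonormality at 10⁻¹². The bulk oracle
agreement suite runs 200 jitter-off stimuli per condition cell (100
rigid + 100 non-rigid × 18 cells) at reduced length (1 s at 30 Hz) —
rigidity violations appear within the first shear/deformation cycle, so
the shorter window loses no discriminative power while keeping the suite
fast. Statistical recovery uses n = 2000 trials per cell with 3-standard-
error bands; the type-I calibration uses 1000 null replicates.

## Known limitations

- The exact animation parameters of the original stimuli (amplitudes,
  frequencies, jitter statistics) are not public; the defaults here are
  reasoned stand-ins, so quantitative image-level properties (e.g.
  projected edge-length variation) characterise this package's stimuli,
  not the originals.
- The 4D projection type and viewing distance of the original setup are
  unknown; both are configurable defaults.
- Human F statistics and p-values are not reproduction targets: they
  depend on raw human data that is not deposited. The reported
  per-condition means/SDs serve as observer defaults and recovery
  targets instead, and head-pose/performance correlations are likewise
  out of scope.
- The synthetic observer is a statistical emulator, not a perceptual
  model; no ideal-observer analysis of 2D retinal input is attempted.
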