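# Methods

`rtnf` is a desk-scale simulator of a real-time fMRI multivoxel-pattern
neurofeedback (NF) loop for motor imagery: a participant imagines left- or
right-hand gripping-and-opening (LGO / RGO) in a block design; each acquired
volume is preprocessed online, classified by linear SVMs, and a correct task
classification raises the matching arm of a (here simulated) humanoid robot.
Since no scanner is in the loop, a synthetic BOLD phantom with known ground
truth takes its place, which is what makes every stage testable.

## The block design

A run is 9 rest and 8 task blocks of 30 s each, alternating and starting and
ending with rest, at TR = 2 s: 255 volumes, 135 rest-labelled and 120
task-labelled (4 LGO + 4 RGO blocks). Blocks are half-open intervals
`[onset, onset + duration)`; volume *i* takes the condition at time
`i * TR`, so no volume is double-labelled. The within-run order of LGO/RGO
blocks is a configuration field (default alternating), and an optional
`label_shift` delays the per-volume labels by whole volumes to compensate
hemodynamic lag (default 0).

## The phantom

Each brain voxel (the brain is an axis-aligned ellipsoid; background is
exactly 0) follows

    y_v(t) = B * (1 + sum_c a_c/100 * (boxcar_c ⊗ h)(t) * P_c(v))
             + d(t) + e_v(t)

with baseline `B = 100`, canonical double-gamma HRF `h` (response peak 6 s,
undershoot peak 16 s, undershoot ratio 1/6, 32-s support, peak normalised
to 1, sampled at TR), low-frequency drift `d` (linear + half-cosine,
coefficients in signal units), and AR(1) Gaussian noise `e` with stationary
SD `noise_sd` and lag-1 correlation `ar1_rho`. Optional rigid-body motion is
injected by trilinear resampling of each volume; voxels sampled outside the
grid are filled with the background value 0 (filling with the brain baseline
would paint bright slabs at the volume edges that corrupt realignment and
masking).

The two task patterns are unions of weighted spherical clusters: a shared
midline cluster (weight 1.0) plus one contralateral lateralised cluster
(weight `lateral_weight`, default 0.35). The patterns therefore overlap and
differ only in their multivoxel configuration — the regime MVPA targets, and
the reason LGO-vs-RGO decoding is harder than task-vs-rest, as observed in
real motor-imagery data.

**Default operating point.** `amplitude = 1%` of baseline, `noise_sd = 1%`,
`ar1_rho = 0.3` (a realistic lag-1 autocorrelation at TR = 2 s), drift
coefficients 1.0 (linear) and 0.5 (cosine) signal units, `lateral_weight =
0.35`. These were chosen once so that the default 4-run session yields SVM
performance in the 60–85% range reported for real-time motor-imagery
decoding, with LGO-vs-RGO accuracy below the task-vs-rest TPVs; a measured
default session gives TPV ≈ 0.80 (both task-vs-rest models) and LGO-vs-RGO
accuracy ≈ 0.74.

What the phantom does **not** emulate: physiological (cardiac/respiratory)
noise, susceptibility distortion, slice timing, spatially varying noise, or
anatomical structure. Passing tests therefore demonstrate correctness of the
pipeline's algorithms under the stated noise model, not performance on real
scanner data.

## Online preprocessing

Each streamed volume is rigid-body realigned to the training run's mean
image, smoothed with an 8-mm FWHM Gaussian, and restricted to a brain mask.

* **Realignment** minimises the mean squared intensity difference over a
  6-parameter rigid transform (translations mm, rotations rad; rotation
  order Z–Y–X about the reference's intensity centre of mass) with a
  two-level multi-resolution trust-region Gauss–Newton
  (`scipy.optimize.least_squares`, finite-difference Jacobian, stopping at
  relative cost change 1e-6). Both images are pre-smoothed by 1 voxel; the
  translation start value moves the centres of mass into register, which
  puts large displacements inside the capture range. The *cost* is
  evaluated with cubic interpolation: trilinear resampling loses
  high-frequency power, which otherwise biases sub-voxel estimates toward
  zero (with trilinear cost, a 0.05-rad rotation of a textured phantom has
  its cost minimum at the identity). The returned resampled volume is
  trilinear, and the reported parameters are the correction applied to the
  moving volume. Measured recovery of injected transforms (|t| ≤ 5 mm,
  |r| ≤ 0.05 rad): RMSE ≈ 0.05 mm / 0.005 rad.
* **Smoothing** is separable Gaussian with σ = FWHM / (2√(2 ln 2)) per axis
  in voxel units, boundary handled by a renormalised truncated kernel so a
  constant image is preserved exactly; total image mass is conserved for
  images supported at least two kernel radii inside the grid.
* **The brain mask** thresholds the mean image at `frac` (default 0.5) times
  its 99th percentile and keeps the largest 26-connected component. This
  replaces template-based mask construction, which needs an anatomical image
  and a normalisation template; its role — excluding non-brain voxels — is
  the same. Training-run preprocessing is two-pass: realign to volume 0,
  average, then realign everything to that mean.

## Decoding

Three linear soft-margin SVMs (c = 1, libsvm via scikit-learn) are trained
on the pre-feedback run: Rest-vs-LGO, Rest-vs-RGO, LGO-vs-RGO. Features are
the in-mask voxel intensities of the smoothed, realigned volumes, z-scored
per voxel by training statistics (SD floored at 1e-12; scaling can be
disabled). Every volume of the relevant blocks is a training row. The
decision value is `w·x̃ + b`, positive for the second-named class; exact
zeros resolve to the first-named class.

**Incremental detrending.** The raw decision value is drift-corrected
before thresholding: the corrector maintains the O(1) running sums of a
least-squares line (intercept + slope) over all decision values seen so
far and subtracts the fitted baseline at the current volume; during a
warm-up window (first W = 10 volumes) the baseline is the running mean.
This is a reconstruction — the recursion used by the original real-time
system is not public — chosen because it nulls any affine drift exactly
(by linearity of least squares, an added `a + b·t` leaves the detrended
trace unchanged after warm-up) and costs O(1) per volume.

Two behaviours of this corrector are worth knowing. First, early in a
stream a genuine signal step (the first task block) is partially absorbed
as if it were a trend, costing accuracy in the first ~2 blocks regardless
of SNR. Second, it serially couples predictions through the shared
baseline. For these reasons the *calibration* tests (pattern recovery,
null-accuracy band) run the stream with detrending disabled — they isolate
the decoder, and the replay-identity property (streamed training volumes
reproduce training predictions) only holds without detrending — while the
detrender has its own tests: exact-line nulling to < 1e-8 after warm-up,
and ≤ 5% label flips under a 0.02/volume decision drift.

## Feedback

During an LGO block the Rest-vs-LGO model is consulted, during an RGO block
the Rest-vs-RGO model (the block identity is part of the protocol); a
prediction matching the block's task raises the matching robot arm by 85°
and lowers it before the next volume, anything else leaves the robot
stationary, and rest-block volumes never generate commands. The robot is an
event log plus a state timeline with instantaneous raise/lower; the arms
are at 0° at every volume boundary by construction. The raise-command count
equals the number of correctly classified task volumes exactly, on every
run. In non-NF sessions the same decoding runs but no commands are emitted.
The LGO-vs-RGO model is evaluated offline only.

## Offline evaluation

The first 5 volumes of a run are discarded (initial signal stabilisation).
The voxelwise GLM regresses each in-mask time course on the task boxcars
convolved with the canonical HRF, the 6 realignment parameters (near
constant columns are dropped — they are collinear with the intercept),
optional polynomial drift terms, and an intercept;
`t = c'β̂ / sqrt(σ̂² c'(X'X)⁻¹c)` per voxel with df = n − rank(X).

**Cluster inference** is a sign-flip permutation test substituting for
random-field-theory FWE cluster correction (which needs smoothness
estimation out of scope here): clusters are formed from |t| at the
two-sided cluster-defining threshold p = 0.001 with 26-connectivity, and
the null of the maximum cluster size is built Freedman–Lane style — the
residuals of the reduced model (contrast regressors removed) are
sign-flipped with one shared sign per time point (preserving spatial
correlation), added back to the reduced fit, and the full model is refit.
Corrected p = (1 + #{perm max ≥ s}) / (n_perm + 1); p < 0.05 is flagged.
Measured on null phantoms: voxelwise type-I rate at the nominal 0.001, and
0/20 null runs with a flagged cluster at 200 permutations.

**Metrics.** TPV (task predictive value) = correctly classified task
volumes / all task volumes; accuracy = correct volumes / all volumes of the
contrast's two classes (other-condition volumes are excluded). Session
comparisons use a paired t-test on per-subject (here per-seed) metrics,
two-sided, df = n − 1; all-zero differences report (t, p) = (0, 1), and
zero-variance nonzero differences are degenerate (p = 0 with a warning).

## Calibration-test conditions

* Null-calibration checks (binomial band for LGO-vs-RGO on a patternless
  phantom; GLM type-I rate) use temporally white noise (`ar1_rho = 0`):
  the binomial and t reference distributions assume exchangeable volumes,
  so a valid calibration requires it. The default phantom keeps ρ = 0.3.
* The high-SNR recovery check uses 60-s blocks (5 rest + 4 task),
  amplitude 8%, noise 0.25%, `label_shift = 3`, fully distinct lateral
  patterns. With 30-s blocks, whatever the shift, one volume per block
  sits near 50% of the hemodynamic plateau — exactly at the learned
  boundary — making the worst-seed TPV a coin flip; longer blocks dilute
  these boundary volumes so pattern recovery, the property under test, is
  what determines the outcome.
* Problem sizes: tests and the acceptance script use grids from 12×12×8 to
  32×32×20 (the full 64×64×37 acquisition grid is the library default and
  exercised by the same code paths); the bundled session run uses
  20×20×12. These sizes were chosen as the smallest on which the
  statistical checks have adequate power.

## Known limitations

* Realignment accuracy is quoted for the phantom's contrast and smoothness;
  no claim of numerical equivalence with any specific neuroimaging package
  is made (cost function and interpolation details differ).
* The permutation cluster test assumes sign-symmetric, temporally
  exchangeable errors; with autocorrelated noise it is approximate.
* The detrender's first-block absorption (above) slightly depresses
  early-run TPV in default sessions; online SVM retraining, which the
  protocol anticipates as a mitigation for drift, is out of scope.
* Group-level analyses beyond the paired metric comparison (factorial
  designs, nonsphericity corrections) are out of scope.
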