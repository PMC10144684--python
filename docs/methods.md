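# Methods

## Scope and design

`coclin` is a desk-scale analysis library for co-clinical trial data: it
assumes images, masks and expression tables already exist as files (NIfTI +
JSON sidecars, read-only DICOM, TSV) bound together by a JSON study
manifest, and chains five stages — parameter maps, lesion features,
response, expression simulation, association — over both the patient and
PDX cohorts. There is deliberately no database, web service or image
annotation layer; each stage is a plain function, the CLI is a thin wrapper,
and every output is a text table so that reruns can be compared byte for
byte.

## ADC fitting

Diffusion signal is modeled as `S(b) = S0·exp(−ADC·b)`. The fit minimizes
the sum of squared residuals in signal space (not log space): log-space
least squares would weight low-signal, high-b measurements too heavily under
additive noise. The closed-form ordinary-least-squares slope of `ln S` on
`b` provides the initial iterate — it is exact on noiseless data — and a
vectorized Levenberg–Marquardt refinement (damped 2×2 normal equations per
voxel, per-voxel step acceptance, convergence when the relative cost change
falls below 1e−14, at most 60 iterations) polishes it. The refinement is
checked in the test suite against SciPy's bounded `least_squares` on noisy
voxels to ~1e−9 mm²/s.

Constraints and degenerate inputs:

* ADC is bounded to [0, 1e−2] mm²/s — free water at body temperature is
  ~3e−3 mm²/s, so the upper bound is physiological headroom, not a tuning
  parameter.
* Voxels with any non-positive signal are NaN rather than clipped: the log
  initializer is undefined there and clipping would bias the fit.
* Fewer than 2 distinct b-values is an error.

## SER computation

`SER = (S_early − S_baseline)/(S_late − S_baseline)` per voxel, with
`S_baseline` the mean of the first `n_baseline = 10` frames, `S_early` the
maximum over frames at/after index `n_baseline` (a pre-contrast frame cannot
be the peak; equal maxima resolve to the earliest frame for determinism),
and `S_late` the frame whose acquisition time is nearest the voxel's peak
time + 360 s. If that target time exceeds the acquisition, the last frame is
used and the voxel is flagged in the map's quality channel rather than
dropped. The denominator guard is scale-free: voxels with
`|S_late − S_baseline| < 1e−6 × max(series)` are NaN, which marks
non-enhancing tissue. Because numerator and denominator are both
differences of signals, SER is invariant under any affine rescaling
`S → aS + c, a > 0` of the series.

The peak is voxel-wise by default: only a voxel-wise definition yields a map
whose ROI mean/median are meaningful summary biomarkers. An ROI-level
variant (`peak_mode="roi"`), which locates a single peak frame on the
ROI-mean curve, is exposed for whole-lesion readings; the two coincide on
homogeneous lesions.

## Lesion geometry

* **Longest diameter** is in-plane by convention (per-axial-slice maximum
  pairwise distance between foreground voxel centers, using the in-plane
  spacings; maximum over slices), matching clinical diameter readings; a
  full-3-D diameter is available behind a flag. Measuring between voxel
  centers is deterministic and carries a documented bias of up to one voxel
  relative to outer-boundary definitions. Slices with > 400 foreground
  voxels are pruned to their convex hull before the pairwise scan; the
  result is exactly the brute-force all-pairs answer (verified in tests up
  to 500 voxels), with a fallback to the full scan for degenerate
  (collinear) slices.
* **Volume** is foreground voxel count × voxel volume.
* **ROI statistics** (mean/median) are computed over finite map voxels
  inside the mask only; even-count medians use midpoint averaging. The
  third array axis is axial by convention; masks and maps must share one
  geometry.
* **Caliper volume** `length × width²/2` reproduces the bench formula used
  to size engrafted tumors (enrollment at ~175 mm³).

## Response

Response rate is the percent change of a biomarker from baseline,
`100·(followup − baseline)/baseline`; percent (rather than fraction) is the
convention of waterfall-plot axes. Zero-baseline lesions, and subject/lesion
pairs missing a timepoint, go to an explicit exclusion list — never dropped
silently. Waterfalls sort ascending by response rate with lexicographic
subject-id tie-breaks; the two cohorts are ordered independently since they
are plotted side by side. Clinical response categories (RECIST 1.1,
mRECIST, RCB) are intentionally out of scope.

## On-treatment expression simulation

Per sample, four multiplicative factors are drawn i.i.d. uniform on
[0.5, 1.5] and fixed; each gene independently receives one of the four with
equal probability. Uniform draws and uniform assignment are the simplest
distributions consistent with a "4 numbers between 0.5 and 1.5, fixed per
sample" scheme. Each sample owns a child RNG stream spawned from the master
seed by position, so extending a cohort never perturbs earlier samples'
simulated values; the full factor matrix and per-gene assignment are
returned for audit, and the simulated table is bit-reproducible from
(T0, seed).

The squared T0–T1 correlation per sample (Pearson or Spearman; both
exposed, Pearson default) is reported as a diagnostic. On real count data
this scheme lands around r² 0.5–0.8; on synthetic data r² depends on the
count distribution's dispersion — the log-normal baselines generated here
are more dispersed than the factor perturbation, so r² runs higher (~0.85+).
Values outside [0.5, 0.8] therefore warn rather than fail.

Gene harmonization restricts two cohorts' tables to their intersection of
gene symbols, rows sorted lexicographically; an empty intersection is an
explicit error.

## Association

Spearman rho is computed as Pearson correlation of average ranks, vectorized
over genes, and verified against an explicit rank-then-correlate oracle to
1e−12. Two-sided p-values:

* **n > 9**: the usual t-approximation `t = rho·sqrt((n−2)/(1−rho²))` on
  n − 2 degrees of freedom.
* **n ≤ 9** (typical PDX arm sizes): exact permutation p by full
  enumeration of the n! sample relabelings. Since rho is an affine function
  of the dot product of the two rank vectors, only dot products are
  enumerated (a chunked matrix product), and the observed average-rank
  vectors themselves are permuted, so ties are handled exactly. The test
  suite confirms agreement with direct enumeration at n = 5.

Benjamini–Hochberg q-values are computed over all tested genes; raw p is
always reported alongside. Constant gene rows get rho = NaN and never enter
ranked lists; a constant feature vector is rejected. The top list holds
only positively associated genes (descending rho, ties by smaller p then
symbol) truncated at both `n_top` and the sign boundary; the bottom list is
the mirror image, so the lists are disjoint by construction. Cross-cohort
overlap intersects the two lists within the shared gene universe (warning if
universes differ). Feature deltas are `t1 − t0` or percent change
(zero-baseline subjects excluded with notice); the delta-expression mode
uses the absolute per-gene difference by default, passed as a signed frame.

## Synthetic cohorts

The phantom module generates what a prototyping-scale co-clinical study
produces, with the generating truth retained:

* **Geometry.** Axis-aligned ellipsoidal lesions digitized at voxel
  centers; patient lesions (semi-axes 10×8×6 mm, 1×1×2 mm voxels on a
  28×28×12 grid) and PDX lesions (4×3×3 mm, 0.5×0.5×1 mm voxels, 24×24×10),
  centered in the grid. Digitization error at these resolutions keeps mask
  volume within 2% of the analytic ellipsoid volume.
* **Diffusion.** Tumor voxels decay at the subject's truth ADC (drawn
  0.8–1.2 ×10⁻³ mm²/s at baseline), background at 2×10⁻³ mm²/s, S0 = 1000,
  additive Gaussian noise with σ = 20 (SNR 50 at b = 0) by default.
  B-values follow each cohort's protocol.
* **Enhancement.** 25 frames every 30 s: a flat 10-frame baseline
  (level 100), a partial rise, the peak (level 250) at 330 s, then linear
  monotone washout passing exactly through the level `L` at 690 s chosen so
  `(peak − baseline)/(L − baseline)` equals the truth SER — the curve
  inverts to the truth by construction, which is what makes zero-noise
  round-trip tests exact. Background voxels are flat (NaN in the SER map).
* **Response.** Default cohort 21 patients / 9 PDX, half responders.
  Responder volume change is uniform on [−60%, −30%] with ADC rising
  20–50% and SER falling 20–40% on treatment; non-responders sit at
  [−5%, +25%] volume change with stable ADC/SER. T1 semi-axes scale by
  `(1 + ΔV/V)^(1/3)`.
* **Expression.** 2,000 genes (log-normal baselines, underlying normal
  mean 4 ± 1, residual SD 0.8 on the log scale), 40 planted genes — 20
  positively and 20 negatively coupled to the subject's volume-change
  fraction with log-scale slope 4. The same planted panel carries the
  signal in both cohorts, so cross-cohort overlap of top/bottom lists is
  non-trivial. At these settings the planted genes rank within the default
  top/bottom-500 lists in ≥ 95% of seeded replicates (verified over 20
  replicates in the test suite).

What the phantoms do **not** emulate: partial-volume and chemical-shift
effects, motion, B0/B1 inhomogeneity, Rician (rather than Gaussian) noise at
low SNR, heterogeneous intratumoral parameter fields, realistic
arterial-input-driven enhancement kinetics, batch effects or library-size
variation in expression, and biological (rather than injected) coupling
between imaging and transcriptome. Passing round-trip tests therefore
demonstrates correctness of the estimators and plumbing under the stated
models, not robustness to real acquisition physics.

## Problem sizes and determinism

Test and example runs use the default 21 + 9 cohort with 2,000 genes —
comfortably the scale of the prototyping studies the tool targets — and the
full pipeline on that cohort completes in well under a minute on one CPU.
All randomness flows from NumPy `SeedSequence` spawning (one master seed per
run; child streams per subject and per sample), and all numeric output is
written with a fixed float format, so a rerun under the same seed is
byte-identical — this is asserted, not assumed, in the test suite.

## Known limitations

* The SER late-frame rule interpolates to the *nearest* frame rather than
  interpolating signal in time; on coarse temporal grids this quantizes
  S_late.
* The in-plane diameter underestimates lesions whose longest extent crosses
  slices; use `in_plane=False` where a 3-D diameter is wanted.
* DICOM support covers single-frame-per-file MR series with standard
  diffusion tags or a sidecar; enhanced multi-frame DICOM and DICOM-SEG
  writing are out of scope (masks are written as NIfTI).
* Exact permutation p-values are limited to n ≤ 9 (9! relabelings); beyond
  that the t-approximation is used, which is standard but approximate under
  heavy ties.
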