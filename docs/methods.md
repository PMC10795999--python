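# Methods

`loomsight` reimplements, as a tested library, the computational chain of a
collision-trajectory detection study: looming-stimulus geometry, low-level
stimulus diagnostics, psychometric and pupillometric inference, voxel-grid
permutation statistics, cross-validated ROI readout, and effective-connectivity
model search. Every stage is exercisable on synthetic cohorts produced by
`loomsight.synthgen`, so the whole pipeline is testable without any scanner or
eye-tracker data. This note records the models, the parameter choices that
matter, and the places where the design was genuinely open.

## Stimulus geometry (`stimgeom`, `study`)

A sphere of diameter *d* at viewing-axis distance *D* subtends
`2·atan(d/2D)` degrees; its remaining time-to-collision at approach speed *v*
is `D/v` (reported in integer milliseconds, rounded half away from zero, the
convention used for printed stimulus timings). Trajectories are straight 3D
segments from a start point to the would-be impact point, traversed at
constant speed; frames sample the visible window uniformly in time. Angular
positions are `atan(offset/distance)` relative to a cyclopean pinhole eye —
no binocular disparity is modelled. Sign convention: +x rightward, +y upward,
so upper-field quadrants have positive elevation.

**Centroid alignment.** Trajectory conditions within a quadrant are aligned by
rigid angular shifts so their image centers of mass coincide. The centroid of
a path weights each frame's disc center by the disc's image area
(∝ angular size²), i.e. it is the center of mass of the space-time luminance
volume. This choice is fixed by the published per-condition on-screen offsets:
with the 7T fMRI geometry the raw near-miss path spans 4.31→8.44°, and
area-weighted alignment moves it to 1.61→5.75°, matching the printed
1.70→5.87° to ~0.1° — uniform frame weighting would land ~2° away. The
residual ~0.1° is within the uncertainty of unstated display details. The
alignment target defaults to the across-condition mean centroid; passing an
explicit target (the designed stimulus eccentricity) reproduces the published
absolute positions.

**Rendering.** Discs are rasterized with a one-pixel linear coverage ramp
(anti-aliasing); defaults are 256×256 pixels, 12° field of view, 60 Hz. For
optical-flow diagnostics the Exp-2 pair is rendered fixation-centered at
0.25°/pixel (96 px over 24°): the late-trajectory edge displacements reach
~1.6°/frame, and this pitch keeps them within the few-pixel regime where
Horn–Schunck estimates are reliable. At much finer pitch the large
displacements saturate the estimator and the hit/near-miss ordering becomes
unstable.

**Trial schedules** are balanced by construction (every factor cell equally
often per run; run counts and ISI sets are arguments), seeded, and
bit-reproducible.

## Optical flow (`optflow`)

Classical Horn–Schunck (brightness constancy plus global smoothness): Jacobi
iteration with the original 2×2×2 derivative stencils and 3×3 neighbourhood
average, boundary handling by replication, deterministic zero initialisation.
Defaults `alpha = 1.0`, 100 iterations. The overall flow magnitude is the sum
over pixels of the *squared* vector modulus (u² + v²), and eccentricity
profiles integrate that quantity (or |luminance − background|) over concentric
rings around fixation and over time. Because the 2×2 stencils are anchored at
half-pixel offsets, mirror symmetry of the flow magnitude holds only up to
discretization (a few percent on smooth patterns). Exact alpha/iteration
settings of the original stimulus diagnostics are not published, so the
hit/near-miss comparisons are asserted as orderings, not values.

## Psychometric inference (`psychofit`)

Hit/miss responses follow `P(hit|x) = 1 − Φ((x − μ)/σ)` with *x* the
extrapolated impact offset in cm. The fit is binomial maximum likelihood over
(μ, log σ) by bounded quasi-Newton with a moment-based start and a small
multistart grid (tolerance 1e−12 on the objective). No lapse or guess
parameters are included. All-hit or all-miss data are non-identifiable and
flagged rather than rejected. The sensitivity statistic is `ln(1/σ)`; the
source renders it "ln(1σ)", which we read as ln(1/σ) per its accompanying
description of σ.

σ identifiability depends on probe placement: the study's four-point set
(0, 3 cm fixed; near/far miss placed adaptively at ~50%/~2% hit rate) is well
conditioned, whereas fixed saturating probes leave σ bounded only from above
whenever the 2%-point yields zero hits (probability ≈ 0.36 at 50
trials/level). The synthetic generator therefore emulates the adaptive
placement by default.

The paired-sensitivity test is an exact sign-flip permutation on the mean
difference (all 2^n assignments for n ≤ 20, seeded Monte Carlo with 10,000
draws and the identity included otherwise); p is the proportion of |null| ≥
|observed|.

## Pupillometry (`pupil`)

Fixed preprocessing order: linear interpolation of blink gaps → zero-phase
4th-order Butterworth low-pass (default 40 Hz; zero-phase so cluster timing
is not shifted) → baseline subtraction (−200–0 ms) → division by the
whole-trace SD (baseline-window SD available as an option). A gap spanning
the entire baseline flags the trial invalid. The condition comparison is a
cluster-length permutation test: pointwise paired t, clusters as maximal runs
with p < 0.05, null = maximum run length under within-subject condition
swaps (10,000 by default), add-one p estimates. Cluster *length* is the
statistic for time series, distinct from the cluster *mass* used on voxel
grids. Calibration note: with white-noise traces the length distribution
collapses onto tiny integers and the test becomes conservative by
discreteness; under autocorrelated traces (as pupil data are, AR(1) ρ≈0.9)
the empirical type-I error sits at the nominal level.

## Voxel and ROI statistics (`roistats`)

**HRFs.** Double-gamma kernels parameterized by peak/undershoot delay (gamma
mode), dispersion and undershoot ratio, peak-normalized, h(0)=0. Canonical:
peak 5 s, dispersion 1.0, undershoot 15 s, ratio 1/6. Subcortical: peak 4 s,
dispersion 0.9, undershoot 12 s, ratio 0.35 — a configurable stand-in for
the faster, narrower subcortical response; the exact parameters of the
kernel cited by the study are not printed, so these are defaults, not ground
truth.

**GLM.** OLS on HRF-convolved boxcar regressors (0.1-s microtime grid),
nuisance columns appended, intercept included; rank-deficient designs raise
with the offending columns named. Percent-signal-change scaling
(`100·(x − mean)/mean` per run) is applied upstream of the GLM.

**Cluster-mass SVC.** Within an anatomical mask: voxelwise one-sample t
across subjects; two-sided cluster-defining threshold at voxel p < 0.05
(the sidedness is unstated in the source; two-sided matches its "two-sided
design for all tests"); clusters by face (6-)connectivity (configurable to
18/26); mass = Σ|t|. Null: per permutation each subject's condition labels
flip at random *after* subtracting the group-average map from every subject
(demeaning), permutations flipping fewer than 15% or more than 85% of
subjects are discarded, and the maximum cluster mass is recorded; p-values
use add-one smoothing. The demean + exchange-fraction filter makes the null
slightly conservative (empirical type-I ≈ 0.03–0.05 at nominal 0.05).

**Cross-validation.** LOSO: per held-out subject, the ROI is the set of
voxels with uncorrected p < 0.05 and positive t for the effect computed from
the remaining subjects only; zero-spread voxels with nonzero mean count as
consistent evidence. LORO: per left-out run, voxels are selected on the
held-in runs (visually responsive at p < 0.05, or top-N by effect t; N = 10
matches the ~30 µl subcortical cluster scale at 1.5-mm voxels) and read out
on the left-out run. The circular variant (selection on the readout run) is
exposed behind an explicit flag solely to demonstrate its positive null bias
— the regression contrast in the test suite.

**ANOVA and corrections.** The 2×2 fully-within ANOVA is computed via
subject-level contrasts (for 2-level factors each F is the squared paired t;
ηp² = F/(F + df_error), algebraically identical to SS_effect/(SS_effect +
SS_error)); an independent implementation (pingouin) serves as the test
oracle. Post-hoc paired t tests (Cohen's d = mean difference / SD of
differences) are computed only when an effect is significant. Holm and
Benjamini–Hochberg adjustments wrap statsmodels. The robust outlier rule
computes FAST-MCD (scikit-learn MinCovDet) Mahalanobis distances and flags
points outside 1.5 IQR of the distance distribution.

## Beta series and path analysis (`pathnet`)

Trial-wise amplitudes come from a GLM with one HRF-convolved regressor per
trial; series are z-scored within each trajectory condition (removing mean
amplitude differences) before connectivity or path modelling; pairwise
connectivity is the second-level regression slope (equal to Pearson r for
z-scored series).

**Model space.** Candidate models over {SC, vmPul, VTA, VC, AttNet} are the
Cartesian product of slots: fixed common edges, three always-present
connections with free direction, and three connections with free direction
or absence — 2³·3³ = 216 models. The published figure defines the slot
identities only graphically, so the shipped default is a documented
reconstruction constrained by the printed counts: 216 candidates, and df = 2
with all optional edges present, which pins exactly two common edges. Default:
common vmPul→VC and VTA→AttNet; two-option SC–vmPul, SC–VTA, VC–AttNet;
three-option SC–VC, SC–AttNet, VTA–VC. All of it is overridable via
`ModelSpaceSpec`. Six bidirectional slots over five variables necessarily
admit some cyclic orientation combinations; all 216 are enumerated (matching
the published count), each flagged `is_recursive`, with an optional
`drop_cyclic` switch.

**Fitting.** Free parameters are the path coefficients and log-scale diagonal
residual variances; the ML discrepancy
`F = ln|Σ(θ)| − ln|S| + tr(S·Σ⁻¹) − p` with `Σ = (I−B)⁻¹Ψ(I−B)⁻ᵀ` is
minimised by quasi-Newton from B = 0, Ψ = diag(S), with jittered restarts;
χ² = (N−1)·F at the optimum, N being the concatenated trial count across
subjects. Indices use the standard definitions: CFI against the independence
baseline, GFI = 1 − tr((Σ⁻¹S−I)²)/tr((Σ⁻¹S)²), AGFI, PGFI = (df/(p(p+1)/2))·GFI,
RMSEA, and RMR as the RMS of the lower-triangle residuals. For recursive
models with diagonal Ψ the ML solution has a closed form (per-equation
regressions from S); the test suite uses that closed form as an independent
oracle against the numerical optimiser.

**Selection.** Models with PGFI below 0.1 are excluded, the survivors ranked
by AGFI (descending; non-converged fits last; lexicographic tie-break), and
alternate rankings (χ², CFI, GFI, RMSEA, RMR) are reported so
ranking-invariance of the winner can be checked. The source text says models
with PGFI "larger than 0.1" were excluded, but its own selected models print
PGFI = 0.133 — with five variables PGFI = (df/15)·GFI, so the printed
winners (df = 2) could only survive a *lower*-bound filter; the filter here
drops insufficiently parsimonious (near-saturated, low-PGFI) models, which is
the reading consistent with the printed results.

**Correlation FWE.** Across-subject correlation matrices are corrected by a
max-statistic permutation: per permutation each column's subject order is
independently shuffled and the largest |r| recorded; corrected p is the null
exceedance (floored at the uncorrected p). Pairwise robust outlier removal
precedes the observed correlations, matching the ROI-effect analysis.

## Synthetic cohorts (`synthgen`)

All generators are pure functions of (config, seed). Defaults mirror the
study scale: 20 subjects, 16 trials per condition cell, ISIs {8, 10, 12} s,
TR 2 s, 1.5-mm voxels on a 20×20×20 grid, behavioral cohort of 15 with 400
trials each, upper-field σ = 1.0 vs lower-field σ = 1.5 cm about μ = 6 cm
(the head edge), pupil constriction bump at 1,100 ms (width 250 ms) on AR(1)
noise (ρ = 0.95 at 1 kHz, rescaled to the working sampling rate), a 7-voxel
(~24 µl at 1.5 mm, the nearest discrete sphere to the ~30 µl cluster scale)
collision-sensitive cluster at Cohen's d = 0.7, and BOLD AR(1) ρ = 0.3.
Voxel noise is smoothed on a padded grid and cropped so the field is
stationary (no boundary variance gradient), then scaled so the across-subject
d of the hit−miss difference inside the cluster equals the configured target.
Beta series are drawn as x = (I−B)⁻¹e, e ~ N(0, Ψ), so their covariance has
the closed form the path fitter assumes.

What the generators do *not* emulate: pupil foreshortening and gaze
artifacts, physiological BOLD noise structure beyond AR(1) + drift, spatial
inhomogeneity of fMRI noise, lapses and response bias in behavior, and
inter-regional HRF differences. Passing tests therefore demonstrate that the
estimators and permutation schemes are correct and calibrated under their
assumed generative structure — not that the original empirical effect sizes
are recoverable from real data.

## Problem sizes and numerics

The test suite and the acceptance script run simulation-based checks at
reduced scale chosen to keep Monte-Carlo error acceptable: type-I error
rates use 400–1,500 simulated null datasets with 150–250 permutations each
(the analysis-facing defaults remain 10,000 permutations); voxel
calibrations run on 10³ grids with SC-sized (~100 voxel) masks; recovery
checks use N = 1,000–2,000 trials. Permutation p-values use add-one
estimates, so they are valid and lie in (0, 1]. Optimisers are
deterministic given the seed; SEM fits agree with the closed-form oracle to
≤1e−3 on all tested models.

## Known limitations

- The Fig-5c slot identities are a reconstruction (see above); a different
  assignment changes which 216 models are searched, though not the machinery.
- The subcortical HRF parameters are plausible defaults, not the cited
  kernel.
- Horn–Schunck underestimates displacements beyond a few pixels per frame;
  diagnostics are rendered at a pitch chosen for that regime.
- The exact sign-flip test is exact only up to n = `max_exact_n` (default 20);
  beyond that it is Monte Carlo.
- `fit_path_model` fits non-recursive models numerically but their ML theory
  (and the closed-form oracle) applies to the recursive subset.
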