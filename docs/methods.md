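# Methods

This note documents the models, numerical choices and simulation design
behind swaykit, in the order the pipeline applies them.

## Signal model and preprocessing

A trial is a quiet-standing recording of the centre of pressure (CoP) in
the medio-lateral (ML) and anterior-posterior (AP) axes together with the
two horizontal shear-force channels, nominally 120 s at 200 Hz.
Preprocessing is deliberately minimal and fixed in order: **decimation
first** (keep every k-th sample, k = fs/50, no anti-alias prefilter),
**then** a 4th-order Butterworth low-pass at 20 Hz. Plain sample-dropping
decimation can alias in principle; it is retained as the default because
postural sway carries essentially no power near the decimated Nyquist
(25 Hz), and an `antialias=True` option exists for data where that
assumption fails. Filtering defaults to zero-phase (forward–backward,
`sosfiltfilt`), which doubles the effective order but introduces no phase
lag — important because the decomposition compares CoP and force
sample-wise; a single-pass causal mode is available. Force channels are
filtered with the same settings by default (`apply_to_force=True`) so
equilibrium-point timing stays aligned with the CoP.

Tests verify the measured single-tone attenuation against the closed form
of the *digital* (bilinear-transform) Butterworth response,
|H(f)|² = 1 / (1 + (tan(πf/fs)/tan(πf_c/fs))^{2·order}); with a 20 Hz
cutoff at fs = 50 the analog prototype formula is badly wrong near
Nyquist, a point worth remembering when comparing filter specs across
packages.

## Sway geometry

*Sway path* is the summed Euclidean step length of the CoP trajectory.
It is sampling-rate dependent (it grows with fs for noisy signals), so
the pipeline computes it on the standardized 50 Hz signal and records fs
with every value.

*Sway area* is the prediction-ellipse area from the eigenvalues λ₁ ≥ λ₂
of the 2×2 sample covariance (denominator n−1):
area = π · c · √(λ₁λ₂). The default constant is the large-sample form
c = χ²₂(coverage) (5.9915 at 95%); a small-sample option uses
c = 2(n−1)/(n−2) · F₂,ₙ₋₂(coverage), which differs negligibly at the
n = 6000 points of a standard trial. Rank-deficient point clouds return
area 0 with a `degenerate` flag rather than raising. Both metrics are
exactly invariant under translation and rotation of the ML/AP frame
(the eigenvalue product is rotation-invariant), which the tests assert
to 1e-8.

## Rambling–trembling decomposition

The horizontal shear force vanishes when the body is momentarily aligned
over its support; these zero crossings are the instant equilibrium points
(IEPs). Each axis is decomposed independently against its own force
channel:

1. IEPs are every sign change of the force, located by linear
   interpolation; exact-zero samples are IEPs themselves, runs of zeros
   collapse to their midpoint, and float-coincident crossings (a
   near-zero sample between opposite signs) are merged so the sequence
   is strictly increasing.
2. The CoP value at each IEP instant is obtained by linear interpolation
   between the bracketing samples.
3. A **natural cubic spline** (zero second derivative at the ends)
   through the (IEP time, CoP value) knots, evaluated on the full time
   grid, is the rambling trajectory. The trial's first and last CoP
   samples are added as knots so the spline never extrapolates — cubic
   extrapolation beyond the outermost IEP diverges fast.
4. Trembling is the pointwise residual, so `cop = rambling + trembling`
   holds exactly by construction.

Degenerate inputs: an identically-zero force channel returns
rambling = cop, trembling = 0 with a flag; fewer than four knots falls
back to linear interpolation with a warning.

Both components are summarised by RMS, **demeaned by default**: RMS about
the trial mean measures variability rather than offset from the plate
origin. A `demean=False` flag exists since conventions differ across
labs; the choice is recorded in outputs.

## The metric battery and normality screen

Six metrics (area, path, ML/AP rambling RMS, ML/AP trembling RMS) × four
sensory conditions (eyes open/closed × base of support open/closed,
coded EOOB/EOCB/ECOB/ECCB) give 24 variables per participant. Each
variable — the whole metric × condition column, never per-observation
subsets — is screened with a Kolmogorov–Smirnov test and replaced by its
natural log when p < 0.05. The default engine is the Lilliefors
correction (statsmodels), because naive KS with estimated mean/sd is
anticonservative; the naive mode is available and the report records
which was used and what was transformed. Variables containing
non-positive values skip the transform with a warning.

## Mixed-design ANOVA

Each metric gets a 2 (Group, between) × 2 (Eye, within) × 2 (Base,
within) mixed ANOVA via the classical split-plot decomposition: the four
cells per participant are reduced to orthogonal contrast scores — the
participant mean, the eye difference (closed − open), the base
difference, and the eye×base double difference — and each stratum is an
OLS fit with sum-to-zero coding and Type-III model-comparison F tests.
The participant-mean stratum carries Group plus the covariates (weight
in kg, centred; race as a White/non-White sum-to-zero indicator, with
full multi-level coding available); each within stratum tests its
factor's main effect (the intercept) and the Group interaction against
the participant × factor error. With 2-level within factors each stratum
has a single contrast, so sphericity corrections are moot and the F
tests are exact under normality. Covariates stay in the between stratum
by default (they are participant-constant); `covariates_in_within=True`
carries them into every stratum, which changes within-stratum error df
by the number of covariate columns. Single-level covariates are dropped
with a warning.

Follow-up contrasts are estimated marginal means at covariate means:
within-group closed-minus-open differences for a Group×Eye (or ×Base)
interaction, and pairwise covariate-adjusted group differences for the
Group effect. Bonferroni adjustment is `min(1, raw · family size)` with
the family equal to the number of reported contrasts. A three-level
regrouping (clinical-medicated / clinical-unmedicated / control) feeds
the identical engine.

Calibration is tested empirically: over 10,000 exchangeable-null cohorts
each of the seven design effects rejects at 5.0% within Monte-Carlo
error. The balanced-design path is also held to an independent
cell-means split-plot oracle to 1e-10, and the covariate stratum to
statsmodels' Type-III ANOVA.

## Multiple Factor Analysis

The 24 variables form four condition blocks of six. MFA weights each
block by the inverse of its leading eigenvalue so no condition dominates
the global solution:

1. standardize every variable (mean 0, sd 1, ddof = 1);
2. compute λ₁ᵇ, the first eigenvalue of each block's standardized PCA;
3. scale block b's columns by 1/√λ₁ᵇ — equivalently, divide its inertia
   by λ₁ᵇ — so each block's isolated leading eigenvalue is exactly 1;
4. a global SVD of the weighted matrix gives eigenvalues, participant
   scores (U·S), variable loadings (reported as correlations between
   the original variables and the scores), per-variable contributions
   (squared right-singular-vector entries, summing to 100% per
   dimension), and partial projections of each block.

Adequacy uses the Kaiser–Meyer–Olkin measure (anti-image partial
correlations; overall and per block, with 0.60 the conventional floor)
and Bartlett's sphericity test. The number of interpretable dimensions
comes from **Horn's parallel analysis** run on the same
standardize-and-weight pipeline: 500 standard-normal datasets of
identical shape, 95th-percentile thresholds per rank, retention = the
leading consecutive observed eigenvalues above threshold; seeded and
deterministic. Retained loadings (two dimensions in the designed
analysis) are varimax-rotated.

Varimax uses Kaiser's pairwise planar rotations, whose per-pair optimal
angle has a closed form; sweeps repeat until the criterion gain drops
below 1e-6. Kaiser row-normalisation is on by default and row
communalities are preserved exactly. The earlier SVD-based fixed-point
iteration was abandoned after it stalled at saddle points for symmetric
two-factor configurations — the pairwise form matches a 0.01° grid
search of the criterion and statsmodels' rotation on random problems.
Rotated columns are sign-fixed so the largest-magnitude loading is
positive. Interpretation thresholds: |loading| ≥ 0.40 is substantial,
more than one dimension above |0.32| flags cross-loading.

Group comparisons: separate per-group MFA fits report each group's
variance share on the leading dimensions, and a one-way ANOVA of the
combined-fit dimension scores on group (with a permutation alternative)
tests score separation, reporting F, df, p and η².

## Synthetic cohorts

No real recordings ship with the package; the generator plants exactly
the structure the analysis assumes, with known ground truth:

- rambling r(t): band-limited Gaussian noise, 0–0.5 Hz (the central,
  visual/vestibular timescale), baseline RMS 4 mm ML / 6 mm AP;
- trembling τ(t): band-limited noise, 1.5–8 Hz (the peripheral,
  proprioceptive-reflex timescale), baseline RMS 0.8 mm ML / 1 mm AP;
- cop = r + τ exactly; force = −k·τ (+ optional noise) with
  k = 0.7 N/mm, a restoring spring toward the reference — so true IEPs
  sit exactly where the CoP crosses its reference and the decomposition
  can be held to the generator's truth (recovery within 5% RMS);
- sample sizes 49 clinical ("ASC") + 94 control ("NC"), 4 conditions,
  120 s at 200 Hz.

Band-limiting is an exact rFFT mask (DC excluded), so ≥99% of each
component's power lies inside its declared band and spectral-separation
tests have a sharp target. A mechanistic inverted-pendulum model was
deliberately not used: exact additive truth and exact IEP placement are
what the recovery tests need.

Effects are multiplicative on component RMS. Condition effects: eyes
closed inflates the slow component (×1.4 control, ×1.2 clinical — the
closed-eye inflation is larger in controls) and the fast component
×1.1; closed base inflates slow ×1.25 and fast ×1.3. Group effect: the
clinical group's fast component is ×1.3. Participants carry log-normal
latent amplitude factors shared across axes and conditions (slow sd
0.15 in both groups; fast sd 0.65 clinical vs 0.30 control) plus
per-trial log-normal jitter (sd 0.18). The shared latents are what give
the 24 variables their two-factor correlation structure (fast: path and
trembling; slow: area and rambling); the *dispersion* asymmetry — not
the ×1.3 mean shift, which standardization removes — is what gives the
clinical group its larger fast-dimension variance share (~8–11
percentage points at the default scale), mirroring the share asymmetry
the analysis is designed to detect. Covariates are drawn per group
(weight: normal with clinical mean 79.6 kg sd 26.7 vs control 69.4 sd
17.4, truncated to [40, 180]; race: White with probability 0.898 vs
0.608; medication: 28/49 in the clinical group only), so covariate
confounding is reproducible. `CohortSpec.null()` zeroes every effect for
calibration studies. All randomness derives from a single spec seed via
per-participant, per-condition substreams, so cohorts are bit-for-bit
reproducible.

What the generator does **not** emulate: non-stationarity and fatigue or
order effects across the fixed condition sequence, non-Gaussian heavy
tails, axis coupling, postural drift, and any mechanistic link between
force and CoP beyond the spring construction. Passing tests therefore
demonstrate correctness of the *pipeline* under the assumed signal
model, not robustness of the metrics to real-world violations of it.

## Simulation sizes in the test suite

Tests scale simulations to keep the suite fast while preserving what
each check measures: decomposition identity and recovery use 100 trials
of 20–30 s; the fast/slow loading structure uses three cohorts of 25+47
participants × 30 s; the per-group variance-share ordering uses 100
cohorts at the design's group sizes (49+94, which drive the sampling
noise of the share comparison) with 20 s trials at 100 Hz; ANOVA
calibration uses 10,000 metric-level null cohorts of 8+12 participants.
The acceptance script runs the full default study (49+94 × 4 × 120 s at
200 Hz) once, in about ten seconds.

## Known limitations

- Path length has no bandwidth correction; values are comparable only at
  a common sampling rate.
- The normality screen decides per variable; borderline variables can
  flip transform status across cohorts, which is reported but not
  stabilised.
- The mixed ANOVA is the classical univariate split-plot; random-slope
  mixed models are out of scope.
- MFA assumes complete cases across all 24 variables; participants with
  missing conditions are dropped, not imputed.
- Horn retention on the weighted matrix refers to MFA dimensions; it is
  not comparable to parallel analysis run on raw correlation matrices.
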