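# Methods

This note documents the models, conventions and design choices behind
`fpsa`, a pipeline for fixation-pattern similarity analysis (FPSA) of
fear-generalization experiments with a circular face continuum.

## The experimental design being modeled

Eight face stimuli sit at 45° steps on a circular perceptual continuum.
One face (the CS+) is paired with an aversive outcome during a
conditioning phase; the opposite face (180° away) is the never-reinforced
CS−. Free viewing is recorded in one baseline run and three
generalization runs of 120 trials each (1.5 s stimulus duration, 6 s
stimulus onset asynchrony, extended to ~12 s by null trials).

Trial orders for baseline/generalization runs are order-2 maximum-length
sequences over GF(11): the recurrence `s[n] = s[n-1] + 3·s[n-2] (mod 11)`
has a primitive characteristic polynomial, so the state sequence cycles
through all 120 nonzero pairs and every nonzero symbol occurs exactly 11
times per period (the zero symbol 10 times). The zero symbol is the null
condition; the ten nonzero symbols map to the 8 faces, the shock (UCS)
and an oddball via a seeded permutation. Excess UCS trials are randomly
pruned to 5 per run and oddballs to 1, pruned trials becoming nulls:
10 + 6 + 10 = 26 null trials, 8 × 11 face trials, 120 trials in total.
The m-sequence balances first-order condition transitions; which
occurrences are pruned is a seeded uniform choice (the design constrains
only the counts). The conditioning run (124 trials; CS+/CS− 25× each
plus 11 reinforced CS+ presentations) is a seeded shuffle, as it is not
sequence-optimized.

## The synthetic gaze generator

Each subject's gaze is a base fixation density over the 500 × 500-px
face window: a mixture of isotropic Gaussians at the left eye, right
eye, nose and mouth with Dirichlet-jittered weights and jittered
centers (idiosyncrasy), mixed with a 10% uniform floor representing
stray fixations. Condition-dependent exploration is carried by two
modulation maps `M_s` (specific: a left-eye/right-eye contrast) and
`M_u` (unspecific: an eye-region/nose contrast):

    p_θ ∝ max(0, base + g_s·cos(θ)·M_s + g_u·sin(θ)·M_u)

with θ the angular distance of the face from the subject's CS+. The
carriers are base-weighted contrast patterns made (i) zero-integral,
(ii) mutually orthogonal with equal L2 norm, and (iii) orthogonal to
the centered base density. (ii) and (iii) are what make the equal-gain
geometry *exactly* circular under the 1 − Pearson metric: without them
the base × modulation cross-terms make the distance of a condition pair
depend on its axis rather than only on its angular separation. The
common scale is set so that a gain of 1 drives the most-modulated pixel
of the base density exactly to zero; gains are therefore fractions of
the nonnegativity ceiling. Defaults: baseline `g_s = g_u = 0.5`
(circular geometry), post-learning `g_s = 0.85, g_u = 0.5` (anisotropy
along the adversity axis). These defaults were chosen once so that the
injected geometry is recoverable above fixation-sampling noise at the
study's trial counts (11 trials per condition per run, 3–6 fixations
per trial); the clipping in `max(0, ·)` never triggers at admissible
gains, so the documented deviation from pure additivity is a guarantee,
not an approximation.

Fixation counts per face trial are uniform on 3–6; durations are
log-normal (median 250 ms, shape 0.35), packed with 30-ms saccade gaps
and rescaled when they would overrun the 1.5-s stimulus. An optional
`effect_onset_ms` draws fixations starting before the onset from the
unmodulated base density — the ground truth for temporal-window tests.
Ratings and per-trial skin-conductance amplitudes follow the Gaussian
tuning model below, with additive Gaussian noise and a null-trial
baseline level in the SCR table.

The generator does **not** emulate: saccade dynamics or main-sequence
kinematics, tracker measurement noise and calibration error, blink/pupil
artifacts, center-of-screen landing biases, non-learner subpopulations
(all subjects share the effect size unless configured otherwise), or
temporal non-stationarity across runs. Passing tests therefore show
that the estimators recover the geometry they target under clean
sampling noise — not that they are robust to every artifact of real
eye-tracking data.

## FPSA conventions

- FDMs: 2D histograms over the centered 500 × 500-px window, smoothed
  with a Gaussian of 1° FWHM (σ = FWHM/2√(2 ln 2) = 12.74 px at
  30 px/deg; the kernel is truncated at the window edge and the map
  renormalized to unit sum — the crop already discards ~5% of
  fixations, and unit sum is the declared contract).
- Mean-pattern correction subtracts the across-condition mean map,
  separately per phase and subject. For n i.i.d. maps this forces the
  mean pairwise correlation to −1/(n−1), so the expected mean
  dissimilarity of unstructured corrected maps is 1 + 1/7 ≈ 1.143 — a
  useful null reference exploited in the test suite.
- Distance: 1 − Pearson on vectorized corrected maps. Matrices are
  re-indexed so the subject's CS+ occupies row/column 4 and the CS−
  row/column 8; aligned positions then correspond to signed angular
  distances (−135°, …, 0°, …, 180°).
- The generalization phase is computed per run and averaged on the raw
  1 − r scale, so baseline (11 trials/condition) and generalization
  (3 × 11) enter with matched signal-to-noise; Fisher z (atanh of the
  implied correlation) is applied only inside inferential tests.
- Element-wise phase comparisons are paired t-tests per matrix element
  on Fisher-z values, reported uncorrected with an optional Bonferroni
  switch downstream.
- MDS: metric SMACOF initialized from the classical (Torgerson)
  solution plus random restarts; quality is Kruskal stress-1.

## Similarity models

With `x_i` the signed angular distance of condition i from the CS+,
the circular similarity structure is `M ⊗ M` for `M = [cos x, sin x]`.
Predictors are sign-flipped into dissimilarity orientation so positive
weights mean separation:

    C_ij = −cos(x_i − x_j)      (circular)
    S_ij = −cos x_i · cos x_j   (specific axis)
    U_ij = −sin x_i · sin x_j   (unspecific axis)
    G_ij = −exp(−(x_i² + x_j²)/(2σ²)),  σ = 65°/2.3548  (CS+ attraction)

`C = S + U` holds identically, so the perceptual model (intercept + C)
is the equal-weights constraint of the adversity model (intercept + S +
U); the CS+ attraction model adds G. Anisotropy is `w_S − w_U`.
Predictors are left unnormalized; weights are comparable within this
convention only.

Subject-level fits are OLS on the 28-entry lower-triangle vector, with
Gaussian ML likelihood, BIC counting coefficients + residual variance,
and adjusted R². Group fits are linear mixed models (subject-level
random intercept + random slopes for every predictor, unstructured
covariance), estimated by maximum likelihood — not REML — because BIC
and likelihood ratios are compared across fixed-effect structures. A
singular random-effects covariance falls back to a random intercept
with a warning; if a variance hits the zero boundary and the solver
returns a non-finite likelihood, the pooled-OLS likelihood is used (the
exact degenerate limit). The phase × predictor repeated-measures ANOVA
is computed as orthogonal paired contrasts (each F(1, n−1) is the
squared paired t of its contrast), which is the exact decomposition of
the 2 × 2 within-subject design.

## Generalization tuning

Responses D(x) at x ∈ {0, ±45, ±90, ±135, 180}° are fitted with
`G(x) = α·exp(−(x/σ_G)²/2)` by maximizing the Gaussian likelihood of
the residuals; the residual sd is profiled analytically (σ̂² = mean
squared residual, floored at 1e−12 so exactly-interpolating fits stay
comparable), reducing the search to (α, σ_G). A 20 × 20 grid
(α ∈ [−2, 4], σ_G ∈ [10°, 180°]) seeds a Nelder–Mead refinement.
Competitors: a flat line (level only; the likelihood-ratio null) and a
binary boxcar with amplitude, offset and a discrete symmetric width
(CS+ only, CS+ ± 45°, CS+ ± 90° — the only boxcars an 8-point design
admits), compared by AIC with df 2 (Gaussian) vs 3 (binary).

The Gaussian is offset-free by default. The package deliberately does
not default to a free offset: on 8-point profiles the extra offset
parameter inflates the flat-null LR type-I rate to ~0.13 at nominal
0.05 and biases amplitude recovery by ~7%, whereas the strict form
calibrates (measured type-I ≈ 0.05, amplitude bias ≈ 2.5%). Profiles
with a genuine baseline level (ratings, fixation counts) are fitted
with `offset=True`; in that variant σ_G is restricted to the [10°,
180°] width range during refinement because σ_G → ∞ otherwise opens a
flat α/offset ridge and the parameters lose identifiability. Reported
df always follow the actual parameterization.

SCR preprocessing: per-trial phasic amplitudes are log-transformed
(log10(1 + amp)), averaged per condition (including null trials), and
z-scored within subject across all conditions and phases.

## Decoding

Single-trial FDMs are 10× block-mean downscaled (500 × 500 → 2500
pixels). Pixels are kept when mean/std > 0.075 across trials — the
operational formula, i.e. high-relative-variance pixels are discarded
(always-zero pixels drop out since their ratio is undefined). Features
are projected on the smallest number of principal components reaching
50% of the training variance. Linear SVMs (squared-hinge, l2, C = 1)
are evaluated with stratified 3-fold cross-validation; the pixel
filter, PCA and SVM are re-estimated inside every training fold, so
test data never touch any fitted statistic (verified by a bit-identity
audit under test-fold perturbations). PCA is fitted per training fold
rather than per run — the strictest reading that guarantees no leakage.
For interpretation, decoder weights w are converted to activation
patterns A = Σ_X·w (the encoding pattern consistent with the decoder),
back-projected through the PCA and pixel filter, z-scored, and averaged
across subjects sharing the same physical CS+ face.

## Spatiotemporal FPSA

Temporal: a 500-ms window stepped by 50 ms over the 1.5-s trial gives
(1500 − 500)/50 + 1 = 21 windows; a fixation belongs to a window iff
its start time falls inside it (unambiguous, no double-weighting of
long fixations; an overlap rule is config-selectable). Per window the
condition FDMs are rebuilt from the included fixations only and the
adversity model refitted per subject; windows with an empty condition
are flagged missing for that subject, never imputed. The rank variant
restricts to the k-th fixation instead. Widening the window to the full
trial reproduces the whole-trial fit exactly (tested).

Searchlight: a 30-px square window slides over the FDM grid at a
configurable stride (1 px by definition; coarser in tests, with
nearest-center upsampling) inside a mask covering the smallest pixel
set holding 90% of group fixation density. Mean-pattern correction is
re-applied locally within every window (mirroring the global pipeline
at patch scale), the 8 × 8 local dissimilarities are fitted with the
adversity model, and the weights are assigned to the center pixel.
Centers whose window leaves the grid are excluded (constant-area
comparability); degenerate windows (a zero-variance condition patch)
yield NaN. A searchlight spanning the whole grid equals the global fit
to 1e−10 (tested). ROI contrasts average each subject's anisotropy map
inside eyes/nose/mouth rectangles and run paired t-tests, uncorrected
with a Bonferroni column.

ROI geometry is a declared choice (an upper band spanning both eyes, a
central nose band, a lower mouth band, disjoint and config-overridable);
no canonical outlines exist for these stimuli.

## Stimulus calibration

The early-vision stimulus model is a quadrature Gabor bank: 5 scales ×
8 orientations, implemented as one-sided frequency-domain Gaussians
(bandwidth 0.3·f0, ≈1 octave) whose complex spatial response magnitude
is the channel energy. Channels are weighted by a band-pass contrast
sensitivity profile with mode 6 cpd and half-amplitude points at 1 and
12 cpd; those three constraints are asymmetric on a log axis, so the
weight is a two-sided log-Gaussian with separate flank widths. The 40
channel energies average into one representation per image; stimulus
dissimilarity is 1 − Pearson on vectorized energy maps, for consistency
with the FPSA metric. Stimuli are normalized to equal mean luminance
and RMS contrast first (with optional 400 → 1000-px bilinear resize and
a 1.4-px-FWHM smoothing). `calibrate_circle` embeds the dissimilarities
with metric MDS at 1–3 dimensions, reports stress-1 per dimensionality,
selects 8 stimuli at 45° spacing around the fitted circle, and — when
generator parameters are supplied — maps the ideal circle back to
parameter space with an affine least-squares fit. The original
stimulus set is not reproducible (it depends on proprietary face
renderings), so this module is validated on analytic geometries and on
the gaze generator's condition densities.

## Problem sizes

Unit and property tests run on a 100-px face window at 6 px/deg — every
geometric relation of the full-size window is preserved under this
scaling. The property suite uses: exact recovery at n = 74 subjects
(dissimilarity-level simulation); model recovery over 100 replicate
cohorts of 16 subjects; tuning calibration over 1000 null profiles and
222 tuned profiles; decoder calibration over 100 seeds of 66-trial
null sets; searchlight localization over 50 replicate cohorts of 8
subjects at stride 5; temporal-onset detection with 32 subjects and 3
generalization runs. The analysis scripts simulate a 12-subject cohort
as a worked example. These sizes are the package's desk-scale choices;
the estimators themselves carry no size assumptions.

## Known limitations

- Weights depend on the (unnormalized) predictor convention; only
  within-convention comparisons are meaningful.
- The mixed-model BIC counts covariance parameters naively (boundary
  estimates are not corrected), a standard but approximate choice.
- The Gaussian-vs-binary AIC comparison has limited resolution on an
  8-point design: a wide Gaussian mimics most of a ±45° boxcar, so
  single-subject discrimination is reliable only at high SNR.
- The 16 × 16 joint matrix's cross-phase block uses pooled-phase maps;
  cross-phase distances are descriptive (MDS input) and never tested.
- The V1 channel bandwidth and CSF flank shapes are principled
  defaults, not fits to psychophysical data.
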