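# Methods

`curiosync` re-implements, as a tested pipeline exercised on synthetic data
with known ground truth, the statistics used to study curiosity- and
incentive-motivated incidental learning of naturalistic video stimuli: a
behavioural arm (logistic mixed models, meta-analytic integration, a
confidence-cutoff sweep) and an imaging arm built on the intersubject
synchrony framework (pairwise ISC, IS-RSA, crossed-random-effects mixed
models, cluster/ROI thresholding). This note records the models, the
numerical choices, and what the synthetic data do and do not emulate.

## Behavioural arm

### Trial coding

Curiosity ratings (1–7) are mean-centred within subject, so the curiosity
effect is a within-person effect and the subject's average curiosity is
absorbed by the random intercept. The incentive manipulation is
effect-coded (−1 control, +1 incentive). Recognition outcomes are combined
with the 1–6 confidence rating: under cutoff *c* a trial counts as
remembered iff the answer was correct **and** confidence > *c* (strict
inequality; cutoff 0 reproduces plain recognition, cutoff 3 is the
high-confidence measure). Cued recall is a 0/1 outcome independent of
confidence. Trials with missing ratings or responses are dropped listwise
with a logged count.

### Logistic mixed model (gLME)

For a binary memory outcome of subject *i* on stimulus *j*:

    logit P(y_ij = 1) = b0 + b_c c_ij + b_g g_i + b_cg c_ij g_i
                        + u_i + v_j + s_i c_ij

with crossed random intercepts `u_i ~ N(0, σ_u²)` (subject), `v_j ~ N(0,
σ_v²)` (stimulus), and — in the `full` variant — uncorrelated per-subject
random curiosity slopes `s_i ~ N(0, σ_s²)`. Estimation is
Laplace-approximate maximum likelihood: for a candidate `(log σ, β)` the
random effects are profiled out by an inner Newton ascent of the penalized
log-likelihood, and the Laplace deviance (including the log-determinant
correction `log|Z'WZ + G⁻¹|`) is minimised by Nelder–Mead over
`(log σ, β)` jointly. Including β in the outer search matters: the joint
penalized mode attenuates the curiosity slope by several percent; the
implemented scheme agrees with an independent Laplace-ML implementation
(lme4's `glmer`, checked in the test suite via Rscript) to ~1e-4 in the
fixed effects and random-effect SDs on identical data. Rows are sorted to
a canonical (subject, stimulus) order before fitting, so estimates are
exactly invariant to input row order.

Standard errors come from the fixed-effect block of the inverse joint
Hessian at the optimum (conditional on the variance estimates), with
normal-reference two-sided p-values — the convention of standard GLMM
software. One calibration caveat is inherent to that convention and worth
stating: within-subject effects (curiosity, its interaction) test at
~3–5% under the null, but the *between-subject* incentive effect rejects
at ~7–8% even at 78 subjects, because its effective degrees of freedom
are the subject count and the subject-intercept variance is estimated
with ML-like downward bias (lme4's `glmer` behaves identically).
Between-group p-values near 0.05 should therefore be read cautiously; the
test suite asserts calibration for the within-subject curiosity test.
The inner Newton step assembles the crossed Hessian blocks directly by
`bincount` (all blocks are diagonals or subject x stimulus tables), so a
200 x 36 full-model fit takes ~20 s on one CPU. A fit is flagged *singular* when any
random-effect SD falls below 1e-4 (the optimiser floor is exp(−10));
non-convergence is warned about and flagged, never silent. `fix_sd` can
hold the SDs fixed (all-zero SDs reduce the model to plain logistic
regression, which the tests verify to 1e-3).

Per-subject curiosity slopes — the CMLE scores — are the fixed curiosity
effect plus the subject's conditional mode (BLUP analogue), mean-centred
across subjects. Whether the fixed effect is included is immaterial
downstream: the Anna-Karenina similarity built from the scores is
invariant to a common offset after centring. Shrinkage bounds how well
the scores can track the true subject slopes; the recovery test uses a
configuration whose theoretical ceiling `sqrt(σ_s²/(σ_s² + SE²))`
comfortably exceeds the asserted correlation.

### Meta-analytic integration and cutoff sweep

Per-collection coefficients are pooled by inverse-variance fixed-effect
meta-analysis: `b̄ = Σ(b/SE²)/Σ(1/SE²)`, `SĒ = 1/√Σ(1/SE²)`; odds ratios
are `exp(b̄)` with 95% CIs `exp(b̄ ± 1.96·SĒ)` (rounding to 2 dp happens
only in the report layer). No heterogeneity statistics and no
random-effects meta-analysis are provided. The cutoff sweep fits the same
gLME at every confidence cutoff 0..5, pools per cutoff, and regresses the
pooled log-odds on the cutoff by *unweighted* OLS (a weighted option
exists), with t-based inference on n−2 degrees of freedom. The regression
is checked against closed-form `(X'X)⁻¹X'y` exactly.

## Imaging arm

### Concatenation and lag

Each subject's run interleaves mock lead-ins, trick (stimulus) volumes,
fixations and rating periods, in per-subject pseudo-randomised order.
Volumes of no interest are dropped; trick volumes are regrouped into a
canonical stimulus order; the retained indices are shifted forward by an
integer lag L (the L volumes after each trick window stand in for its
first L), non-circularly — the post-trick fixation/rating window
guarantees availability, and the plan builder errors if a shift runs past
the end of an acquisition. With the package defaults (36 stimuli of 16/17
trick volumes) the concatenated series is 594 volumes long.

The lag is chosen by intersubject pattern correlation: at each candidate
lag, the spatial Pearson correlation of masked voxel patterns is computed
for every subject pair at every time point and averaged; the argmax lag
wins. The exact ISPC formulation is a package choice (time-point-wise
spatial correlation, averaged over time then pairs).

### Pairwise ISC

For every unordered subject pair and voxel, Pearson r over the
concatenated volumes, clipped to |r| ≤ 1−1e−7 and Fisher
z-transformed (the clip keeps z finite; the bias is negligible).
Zero-variance voxel series yield z = 0 with a logged count rather than
NaN, preserving the map geometry. Censored volumes are included as stored
by default (the zeroed-volume convention); `censor_policy="pairwise-drop"`
excludes volumes censored in either member of a pair. N subjects give
N(N−1)/2 maps — 1225 at N=50.

### Behavioural similarity

Trial-vector similarity (curiosity: centred ratings; memory:
high-confidence 0/1 outcomes, both in canonical stimulus order) is
pairwise Pearson r, Fisher z. Unique effects are obtained by residualising
one similarity on the other (OLS with intercept over pairs; a projection,
idempotent, residuals orthogonal to the covariate). Zero-variance trial
vectors (a subject who remembered everything) get pair similarity 0 with a
warning instead of dropping the pair. CMLE scores being scalar, their
similarity uses the Anna-Karenina form — the pair mean (s_i + s_j)/2 —
which encodes absolute position: a positive brain–behaviour effect means
high scorers are alike, a negative one means low scorers are alike.
Behavioural similarity is grand-mean-centred before interactions. Group
membership enters as a deviation code: +0.5 control / −0.5 incentive per
subject, summed per pair to {1, 0, −1}.

### Crossed-random-effects model (LME-CRE)

Pair observations are doubly dependent (each subject sits in N−1 pairs),
so each voxel's Fisher-z values are modelled as

    z_ij = x_ij'β + u_i + u_j + e_ij,  u ~ iid N(0, τ²), e ~ iid N(0, σ²)

with one shared τ² for both members (exchangeable subjects). REML
estimation profiles θ = τ²/σ² on a log scale with an explicit boundary
comparison at θ = 0 (where the fit is exactly OLS; boundary estimates are
reported as τ² = 0, not errors). The covariance `σ²I + τ²ZZ'` is handled
through the eigendecomposition of the N×N matrix Z'Z, so one design's
spectral precomputation is shared by all voxels and each candidate θ
costs O(N) per voxel; the fast path is tested against a dense-V REML
oracle at N=5 to 1e-8.

Inference: Wald statistics referred to a t distribution with
Satterthwaite-style degrees of freedom (delta-method variance of the
coefficient variance against the numeric REML information). This is the
package default rather than an option because subject-level regressors
(group codes, Anna-Karenina similarity) have effective df near N — not
near the pair count — and the plain normal reference is measurably
anticonservative at small N: under the null at N=20 the similarity z has
SD ≈ 1.05 and P(|z| > 3.29) ≈ 0.0037 instead of 0.001, while the
Satterthwaite reference gives 0.0005 (median df 17). `df_method="normal"`
restores the normal reference.

### Thresholding

Whole-brain: two-sided voxelwise p < 0.001, connected components under
first-nearest-neighbour adjacency (faces touch), labelled separately for
positive and negative statistics, retained at size ≥ k = 20 (the extent
rule is inclusive). ROI: Benjamini–Hochberg FDR at q = 0.05 over the ROI's
voxels, then the same NN1 clustering at k ≥ 5. The group grey-matter mask
includes a voxel iff it is GM in at least 50% of subjects (inclusive at
exactly half). In place of smoothness-based Monte-Carlo cluster
calibration, a permutation null is provided: whole subjects' behavioural
data are permuted (pair rows are not exchangeable — permuting subject
scores and rebuilding pair values respects the crossed dependence), the
voxelwise model is refitted, and the 95th percentile of the maximum
suprathreshold cluster size is returned as an extent threshold.

## Synthetic data

The behavioural generator draws ratings from a latent stimulus-appeal +
subject-bias + noise model discretised to 1..7, then memory outcomes from
exactly the gLME above; defaults (curiosity 0.084, incentive 0.155, no
interaction, subject/stimulus intercept SDs 1.0/0.8, slope SD 0.2, 36
stimuli) match the effect scale the pipeline is designed around.
Confidence comes from two categorical distributions conditioned on
correctness (monotone confidence–accuracy association by default); recall
uses the same linear predictor with its own (lower) intercept.

The fMRI generator writes, per voxel, a stimulus-locked signal shared
across subjects (delayed by an integer `true_lag_tr`, default 4), plus
subject-idiosyncratic signal and white noise spanning the session, in each
subject's own pseudo-randomised trial order with mock/fixation/rating
volumes interleaved. With unit amplitude scaling, expected pairwise ISC is
the variance ratio `sd_shared²/(sd_shared² + sd_idio² + sd_noise²)`.
Anna-Karenina structure is induced by scaling the idiosyncratic amplitude
with the subject's normalised score: direction `"negative"` (default,
matching the sign convention in which low scorers synchronise more) gives
high scorers more idiosyncratic variance; `"positive"` inverts it. There
is no HRF convolution beyond the integer-TR delay, no spatial
autocorrelation by default, no physiological noise, and no motion — so
passing tests demonstrate the statistics are implemented and calibrated
correctly, not that the pipeline is robust to realistic artefacts.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale as a deliberate design
point: voxel grids 4³–12³, 6–50 subjects, concatenated length 594, 20–200
Monte-Carlo replicates, 100-replicate type-I checks for the gLME at 30×36
trials. Optimiser settings: Nelder–Mead xatol 1e-5 on (log σ, β) for the
gLME with the random-effect SD floor exp(−10) and singularity threshold
1e-4; bounded scalar search on log θ ∈ [−12, 8] with xatol 1e-7 for the
CRE model. Fisher-z clip 1−1e−7. Ties and degenerate inputs: zero-variance
responses are flagged unconverged with p = 1; constant residualisation
covariates are an error (nothing to remove); duplicate cutoffs are an
error.

## Known limitations

Confidence intervals and p-values for the gLME are conditional on the
estimated variance components (as in standard Laplace GLMM software); the
meta-analysis is fixed-effect only; the LME-CRE assumes homoscedastic
residuals across groups and models no spatial dependence across voxels;
the permutation null permutes behavioural scores only (it does not
re-generate time series). The synthetic data's idealisations are listed
above.
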