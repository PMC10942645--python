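# Methods

## Task geometry

Stimulus locations live on the unit circle; polar angle is measured
counterclockwise from the rightward horizontal, up is +y. Each conflict
type is an axis with angle θ ∈ {90°, 67.5°, 45°, 22.5°, 0°} from the
horizontal; sin θ and cos θ are its spatial-Stroop and Simon loadings, and
conflict similarity between types is cos Δθ. One participant group sees
stimuli in the top-right/bottom-left quadrants and answers up with the
right key; the other group sees the mirrored quadrants and answers up with
the left key. These pairings are the only ones for which the two conflict
sources (direction vs vertical position, response vs horizontal position)
agree on which axis endpoint realizes a congruent or incongruent trial; any
other pairing is rejected as malformed. For the analysis, conflict type is
compared after mirroring all axes into the top-right quadrant ("rotated"
angles), while raw axial angles carry the stimulus-orientation confound;
the two coincide within a group and decouple across groups, which is what
the cross-subject analysis exploits.

One angular-level listing in the source materials reads 42.5° where the
isometric design requires 45°; the package uses 45° throughout.

Balanced sequences are Eulerian circuits on the complete directed graph
with self-loops over the 10 task conditions (Hierholzer's algorithm with
seed-shuffled adjacency): 101 trials per run, each of the 100 ordered
transitions exactly once. The scanner-length variant (2 × 170 trials) uses
constrained randomization with per-conflict-type counts in [64, 73]; the
genetic-algorithm sequence optimization used for hemodynamic efficiency is
out of scope because no hemodynamic model is fitted here. Trials are 2000
ms with a uniformly jittered 100–300 ms initial fixation; timing is carried
in the schedule but unused by the analyses.

## Behavioral generator and calibration

Trial RT = base + subject effect + per-type congruency cost (on incongruent
trials) + 0.5·g·cosΔθ·λ + subject×CSE-cell offset + repetition effect +
post-error slowing + Gaussian noise, where λ is the CSE loading (+1 for CI
and IC, −1 for CC and II), so the classic CSE contrast at similarity s
equals 2·g·s. Accuracy is Bernoulli with a congruency increment and an
analogous (much smaller) CSE term. Defaults (base 520 ms, congruency costs
60–100 ms with the blended types largest, subject SD 40 ms, trial SD 90 ms,
repetition benefit 15 ms, post-error slowing 30 ms, error rates ≈ 2.5–5.5%)
are chosen to produce exclusion fractions and effect sizes typical of this
paradigm.

The one-stage analysis z-scores the 60 per-subject cell means over the
pooled subjects × cells sample, so the standardized slope a generator
produces depends on every pipeline stage. Calibration is exact rather than
approximate: because the schedule is deterministic, each trial's keep
probability (errors, post-error, run-initial exclusions) and expected value
are known in closed form, so the expected *centered* cell profile — the
response-repetition centering mixes repetition-class means into cell means
and attenuates the CSE coefficient by a few percent — is computed exactly
as a linear function of the gain g. The pooled SD adds the subject and
subject×cell variances and the per-cell sampling noise E[σ²/n] with a
second-order 1/n correction (important at the 340-trial scale where cells
hold ~6 trials) and a 0.9734 variance factor for the ±3 SD outlier
truncation. The slope-vs-gain curve is then inverted with a root finder.
Validation over 60 independent seeds recovers 0.100 ± 0.002 (RT, 33
subjects), 0.158 ± 0.009 (ER) and 0.233 ± 0.006 (scanner-scale RT) for
targets 0.10 / 0.15 / 0.24.

Filtering order for RT: run-initial trials, errors, per-subject mean + 3 SD
or < 200 ms outliers (cutoff computed after error removal), then post-error
trials; ER keeps error trials and drops only run-initial and post-error
trials. The dependent-variable unit is per-subject cell means, and the
one-stage model places random intercepts and slopes on both participants
and the four CSE cells (independent variances). With only four CSE-cell
levels the random-slope variance is weakly identified; this inflates the
reported SE and collapses the Satterthwaite df toward ~3 whenever the
per-cell slopes differ (which the congruency-cost profile induces), but
leaves the fixed-effect estimate unbiased — recovery tests therefore
average estimates across seeds rather than trusting a single fit's SE.

## Mixed-model engine

`mixedlm` implements Gaussian linear mixed models in the profiled
penalized-least-squares form, with each random term a grouping factor
crossed with a small covariate design and one independent variance per
covariate (diagonal G; no intercept–slope correlations, a deliberate
simplification that none of the analyses here are sensitive to). All
cross-products are precomputed, so each deviance evaluation costs one q × q
Cholesky factorization; optimization is L-BFGS-B over the relative standard
deviations with multiple starts, and infeasible proposals are penalized.
Satterthwaite df use df = 2·Var(c'β̂)² / Var(Var(c'β̂)), propagating the
finite-difference Hessian of the (RE)ML deviance in the variance
components; boundary components are held fixed. REML is used for reported
effects, ML wherever BICs are compared. The engine is validated in the test
suite against OLS in the zero-variance limit, statsmodels MixedLM for the
random-intercept case, and R lmerTest (estimates, SEs, Satterthwaite dfs,
logLik, BIC) on a fixture dataset.

## Neural generator

Patterns are beta(s, r, c) = Σ_k w_k f_k(c, s) P_k + offset(c) + noise.
Component features: conflict space uses (cos θ_rot, sin θ_rot) so its Gram
matrix is exactly cos Δθ (or the matrix square root of any supplied 5 × 5
similarity model); orientation embeds the folded-angle cosine matrix over
all eight axial angles, which is indefinite and therefore diagonally loaded
just enough to reach PSD — off-diagonal similarities are untouched, so
empirical correlations follow the intended structure up to a monotone
rescaling; target, response and group are ±1 indicators; the distractor
components are the location's y and x coordinates; the congruency
interaction adds conflict-space signal on incongruent conditions only and
shares the conflict component's voxel directions. The voxel embedding is a
single orthonormal basis sliced per component and shared by all subjects:
cross-component leakage is exactly zero, per-component signal Grams are
exact, and cross-subject correlations inherit the latent structure — which
is what makes the RSA specificity checks sharp. Noise is drawn per
(subject, run) with a diagonal (default), identity or Toeplitz residual
covariance; the diagonal default gives the noise-normalization step real
work to do. An optional per-subject multiplier on the conflict-space weight
couples neural effect strength to a behavioral trait, which is how
brain–behavior correlation (screen criterion 3) is made realizable in
synthetic cohorts.

## Cross-subject RSA

Patterns are noise-normalized per run by the inverse matrix square root of
the (optionally shrunk) residual covariance, correlated across all
(subject, run, condition) entries, and all ordered cells whose row and
column subjects differ are kept (which also removes within-run cells),
Fisher r-to-z transformed and standardized — both steps toggleable, since
"z-transform" is ambiguous in common usage. Keeping both ordered copies of
each symmetric cell doubles every observation exactly; subject-level random
effects cannot absorb an exact twofold replication, so the fixed-effect
covariance is doubled after fitting (`replicate_correction`). With this
correction the one-tailed false-positive rate of every regressor is at the
nominal level across 100 null cohorts; without it, rates run near
2α√2-inflated levels. Random intercept, conflict-similarity, orientation
and group effects are crossed over row-subject and column-subject.

The region screen applies (1) Bonferroni across regions on the one-tailed
conflict-similarity p, (2) BH-FDR among survivors on the incongruent >
congruent interaction from the congruency-split model, and (3) BH-FDR on
the one-tailed p of the across-subject Pearson correlation between
per-subject conflict-similarity effects (fixed effect plus averaged
row/column conditional modes) and the behavioral similarity slope.

Model comparison swaps only the conflict-similarity regressor (the 5 × 5
model entry broadcast to all condition pairs of a type pair), refits with
ML on identical cells, and ranks by BIC; an incongruent-only variant
restricts to cells where both conditions are incongruent. The domain-general
model is the sign-flipped z-score of |cᵢ − cⱼ| over group-averaged RT
congruency effects (the 0–1 display scaling seen in figures is treated as
visualization only); it degenerates, with an explicit error, if all five
congruency effects are equal. Dimensionality is the participation ratio of
the 5 × 5 conflict-type-averaged similarity matrix; raw eigenvalues are
used by default (their squares handle signs) with a clipped-at-zero variant
also reported, since empirical matrices can be indefinite.

## Representational connectivity

Within-subject 40 × 40 RSMs (diagonal excluded, Fisher z) are regressed
region-on-region with random intercept and slope per subject. A candidate
is connected when its slope exceeds the largest control-region upper 95%
confidence bound (mean + 1.96·SE, strict inequality); the control set mixes
truly null regions and orientation-only regions without the congruency
boost. At the default cohort's signal-to-noise level the pattern-level
noise attenuates slopes heavily; the demonstration cohort therefore uses
noise SD 0.4, where shared-structure slopes (~0.65) sit in the regime the
empirical literature reports, while null-region slopes stay at zero.

## What the synthetic data do and do not show

The generators reproduce the *structure* the analyses consume — factorial
balance, transition counts, group counterbalancing, component similarity
geometry, noise covariance, brain–behavior coupling — with linear-Gaussian
signal and Bernoulli errors. They do not emulate hemodynamics, autocorrelated
GLM residuals, spatial smoothness across real voxels, RT distributions'
right skew, learning or fatigue. Passing recovery tests therefore
demonstrates correctness and calibration of the estimators under the
design's structure, not robustness to every property of real data.

## Problem sizes

Tests and the acceptance script run the behavioral recovery at the full
design sizes (33 subjects × 3030 trials; 35 × 340), averaging 30–80
simulation seeds per target. RSA-based checks use 8-subject cohorts with 40
voxels per region — the smallest scale at which the two groups, the
congruency split and the screen are all well-posed — with 100 seeds for
type-I calibration and 20 per generator for model identifiability.
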