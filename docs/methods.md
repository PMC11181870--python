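# Methods

`nephropep` implements a biomarker-discovery pipeline for diabetic kidney
disease (DKD) progression under renin–angiotensin-system inhibitor (RASi)
treatment: longitudinal eGFR trajectories define a controlled/uncontrolled
kidney-function label, urinary peptide intensities are screened against that
label, a cross-equation concordant peptide panel is selected, and an SVM
classifier over the panel is trained and evaluated by leave-one-out ROC
analysis. This note records the models, the defaults, and the judgment
calls.

## eGFR estimating equations

Four equations are implemented (`egfr` module), all returning
mL/min/1.73 m²:

* CKD-EPI 2009 creatinine:
  `141 · min(Scr/κ,1)^α · max(Scr/κ,1)^−1.209 · 0.993^Age · [1.018 if F]`
  with κ = 0.7 (F) / 0.9 (M) and α = −0.329 (F) / −0.411 (M);
* CKD-EPI 2012 cystatin C:
  `133 · min(Scys/0.8,1)^−0.499 · max(Scys/0.8,1)^−1.328 · 0.996^Age · [0.932 if F]`;
* CKD-EPI 2012 creatinine–cystatin (prefactor 135, exponents −0.601/−0.375/
  −0.711, age factor 0.995, female factor 0.969, α = −0.248 (F) / −0.207 (M));
* EKFC cystatin C (adult form):
  `107.3 · (Scys/Q)^−0.322` below `Scys = Q`, exponent −1.132 above, times
  `0.990^(Age−40)` for ages over 40. `Q` defaults to 0.83 mg/L for both
  sexes; whether a sex-specific Q should be used is not a settled convention,
  so it is a parameter (`ekfc_q`), not a hard-coded choice.

Units are fixed (creatinine mg/dL, cystatin mg/L) and never guessed;
non-positive or missing inputs raise typed errors rather than propagating
NaN. The optional Black race coefficient of the 2009/2012 equations is off
by default (European-cohort setting) behind a flag. The 2021 race-free
CKD-EPI refits and MDRD are deliberately out of scope.

The two single-analyte CKD-EPI equations are inverted analytically for the
simulator: each is a strictly decreasing piecewise power law of the analyte,
so the branch is chosen by comparing the target eGFR with the value attained
at the knot, and the round trip is exact to floating-point rounding
(tested at 1e−9 relative over random triples).

## Slope fitting and labeling

Per patient and per equation, eGFR is regressed on follow-up time by
ordinary least squares, either over the full follow-up or per consecutive
visit pair (`between_visits`; each pair is re-referenced so its intercept is
the fitted value at the interval start, and the summary is the arithmetic
mean of per-interval percentage slopes — the aggregation rule is not
dictated by any convention we know of, so it is isolated in one function).
The annualized percentage slope is `100 · slope / intercept`. The
denominator is the *fitted* eGFR at time zero rather than the observed
baseline: it is robust to baseline measurement noise and well defined for
every window; the observed-baseline denominator is available via
`denominator="baseline"` for sensitivity analysis.

Discovery labeling: percentage slope below −10 %/yr → UNCONTROLLED; within
[−5, +5] %/yr → CONTROLLED; the 5–10 %/yr loss zone and gains above 5 %/yr →
EXCLUDED (such patients cannot be assigned with confidence). Boundary
semantics are strict on −10 and closed on the controlled band; under
measurement noise the boundaries have probability zero, so this is a
documentation choice, not a scientific one.

Validation labeling (absolute rules used for external cohorts):
UNCONTROLLED requires losing more than 10 mL/min/1.73 m² from baseline
*and* progressing below 60 (CKD stage 3); CONTROLLED requires a total loss
under the cohort threshold (5 or 10 mL/min/1.73 m² depending on cohort)
with every value above 60. The loss is measured to the minimum follow-up by
default (most sensitive reading); measuring to the last visit is a flag.

## Peptide preprocessing

Intensities are non-negative with 0 meaning "not detected"; zeros are never
treated as small abundances. Normalization fits one multiplicative factor
per sample against internal-standard peptides: regressing the sample's
log-intensities of detected standards on reference log-intensities with
unit slope reduces to the intercept, i.e. the factor is exp(mean log-ratio).
The reference defaults to each standard's median log-intensity across
samples, making the operation self-contained and idempotent. Samples with
fewer than two detected standards pass through unscaled and are flagged.
The detection-frequency filter keeps a peptide when its nonzero fraction
reaches 30% (inclusive) in at least one of the two label groups.

## Differential screen

Per peptide: two-sided Wilcoxon rank-sum between uncontrolled and
controlled samples — exact null enumeration when the combined group size is
at most 25 and tie-free, otherwise the tie- and continuity-corrected normal
approximation (both via scipy's `mannwhitneyu`; an independent brute-force
enumeration oracle backs the exact path in the tests). Fold change is the
raw-scale ratio of group means with zeros included (a non-detection
contributes zero abundance); a zero controlled-group mean makes the fold
change undefined — the peptide is flagged and its direction taken from the
rank statistic, never silently dropped. No multiple-testing correction is
applied for selection (nominal significance is the selection currency at
these sample sizes); Benjamini–Hochberg q-values are reported as metadata
only. Spearman correlations between each peptide and the percentage slope,
and the between-equation agreement regression (r² of rho profiles,
restricted to peptides with rho p < .1 under both equations), complete the
screen.

## Panel selection and the SVM classifier

A peptide enters the candidate panel when at least three of the four eGFR
labelings find it nominally significant (p < .05) *with one shared
regulation direction* — the count is of the largest direction-consistent
subset of significant methods, so a lone significant method with the
opposite direction does not veto three concordant ones. This reading keeps
selection monotone in both the p-threshold and the method count (the
all-significant-methods-must-agree alternative is not monotone: relaxing
the threshold can bring in a conflicting method and silently drop a
previously selected peptide). A separate consistency filter keeps peptides whose
direction replicates across arbitrary additional cohorts/assessments.

The classifier is an RBF-kernel C-SVM at fixed hyperparameters C = 256,
gamma = 2e−5 (no hyperparameter search by design). Features are
ln(intensity + 1), z-scored per feature using training-fold statistics
only; the score is the signed distance to the hyperplane. Leave-one-out
(LOO) evaluation recomputes the standardization inside every fold, so the
held-out sample never leaks into its own score.

"Take-one-out" panel refinement is implemented as greedy backward
elimination: every round evaluates the LOO AUC of each single-peptide
removal, applies the best strictly-improving removal (lexicographically
smallest peptide id on ties), and stops when nothing improves. The round
therefore costs |panel| LOO evaluations, and the final panel's LOO AUC can
never fall below the input panel's. This is an interpretation — reasonable
alternatives (e.g. forward selection) are pluggable behind the same
signature.

Two implementation facts make the elimination loop affordable without
changing its results: a common mean shift cancels exactly in an RBF kernel,
so a LOO fold enters the kernel only through per-feature standard
deviations, and each feature's fold deviation does not depend on which
other features are in the panel. Per fold the weighted squared-distance
matrix of the full panel is therefore assembled once and each candidate
removal subtracts a single feature's contribution; the per-candidate kernel
is built by a fused numba loop and solved by libsvm through its low-level
entry point (same solver, tolerance 1e−3, as the public scikit-learn
estimator — an agreement test pins the two paths together to 1e−8).

## ROC evaluation and concordance

AUC uses the Mann–Whitney identity with midrank tie handling; its
confidence interval and the test against AUC = 0.5 use DeLong's
structural-component variance (the convention of clinical ROC software),
written in-house and validated by brute-force pair counting and a coverage
Monte-Carlo. With perfectly separated scores the DeLong variance collapses
and the CI degenerates to the point estimate.

Label concordance across equations reports, per label, Venn-style cell
counts over method subsets, plus the proportion of patients labeled
identically by all methods — with two denominators (all commonly labeled
patients, and patients no method excluded), since overlap statistics are
sensitive to that choice. Verification rates count discovery-significant
peptides re-found in a validation screen with the same direction
(optionally also p < .05 there).

## Synthetic cohorts

The generator (`simulate` module) emulates the structure of the target cohort data
so every stage has a parameter-recovery surface: ~200 patients (53% female,
baseline age N(67.5, 8) truncated to [30, 90]), one baseline urine sample
each, four roughly annual visits (intervals N(1.0, 0.2) years, floored at
0.1), baseline true GFR N(63.3, 16.8) truncated to [20, 120].

A latent decline status drives everything. True GFR follows
`GFR(t) = GFR0 · (1 + rate · t / 100)` — linear in time on the relative
scale. With the pipeline's percentage-slope definition (OLS slope over
fitted intercept) this makes the configured %/yr an *exact* parameter: a
noise-free decliner at −15 %/yr is recovered at −15 %/yr to regression
round-off. (An exponential trajectory would not have this property: its
OLS percentage slope at −15 %/yr true decay evaluates to about −13 %/yr
over 3 years.) Serum creatinine and cystatin C are back-calculated from
true GFR by inverting the CKD-EPI creatinine and cystatin equations at the
patient's visit age, then multiplied by log-normal noise with mean 1 and
the configured CV (default 5%, a typical assay-level imprecision). Because
only those two equations generate the markers, the combined CKD-EPI and
EKFC equations disagree with truth through noise and functional-form
differences — deliberately reproducing the between-equation labeling
discordance the pipeline is designed to study (including a small
deterministic drift under EKFC from its different age coefficient).

Peptides are zero-inflated log-normal: per-peptide mean log-intensity
N(10, 1.5), within-group SD 1.0 (so `effect_size` is a standardized mean
difference), detection Bernoulli with probability logistic in the mean
log-intensity (slope 0.35 per log unit, intercept calibrated numerically so
non-differential peptides average the configured base detection frequency,
default 0.7). Differential peptides (default 10% of the matrix) shift their
mean in decliners — 80% down-regulated, mimicking the collagen-fragment
depletion typical of progressive DKD, 20% up-regulated, mimicking
antitrypsin-like increases. The planted effect size is a free parameter of
the simulation, not an estimate of any real cohort's effect distribution.

What the simulator does *not* model: instrument-side artifacts (peak
migration, mass drift), correlated peptide blocks from shared parent
proteins, informative missingness beyond the abundance–detection link,
visit dropout, and medication changes. Passing recovery tests therefore
demonstrates the statistical machinery is correct and calibrated under the
stated generative model — not that the biological effect sizes of any real
cohort are attainable.

## Problem sizes and numerical choices

Tests and the acceptance script exercise cohorts of 200 patients × 500
peptides with 50 planted effects (recovery, calibration) and smaller
cohorts for orchestration checks; these sizes give stable statistics
(binomial SEs of a few percent) while keeping the elimination loop's
O(rounds × |panel| × n) SVM fits tractable on one core. Other fixed
choices: natural logs throughout; z-score denominators of zero replaced by
1 (constant features carry no information either way); SVM solver tolerance
1e−3 (libsvm default); exact Wilcoxon limited to tie-free pooled samples of
≤ 25; percentage-slope denominator guarded against a zero intercept
(infinite slope rather than NaN); all randomness flows from a single
integer seed per run through numpy Generators.

## Known limitations

* The "take-one-out" refinement and the internal-standard normalization are
  documented interpretations of under-specified procedures; both are
  isolated behind single functions so alternatives can be swapped in.
* DeLong inference degenerates under perfect separation (CI collapses to a
  point); a bootstrap fallback would be the next addition.
* Per-patient OLS is the only trajectory model — no mixed-effects shrinkage.
* The discovery screen is unadjusted for covariates by design.
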