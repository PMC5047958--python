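# Methods

This note records the statistical models implemented in `qifcal`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions that were genuinely open.

## Measurement model and calibration

Both platforms are assumed to measure an unknown true log-intensity
`mu_i` linearly, with independent errors:

    x_i = alpha_1 + beta_1 mu_i + e_1i ,   y_i = alpha_2 + beta_2 mu_i + e_2i .

This implies a linear relation between the platforms themselves and between
the paired differences `D_i = y_i - x_i` and averages `A_i = (x_i + y_i)/2`.
`ba_regression` fits `D = a + b A` by ordinary least squares;
`conversion_from_ba` inverts the algebra to the conversion equation

    y = a/(1 - b/2) + (1 + b/2)/(1 - b/2) · x ,

and `invert_calibration` gives the exact algebraic reverse map
(`alpha' = -alpha/beta`, `beta' = 1/beta`). When the reverse direction is
instead refitted from data the two differ at O(residual variance); on
noise-free affine platforms recovery is exact (unit-tested to 1e-9).
Limits of agreement are the fitted difference line ± z(level)·sd(residual)
using standard normal quantiles; the residual sd uses the n−2 denominator.
A single residual sd is used for the prediction band — no replicate-based
variance components, Deming or total-least-squares variants.

Scores are log-transformed with the **natural log**. The conversion
structure is base-invariant, so this is a documentation choice, not a
modelling one. Nonpositive scores are rejected (with the offending case
named) rather than offset-corrected, to avoid silently distorting the
log-linear model.

## Concordance statistics

Lin's concordance correlation coefficient uses n-denominator (population)
moments — the original estimator's form; n−1 variants shift the third
decimal at n ≈ 200, which matters when reporting to three decimals. The CI
applies the Fisher z-transform with Lin's asymptotic variance and
back-transforms; at |rho_c| = 1 the CI degenerates to the boundary point.

The replicate coefficient of variation is sd/mean per case (sd with n−1
denominator), aggregated as the root-mean-square across cases, ×100. RMS
aggregation is the convention under which the estimate is centred on the
generating per-run CV.

Cohen's kappa for the 2×2 cross-classification is computed via statsmodels:
the CI uses the large-sample standard error under the alternative, the
two-sided p-value the standard error under the null. When a rater never
uses one category the SE is uninterpretable and the CI is reported as NaN.

## Survival analysis

Recurrence-free survival runs from diagnosis to first recurrence; death
without recurrence, like loss to follow-up, is treated as censoring — the
reading consistent with "time to first recurrence" as the event of
interest. Kaplan–Meier, the multivariate log-rank test and the Cox model
are delegated to lifelines. Ties use Efron's method, the less biased choice
for the month-granularity ties clinical follow-up produces. Hazard ratios
are Wald-based with 95% CIs and two-sided p-values. Monotone partial
likelihood (complete separation) is detected as |coef| > 10 on the log-HR
scale and flagged, with the hazard ratio reported as infinite instead of a
spurious finite number.

## Data-driven cutpoints

Candidate thresholds are midpoints between consecutive distinct marker
values that leave at least `min_frac` (default 0.10) of the cohort on each
side; the threshold maximizing the two-group log-rank chi-square is
selected. This is the first-split criterion of a survival tree restricted
to a single split; full tree growth/pruning and multiplicity-adjusted
p-values are out of scope (the latter is a caveat for interpreting the
split statistic). "Low" includes the threshold (≤). The scan is vectorized
over candidates (an n × C at-risk matrix), making a full scan at n = 2000
sub-second; it is verified against per-split log-rank tests and is
rank-invariant by construction.

Cross-validation (default 10 folds, seeded fold assignment) re-derives the
threshold and the binary-covariate Cox effect on each training part and
accumulates the held-out deviance change 2·[ll(beta_train) − ll(0)] on the
test part (own Efron partial-likelihood implementation, reused as an
independent check of the Cox fit in tests). `cv_supported` is true when
the total held-out deviance improves. Under a null marker this is rarely
the case (simulated false-support rate ≈ 10% at the default settings);
under the study's effect size it essentially always is. CV is a support
check only — thresholds are never averaged across folds.

Percentile cutpoints use the ⌈pct/100·n⌉-th order statistic so that at
least pct% of cases fall at/below the threshold. Transfer of a threshold
between platforms is the conversion equation applied to the threshold.

## Time-dependent ROC

The cumulative-case / dynamic-control estimator with inverse probability of
censoring weighting: at horizon t, cases (observed event ≤ t) are weighted
by 1/G(T−), where G is the reverse Kaplan–Meier estimate of the censoring
survival on the pooled cohort; controls (followed beyond t) are
unweighted. Ties in the risk score contribute 0.5. This estimator was
chosen because it is consistent under independent censoring and reduces
*exactly* to the empirical rank AUC when censoring is absent, which makes
it testable against a brute-force pairwise count; with censoring it agrees
with scikit-survival's cumulative/dynamic AUC to machine precision (test
cross-check, not the implementation). The marker is protective, so the
negated marker is the default risk direction; AUC is invariant to strictly
increasing marker transformations, which is why no between-platform
calibration is needed for ROC analyses. No incident/dynamic variant, AUC
confidence bands, or formal AUC-difference test.

## Synthetic cohort generator

The generator defines the regime in which the pipeline's statistical
properties are demonstrated:

| parameter | default | rationale |
|---|---|---|
| latent mean, sd (log-units) | 2.0, 0.5 | lognormal raw intensities; linear log–log scatter between platforms |
| platform pair | identity vs `0.43 + 0.95·mu`, noise sd 0.05 | offset/slope disagreement of the magnitude seen between a microscope-based and line-scanner-based platform; noise level that yields post-calibration CCC ≈ 0.99 |
| low-group quantile | 0.20 | ≈20% marker-low prevalence |
| hazard ratio (low) | 3.7 | elevated recurrence risk of the marker-low group |
| baseline event rate | 0.003 /month | ≈35% event fraction over the follow-up window |
| censoring | uniform on 1–205 months | administrative censoring over the stated follow-up range |
| PR-negative fraction, HR | 0.16, 3.5 | a second prognostic covariate so the parsimonious two-covariate Cox model is identifiable |
| chromogen floor quantile | 0.875 | ≈87.5% of cases below the 1% detection floor of pathologist review |
| replicate CV | 1.0% | inter-operator reproducibility regime |

Latent values are normal on the log scale; event times exponential (the
simplest proportional-hazards-consistent generator). Chromogen scores are
integers in {0} ∪ [1, 95], mapped monotonically by latent rank among
positives. Operator replicates are each perturbed multiplicatively:
`rep_i = score·(1 + delta_i)`, delta independent per run, so that the
estimated replicate CoV is centred on the generating `cv_percent` (if only
one copy were perturbed the estimate would be centred on cv/√2 — each
operator's analysis carries its own noise, so both copies are noisy).
All operations are pure functions of (inputs, seed); platform noise streams
are keyed by (seed, platform id) so errors are independent across
platforms.

What the generator does **not** emulate: tissue-microarray spatial
structure, cell- or pixel-level image content, core-to-core heterogeneity
within a tumor, non-affine platform distortions, informative censoring, and
batch/staining-run effects. Passing tests therefore demonstrate the
statistical machinery under the assumed measurement and hazard model, not
robustness to those violations on real data.

## Problem sizes

The test suite exercises the calibrated regimes at the sizes the package
itself uses for validation: calibration recovery at n = 323 pairs
(200 replicates in the acceptance checks, 30 in the unit suite), cutpoint
recovery at n = 2000 (scaled to n = 800 in the unit suite), null
cross-validation behaviour at n = 300 with 20 replicates, Cox CI coverage
at n = 500 with 50 replicates, operator replicates at n = 336, and the
end-to-end pipeline at n = 323.

## Known limitations

* The difference-vs-mean fit uses OLS; no errors-in-variables correction
  is applied to the averages, which is adequate when the two platforms'
  noise levels are similar (as here) but biased when they differ greatly.
* The split-statistic of a data-driven cutpoint is maximally selected and
  its nominal p-value is anticonservative; the cross-validation flag, not
  the p-value, is the supported evidence summary.
* Kappa and agreement are reported for 2×2 tables only; no weighted or
  multi-category agreement.
* One score per (case, platform) is required; aggregation over multiple
  cores per tumor is left upstream.
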