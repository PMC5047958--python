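# qifcal

Cross-platform calibration, concordance and prognostic-cutpoint transfer for
continuous quantitative-immunofluorescence (QIF) biomarker scores.

## The problem

Digital pathology platforms score a tissue biomarker as a continuous mean
fluorescence intensity inside a molecularly defined compartment (for example
the cancer-cell nuclei of a tissue-microarray core). Two platforms measuring
the same tumors never agree exactly: each reports its own affine distortion
of the underlying signal plus independent noise. Before a prognostic
threshold derived on one platform can be used on another, the two scales
must be calibrated against each other and the residual disagreement
quantified — both on the continuous scale and on the dichotomized
(low/high) calls that drive clinical decisions.

`qifcal` is for biostatisticians and assay developers validating such
platform pairs. It implements:

* **Assay-comparison calibration** (extended Bland–Altman). With
  log-transformed scores, each platform measures an unknown true value
  linearly: `y_i = alpha_p + beta_p * mu_i + e_i`. The paired differences
  `D = y - x` are then linear in the averages `A = (x + y)/2`; from the OLS
  fit `D = a + b A` the conversion equation follows as

      y = a / (1 - b/2) + (1 + b/2)/(1 - b/2) * x

  with limits of agreement at the fitted line ± z·sd(residual).
* **Concordance statistics**: Lin's concordance correlation coefficient
  `rho_c = 2 s_xy / (s_x^2 + s_y^2 + (x̄ - ȳ)^2)` with its Fisher-z
  asymptotic CI; replicate coefficient of variation; percent agreement and
  Cohen's kappa for 2×2 cross-classifications.
* **Data-driven survival cutpoints**: the threshold maximizing the
  two-group log-rank chi-square over all admissible splits, with seeded
  k-fold cross-validation checking that the split reduces held-out Cox
  partial-likelihood deviance, and transfer of thresholds between platforms
  through the fitted conversion equations.
* **Survival analysis** of recurrence-free survival: Kaplan–Meier,
  log-rank, Cox proportional hazards (Efron ties, separation flagging).
* **Time-dependent ROC / AUC(t)** for the continuous marker under
  censoring (IPCW cumulative-case / dynamic-control estimator).
* A **synthetic cohort generator** producing paired platform scores,
  marker-driven survival, pathologist chromogen scores with a 1% detection
  floor, and operator replicates — so the entire pipeline is testable
  without access to the original tissue data.

## Worked example

```python
from qifcal import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(synthetic_n=323, seed=7))
print(bundle.to_text())
```

prints (abridged):

```
## Calibration
  TissueStudio = +0.44 +0.95 x AQUA
  AQUA = -0.46 +1.05 x TissueStudio
  ccc_before: 0.806 (95% CI 0.793, 0.818)
  ccc_after_forward: 0.990 (95% CI 0.988, 0.992)

## Agreement
  AQUA_native_vs_TissueStudio_transferred: agreement 95.7%, kappa 0.849 (0.772-0.926), P=1.54e-52
  AQUA_transferred_vs_TissueStudio_native: agreement 96.0%, kappa 0.894 (0.838-0.950), P=3.79e-58

## Outcome
  AQUA_native: frac_low 0.17, HR 2.84 (1.90-4.25), log-rank P=2.03e-06
  TissueStudio_transferred_from_AQUA: frac_low 0.17, HR 2.56 (1.69-3.86), log-rank P=0.000113
```

The synthetic cohort was generated with the second platform related to the
first by `0.43 + 0.95 x` plus noise (sd 0.05 log-units): the calibration
recovers that relation (`+0.44 +0.95 x`), calibration lifts the concordance
correlation from 0.81 to 0.99, the cutpoint found on one platform
classifies the other platform's cases with ≥95% agreement (kappa ≥ 0.85)
after transfer through the conversion equation, and the low-marker group
carries a significantly elevated recurrence hazard on both platforms.

The same analyses are available as CLI subcommands over delimited-text
tables (`qifcal simulate | calibrate | concord | cutpoint | survfit | roc |
report`); run `qifcal --help`.

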