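# wbconform

Image-based detection of the **woody breast (WB)** condition in commercial
broiler carcasses from conformational silhouette measurements.

Woody breast is a myopathy of the pectoralis major that hardens the fillet
and degrades meat quality; it is traditionally graded by manual palpation of
the deboned fillet (ordinal score 0–3 in half steps, score ≥ 2.0 = moderate
or severe, the "Yes" class). Because the affected breast grows wider and
rounder — most visibly at the caudal end near the keel tip — the condition
leaves a signature in the carcass silhouette that a line camera can see
before deboning. This package implements that detection chain:

1. **Silhouette morphometry** (`wbconform.geometry`). From a calibrated
   binary mask with the keel tip pointing down, eight measurements and four
   ratios are taken along the keel-tip → cranial-end axis:

   | | definition |
   |---|---|
   | M0 | breast length (cm) |
   | M1 | maximal cranial-half width ⊥ to the axis (cm) |
   | M2 | keel-tip offset, M0/5 (cm) |
   | M3 | width at distance M2 from the keel tip (cm) |
   | M4 | apex angle at the keel tip over the M3 chord (°) |
   | M5 | apex-triangle area (cm²) |
   | M6 | silhouette area on the keel side of the M3 chord (cm²) |
   | M7 | M6 − M5 (caudal bulge area, cm²) |
   | M8–M11 | M3/M1, M3/M2, M7/M5, M1/M0 |

2. **Binary logistic detection models** (`wbconform.logit`). Six candidate
   predictor subsets (`model1` = {M1, M2, M3} … `model6` = {M3, M11}) are
   fitted by maximum likelihood, Logit(p) = α + Σ βᵢ xᵢ, with in-house IRLS,
   Wald χ² inference and odds ratios OR = exp(β), in statsmodels style:
   a `BinaryLogit` model whose `fit()` returns a `BinaryLogitResults` with
   `params`, `bse`, `pvalues`, `odds_ratios`, `predict()` and `summary()`.

3. **Evaluation statistics** (`wbconform.metrics`). Misclassification rate,
   sensitivity (TPR), false-positive rate, specificity, rank-statistic AUC,
   Nagelkerke generalized R², RMSE and MAD of the predicted probability;
   a stratified 70/30 training/validation split over the four score bins
   {0–0.5, 1–1.5, 2–2.5, 3}; and the Spearman screen of M0–M11 against the
   ordinal score.

4. **Synthetic cohorts** (`wbconform.synthdata`). No image dataset is
   distributed, so a seeded generator reproduces the trial's structure:
   900 carcasses (high- vs standard-breast-yielding strains, 60/30 per
   sex × age cell, ages 6–10 wk), live weights per published cell
   parameters, ordinal scores from a proportional-odds latent model, and
   allometric breast dimensions deformed per unit of severity. Parametric
   silhouettes can be rendered to masks for end-to-end tests of the
   measurement chain.

5. **Study pipeline** (`wbconform.pipeline`). `run_study` screens, splits,
   fits and compares all six models, selects the working model (lowest
   validation MR, highest TPR tie-break), refits it by strain, sex,
   age, live-weight class (< / ≥ 3.402 kg) and strain × weight, and runs
   the prediction profiler on group-mean measurements.

## Worked example

```python
import wbconform as wb

cohort = wb.sample_cohort(wb.CohortConfig(seed=17))      # 900 carcasses
print(wb.spearman_screen(cohort).head(4).round(3))

train, val = wb.stratified_split(cohort, 0.70, seed=17)  # 630 / 270
res = wb.BinaryLogit.from_dataframe(train, wb.MODEL_SPECS["model1"]).fit()
print(res.summary())
print(wb.evaluate_fit(res, val).to_dict())
```

prints

```
                rs  pvalue      band
measurement
M11          0.726     0.0      high
M4           0.700     0.0      high
M9           0.700     0.0      high
M3           0.600     0.0  moderate

Binary logistic regression (model1)
  n = 630, log-likelihood = -151.4757 (null -300.8843)
  converged: True in 7 iterations

  Parameter     Estimate  Std. Error   Wald chi2   Pr > chi2          OR
  const          -8.0288      2.1643       13.76   0.0002076
  M1              1.6572      0.3353       24.42   7.728e-07       5.245
  M2             -7.8355      0.8824       78.85   6.706e-19   0.0003954
  M3              1.2826      0.4363        8.64    0.003283       3.606

{'n': 270, 'TP': 32, 'FP': 5, 'TN': 215, 'FN': 18, 'MR': 8.519,
 'TPR': 64.0, 'FPR': 2.273, 'specificity': 97.727, 'AUC': 0.92,
 'GenR2': 0.599, 'RMSE': 0.27, 'MAD': 0.144}
```

The width ratio M11 leads the correlation screen; in the fitted model the
odds of a woody carcass rise ~5.2-fold per cm of cranial width (M1) and
~3.6-fold per cm of caudal width (M3) while a longer keel-tip offset (M2)
sharply lowers them — on the validation split 91.5 % of carcasses are
classified correctly (MR 8.5 %) with 64 % sensitivity and AUC 0.92.

The same chain is available from the shell:

```sh
wbconform simulate --seed 17 --out cohort.csv --masks masks/ --cm-per-px 0.04
wbconform measure masks/*.png --out measured.csv
wbconform fit --model model1 --train cohort.csv --out fit.json
wbconform evaluate --fit fit.json --data cohort.csv --report report.json
wbconform study --seed 17 --out report/
```

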