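# heatmir

Milk FT-MIR based phenotyping of the individual heat-stress response of
dairy cows.

Heat stress depresses milk yield, protein % and milk minerals and raises
body temperature, but direct temperature recording does not scale and THI
alone ignores how individual cows actually respond.  `heatmir` implements a
routine-data alternative: predict each cow's heat-stress response from the
milk mid-infrared (FT-MIR) spectrum already collected at every milk
recording.  It is aimed at quantitative geneticists and dairy-phenomics
researchers who want a fully testable, end-to-end reference implementation
of this approach, exercisable on synthetic data with known planted effects.

## The method

1. **Heat load.**  Hourly THI = (1.8 T + 32) − (0.55 − 0.0055 RH)(1.8 T − 26),
   averaged per day; a test day's exposure `thi_td3d` is the rounded mean
   daily THI of the test day and the 3 previous days.
2. **Expected-performance residuals.**  A single-trait random-regression
   test-day model, y = Xb + Q(Z₁a + Z₂p) + e, with herd×year, month,
   lactation-class and DIM-class fixed effects and second-degree Legendre
   random regressions (genetic covariance A ⊗ G_a via Henderson's sparse
   A⁻¹), fitted by the mixed-model equations.  Standardized residuals of
   protein % and Mg expose heat stress free of systematic effects.
3. **Reference classes.**  On heat-wave visit days, a cow is *affected*
   (X1) when her udder surface temperature exceeds the farm's
   thermoneutral mean + 3 SD **and** both residuals are < −0.1;
   *non-affected* (X0) when below mean + 2 SD with both residuals ≥ −0.1;
   X0.5 otherwise.
4. **Spectral calibration.**  Gap-5 first derivative (1,056 values, points
   3–1,058), a 212-point low-noise region mask, |r| ≥ 0.3 pre-selection;
   then (a) PLS regression of surface temperature and (b) a two-stage
   random forest (importance top-50 + month-risk dummy) for X0/X0.5/X1 —
   both under 5-fold cross-validation grouped on cow-period so no
   cow-period is split between calibration and validation.
5. **Combination and population analysis.**  combined = 1 if predicted
   temperature ≥ 36 °C and class X1, 0.5 if ≥ 36 °C and X0.5, else 0.
   After filtering (HTD ≥ 10 records, DIM 5–365, milk ≥ 3 kg) the combined
   value is Snell-scored and analysed with
   y = HTD + lact + DIM(5 d) + milk(7 classes) + animal + pe + e,
   plus per-THI-class averages of the combined value.

Everything runs on synthetic multi-farm data generated by
`heatmir.simulate`, which plants heat-wave weather, trait depressions, a
spectral heat signature and susceptibility structure (parity 3+ > 2 > 1,
early-lactation peak) that the pipeline must recover.  See
`docs/methods.md` for the full model description and design choices.

## Worked example

```bash
heatmir run --seed 1 --outdir demo_run
```

runs simulate → thi → residuals → phenotype → preprocess → train →
predict → combine → analyze on the default configuration (5 farms × 70
cows × 2 years) and writes all CSV artifacts plus a manifest to
`demo_run/`.  From Python, at a smaller scale:

```python
from heatmir.pipeline import DEFAULTS, run_pipeline
import pandas as pd, json

cfg = dict(DEFAULTS, seed=1,
           simulation={"n_farms": 3, "n_cows_per_farm": 30, "n_years": 2},
           min_bin=50)
run_pipeline(cfg, "demo_run")

print(json.load(open("demo_run/models.json"))["pls_cv"])
print(pd.read_csv("demo_run/thi_summary.csv").tail(4))
```

prints (numbers from this exact run):

```
{'n_components': 3, 'r2cv': 0.9326, 'rmsecv': 0.3758}
    thi_td3d    n  mean_combined  mean_pred_temp
12        62  105       0.176190       36.774561
13        63  145       0.362069       36.971669
14        64   80       0.418750       37.199196
15        71   59       0.694915       38.630317
```

Reading: the PLS temperature model reaches a cross-validated R² of 0.93
(RMSE 0.38 °C) on the synthetic reference set, and the combined phenotype
averages near 0 for THI classes below 50 (not shown) before rising steeply
— 0.69 in the THI-71 class — exactly the planted population response.
`demo_run/population_solutions.csv` holds the population-model solutions; the
lactation-class solutions from this run are 0 / 0.14 / 0.37 (classes
1 / 2 / 3+), recovering the planted parity susceptibility ordering.

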