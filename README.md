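# hemocorr

Detection and individualized correction of hemolysis interference on serum
neuron-specific enolase (NSE).

NSE is a serum tumor marker for small cell lung cancer and neuroblastoma —
and it is abundant in red blood cells. Even hemolysis far too slight to see
by eye falsely elevates a serum NSE result, which can mimic relapse or
confuse diagnosis. `hemocorr` is a toolkit for clinical-laboratory
scientists and LIS developers that implements the full workflow around this
problem:

* **Hemolysis index (HI)** — quantify free hemoglobin from the bichromatic
  absorbance difference A570 − A600 (1 HI unit ≡ 10 mg/L Hb, integer range
  1–1000), establish nonparametric reference intervals (CLSI-style rank
  interpolation), and flag hemolyzed specimens (HI > 5).
* **Interference model** — fit the straight line `y = a·HI_meas + b` for the
  hemolysis-driven NSE increment *y* (μg/L) from a 23-pool × 11-aliquot
  RBC-lysate spike-recovery experiment, statsmodels-style:
  `HemolysisIncrementModel(...).fit()` returns a results object with
  estimates, standard errors, R² and a `summary()` table.
* **Individualized correction** — normalize the fitted coefficients by the
  spiking donor's NSE/HI lysate ratio *R* to get the transferable form
  `y = (a/R₀)·R·HI_meas + (b/R₀)·R`, then correct any patient using their
  own lysate ratio: `NSE_corr = NSE_meas − y` (clamped at the assay floor,
  0.05 μg/L).
* **Validation** — percent-difference Bland–Altman limits of agreement
  (mean ± 1.96·SD) against a ±20% total-allowable-bias rule, plus Spearman
  independence of residuals from HI.
* **Workflow** — an automated report-decision cascade (release / annotate /
  request-ratio / correct-and-report) gated on HI > 5, NSE > 16.3 μg/L, and
  clinical need (diagnosis purpose, or a >25% move in trend monitoring).
* **Simulation** — seeded generators for healthy-control cohorts, the full
  in-silico spiking experiment, and paired intentional-hemolysis validation
  cohorts with known ground truth, so everything above is testable without
  patient data.

## Worked example

```python
import numpy as np
from hemocorr import (NoiseModel, simulate_spiking_experiment, make_validation_cohort,
                      HemolysisIncrementModel, correct_nse,
                      bland_altman_percent, acceptability)

# 1. run the in-silico spiking experiment and fit the increment line
cohort = simulate_spiking_experiment(noise=NoiseModel(seed=0))
fit = HemolysisIncrementModel.from_cohort(cohort.frame).fit()
print(fit.summary())

# 2. personalize by the spiking donor's NSE/HI ratio and correct a specimen
pm = fit.personalize(0.31)
res = correct_nse(nse_meas=60.9, hi_meas=36, r=0.309, model=pm)
print(f"measured {res.nse_meas} -> corrected {res.nse_corr:.1f} ug/L")

# 3. validate on a paired intentional-hemolysis cohort
paired = make_validation_cohort(noise=NoiseModel(seed=0)).paired()
corrected = np.array([correct_nse(r.hemolyzed_nse, r.hemolyzed_hi, r.true_r, pm).nse_corr
                      for r in paired.itertuples()])
ba = bland_altman_percent(paired["baseline_nse"], corrected)
print(f"bias {ba.mean_diff_pct:.2f}%  SD {ba.sd_diff_pct:.2f}%  "
      f"LoA ({ba.loa_lower_pct:.2f}%, {ba.loa_upper_pct:.2f}%)  "
      f"acceptable: {acceptability(ba)}")
```

prints

```
NSE increment ~ HI (ordinary least squares)
x variable: hi_meas    n = 182    R² = 0.9926
                                coef     std err
slope (μg/L per HI)           0.3090      0.0020
intercept (μg/L)             -0.2432      0.4414
measured 60.9 -> corrected 50.1 ug/L
bias 0.64%  SD 5.66%  LoA (-10.46%, 11.74%)  acceptable: True
```

The fitted slope recovers the simulation's donor ratio (0.31 μg/L NSE per
HI unit): each HI unit of hemolysis drags roughly 0.31 μg/L of red-cell NSE
into serum for this donor. For the corrected patient, 10.8 μg/L of the
measured 60.9 μg/L was hemolysis artifact. On the 47-patient synthetic
validation cohort the corrected results agree with the pristine baselines
within (−10.5%, +11.7%) — inside the ±20% total allowable bias, i.e. a
corrected result is clinically interchangeable with a redraw.

The same steps are available from the shell:

```bash
hemocorr simulate spiking --seed 0 --out spiking.csv
hemocorr derive --cohort spiking.csv --donor-r 0.31 --out model.json
hemocorr correct --model model.json --nse 60.9 --hi 36 --r 0.309
hemocorr report --specimens specimens.csv --model model.json --out report.csv
```

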