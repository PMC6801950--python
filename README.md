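# aqews — air-quality early-warning system

Daily pollutant-concentration forecasting and fuzzy air-quality grading in
one package. The forecasting pipeline decomposes a concentration series
into intrinsic mode functions with ICEEMDAN (improved complete ensemble
empirical mode decomposition with adaptive noise), trains one
whale-optimized extreme learning machine (WOA-ELM) per mode, and sums the
per-mode forecasts. A fuzzy comprehensive evaluation (FCE) stage converts
the six criteria-pollutant concentrations (PM2.5, PM10, NO2, SO2, CO, O3)
of a day into an air-quality level I–V with an early-warning handbook entry
(category, colour, health condition, recommended measures).

Because real regulatory data cannot be redistributed, the package ships a
seeded synthetic generator that reproduces the marginal statistics of a
two-year Beijing record (per-pollutant mean/std, persistence, seasonality,
right skew), so every stage is testable offline.

## Worked example

```python
import numpy as np
from aqews import (HybridForecaster, SynthConfig, evaluate_day, generate,
                   metrics)

# simulate two years of daily PM2.5 and hold out the last 61 days
series = generate(SynthConfig(seed=0))["PM2.5"]
train, test = series.values[:-61], series.values[-61:]

model = HybridForecaster(ensemble_size=10, woa_iters=50, random_state=0)
model.fit(train)                      # -> 5 component models (4 IMFs + residue)
result = model.predict(61, actuals=test)   # rolling one-step forecasts
print(metrics(result.integrated, test))
# MetricReport(mae=15.10, rmse=19.73, mape=114.8, tic=0.2963, n=61)

# grade one day's six concentrations (PM2.5, PM10, NO2, SO2, CO, O3)
day = evaluate_day(np.array([55.0, 100.0, 60.0, 100.0, 3.0, 130.0]))
print(day.level, day.category, day.color)   # I excellent green
print(np.round(day.composite, 4))           # [0.2335 0.2335 0.  0.  0. ]
```

(The large MAPE is expected on a right-skewed series whose smallest values
approach zero; compare RMSE against the series std of 57.5.)

## Command line

```bash
aqews simulate --seed 0 --n-days 760 --out synth.csv
aqews train --csv synth.csv --pollutant PM2.5 --train-end 2018-07-31 \
            --out model.json
aqews predict --model model.json --horizon 61 --actual-csv synth.csv \
              --out pred.csv
aqews evaluate --pred pred.csv
aqews evaluate-fce --pred synth.csv --out levels.csv
```

## Package layout

| module | contents |
| --- | --- |
| `aqews.data_io` | CSV reading/writing, imputation, chronological split, lag windows |
| `aqews.decomposition` | EMD sifting, ICEEMDAN, exact reconstruction |
| `aqews.woa` | whale optimization algorithm (encircle/spiral/explore) |
| `aqews.elm` | `ELMRegressor`, `WOAELMRegressor` (sklearn estimators) |
| `aqews.hybrid` | `HybridForecaster`: decomposition + one WOA-ELM per mode |
| `aqews.metrics` | MAE/RMSE/MAPE/TIC, Diebold–Mariano test |
| `aqews.fce` | memberships, weights, Zadeh composition, level handbook |
| `aqews.synthetic` | seeded pollutant-series generator |
| `aqews.benchmark` | paired hybrid vs WOA-ELM vs ELM comparison |

## Reproduction

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the headline quantities (decomposition reconstruction error,
two-tone separation, optimizer convergence, ELM interpolation, the 20-seed
paired forecasting benchmark, metric closed forms, Diebold–Mariano null
calibration, FCE worked values and monotonicity count) from scratch and
writes them as JSON. `tests/test_acceptance.py` asserts the corresponding
criteria; see `docs/methods.md` for the modelling choices, the causal
forecasting protocol, and known limitations — including why the hybrid's
advantage over a plain ELM is small under a leak-free evaluation.
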