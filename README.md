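# biogasdlm

Self-learning simulation of full-scale biogas production from substrate
feeding, by distributed-lag time-series regression.

## The problem

Demand-oriented biogas plants need to know, hours to days ahead, how much gas
a planned feeding schedule will produce. Mechanistic digestion models (ADM1
and its simplifications) need dozens of biochemical parameters that full-scale
plants cannot measure. This package takes the opposite, data-driven route: it
uses only two signals every plant already logs — hourly solid-substrate
feeding X (kg h⁻¹) and hourly biogas production Y (m³ h⁻¹ at standard
conditions) — and lets the plant's own history identify the response.

The model is a distributed-lag linear regression

    Y_t = α + β₀X_t + β₁X_{t−1} + … + β_k X_{t−k} + ε_t

fitted by OLS on a rolling window of the most recent T observations. Because
it is refitted at every forecast origin, it tracks gradual changes in feed
composition and digester state by itself ("self-learning"). The right-hand
side contains only feeding, so an H-hour forecast from a planned schedule is
a direct evaluation — no recursion, no error accumulation mechanism other
than model aging.

The fitted coefficients carry physical meaning: β_j (m³ kg⁻¹) is the gas
released j hours after feeding one kilogram, so the lag profile of β is an
empirical gas-formation curve and its area is the specific biogas yield
realised within the lag window.

Because full-scale plant records of this kind are not publicly deposited, the
package ships a synthetic plant generator (`biogasdlm.synthetic`) that
reproduces the operating statistics of a research-scale digester — discrete
feedings totalling ≈6,000 kg d⁻¹, a gas-response kernel of 0.101 m³ kg⁻¹
with 62 % released within 12 h, baseline 45 m³ h⁻¹, Gaussian sensor noise —
and doubles as the ground-truth oracle for every test.

## Worked example

```python
import numpy as np
from biogasdlm import (PlantScenario, generate, ModelConfig, rolling_evaluate,
                       collect_coefficients, median_curve, auc_yield)

series, truth = generate(PlantScenario(seed=1))          # one synthetic digester-year
cfg = ModelConfig(lag_order=48, training_length=500, horizon=48)
runs = rolling_evaluate(series, cfg)                     # refit every 24 h, simulate 48 h

print(f"{len(runs)} rolling simulations")
print(f"mean MAPE : {np.mean([r.mape for r in runs]):5.2f} %")
print(f"mean RMSE : {np.mean([r.rmse for r in runs]):5.2f} m3/h")
print(f"mean MAE  : {np.mean([r.mae for r in runs]):5.2f} m3/h")

ensemble = collect_coefficients(runs)
curve = median_curve(ensemble)
yc = auc_yield(curve, window=curve.size,
               median_intercept=float(np.median(ensemble.intercepts)))
print(f"specific yield within 48 h : {yc.total:.3f} m3/kg "
      f"(generating kernel: {truth.kernel.sum():.3f})")
print(f"fraction released in first 12 h : {yc.fraction_by(12):.2f}")
print(f"median intercept : {yc.median_intercept:.1f} m3/h")
```

Output:

```
341 rolling simulations
mean MAPE :  6.23 %
mean RMSE :  5.18 m3/h
mean MAE  :  4.15 m3/h
specific yield within 48 h : 0.100 m3/kg (generating kernel: 0.101)
fraction released in first 12 h : 0.63
median intercept : 45.1 m3/h
```

Reading this: 341 times through the synthetic year the model was refitted on
its latest 500 hours and asked for a 48-hour forecast; on average its
percentage error against the (noisy) recorded production was ~6 %, on the
order of the 5 m³ h⁻¹ sensor noise the data carry. The ensemble median of the
lag coefficients integrates to 0.100 m³ kg⁻¹ — the generator's kernel total
recovered to 1 % — with 63 % of the gas in the first 12 hours, and the
intercept lands on the 45 m³ h⁻¹ baseline. (On real plant data, errors are
larger: real digesters are not exactly linear and drift with season and feed
composition.)

## Command line

The same stages are available as subcommands of `biogasdlm`:

```sh
biogasdlm synth --seed 1 --out year.csv --truth-out truth.yaml
biogasdlm ccf --input year.csv --max-lag 96 --out ccf.csv
biogasdlm evaluate --input year.csv --grid grid.yaml --out-long long.csv --out-wide table.csv
biogasdlm kinetics --input year.csv --config model.yaml \
    --out-quartiles quartiles.csv --out-cumulative yield.csv --plot boxplot.png
```

`grid.yaml` lists `T_set`, `k_set`, `H_set` (e.g. the canonical
{200, 500, 800} × {48, 72, 96} × {48, 96, 144} grid); `model.yaml` holds one
`ModelConfig` (`lag_order`, `training_length`, `horizon`, `regressors`).

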