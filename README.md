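# smite

Multivariate calibration of coral skeletal geochemistry to sea-surface
temperature (SST) and seawater pH, by truncated-SVD pseudoinverse
regression, with the pseudoproxy machinery needed to characterize the
method before trusting it on real cores.

## Who this is for

Coral paleoclimatologists who have measured several geochemical variables
along a core (Sr/Ca, δ¹⁸O, δ¹¹B, B/Ca, Li/Ca, Mg/Ca, U/Ca, Li/Mg, …) and
want a single calibrated reconstruction of SST or seawater pH that uses the
covariance of the whole variable field instead of one proxy at a time —
plus honest, Monte-Carlo-propagated uncertainties for it.

## The method

Calibration is the linear inverse problem

    A x = b

where *A* (t × p) holds the age-modeled coral variables, and *b* is the
climate target on the same monthly grid. Both sides are z-scored over the
calibration window. *A* is factored by singular value decomposition,
*A* = *U S Vᵀ*, and the model parameters come from the pseudoinverse

    x† = V S⁻¹ Uᵀ b

Optionally the *k* smallest singular values (and their singular vectors)
are **truncated** before inversion. This is exactly principal-components
regression: truncation trades a little in-sample fit for a large gain in
parameter stability, which is what makes coefficients transferable between
cores. The first two singular values are never truncated. Predictions are
`b̂ = (A_z x†)·σ_b + μ_b`, where the normalization statistics always come
from the calibration window.

Uncertainty is bootstrap Monte Carlo: at each iteration every proxy entry
and every target entry is resampled from a normal law centered on its
measured value with its 1σ uncertainty, the model is refit, and predictions
are stored. The per-time 95% band comes from the 2.5/97.5 percentiles; the
standard error of prediction (SEP) is the mean half-width of that band
divided by 1.96, averaged over the calibration window.

The package also ships:

- **Forward proxy-system models** — Sr/Ca thermometer, bivariate δ¹⁸O
  (SST + SSS), and the full boron system: pK_B(T, S), calcifying-fluid pH
  up-regulation, borate isotope mass balance, and their closed-form
  inverses (the classical univariate δ¹¹B → pH baseline).
- **A synthetic climate emulator** — monthly SST/SSS/pH with prescribed
  means, variances, trends (including a two-segment pH decline), an
  SST–SSS anti-correlation hit exactly by construction, and episodic
  freshening events that skew salinity left.
- **Experiment harnesses** — sweeps over measurement noise (white and
  AR(1)), calibration length, variable subsets, and truncation level, plus
  cross-core transfer of fitted parameters.

## Worked example

```python
import numpy as np
from smite import (EmulatorConfig, NoiseSpec, emulate_climate,
                   generate_pseudoproxies, fit_smite,
                   MonteCarloConfig, monte_carlo_sep)

climate = emulate_climate(EmulatorConfig(n_years=101, seed=7))
proxies = generate_pseudoproxies(climate, noise=NoiseSpec(gaussian_rsd_increment=0.5),
                                 seed=7)

window = ("1900-01", "1929-12")
model = fit_smite(proxies, climate["SST"], window=window)
print("x_dagger :", np.round(model.x_dagger, 3))

report = monte_carlo_sep(proxies, climate["SST"], window=window,
                         cfg=MonteCarloConfig(n_iter=1000, seed=7))
print(f"r = {report.r:.3f}   RMSE = {report.rmse:.3f} degC   "
      f"SEP = {report.sep:.3f} +/- {report.sep_ci:.3f} degC")
```

prints

```
x_dagger : [-0.378 -0.543 -0.091]
r = 0.966   RMSE = 0.491 degC   SEP = 0.374 +/- 0.021 degC
```

Read: with +0.5% RSD of measurement noise on all three pseudoproxies, the
multiproxy fit spreads its weight across Sr/Ca and δ¹⁸O (both
anti-correlated with SST, hence the negative coefficients), reconstructs
30-year calibration-window SST with r = 0.97 and half a degree RMSE, and
the propagated measurement uncertainty contributes ±0.37 °C (1σ) to any
single monthly estimate.

The same workflow is available from a shell:

```sh
smite simulate --years 101 --seed 7 --out-dir work/
smite calibrate --in work/pseudoproxies.csv --target work/climate.csv \
      --target-name SST --window 1900-01:1929-12 --out work/model.json
smite evaluate  --in work/pseudoproxies.csv --target work/climate.csv \
      --target-name SST --window 1900-01:1929-12 --out work/report.json
```

plus `sweep-noise`, `sweep-ar1`, `sweep-length`, `sweep-combos`,
`sweep-trunc`, `transfer`, and `run --config run.yml` for a fully
configured calibration.

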