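# Methods

This note documents the models implemented in `smite`, the choices made
where the design was genuinely open, and what the synthetic tests do and do
not establish about real coral data.

## The calibration model

The coral variable field *A* (t months × p variables) and the climate
target *b* are both z-scored over the calibration window (sample standard
deviation, ddof = 1). The model parameters are the pseudoinverse solution
`x† = V S⁻¹ Uᵀ b_z` from the thin SVD of the normalized window matrix.
Predictions for any record use the *calibration-window* mean and standard
deviation for normalization and back-transformation — never statistics
refit on the full record — so out-of-window reconstructions are genuine
extrapolations of the calibrated relationship.

Assumptions: each variable is linearly related to the target over the
calibration range; measurement noise is additive and Gaussian; the window
is long enough to estimate p coefficients (the fit warns when t < p and
refuses when the retained rank exceeds t). Nonlinear proxies must be
transformed by the user before entering the matrix — no link functions are
applied internally.

### Truncation

`k_trunc` removes the k smallest singular values and their singular-vector
pairs before inversion, capped at p − 2 (the two leading singular values
are never truncated). The truncated solution is identical to
principal-components regression retaining p − k components, which the test
suite verifies against an independent eigendecomposition oracle.

Numerical choices:

- Independently of `k_trunc`, singular values below `rtol·S_max`
  (rtol = 1e−10) are excluded from the inversion, so exactly collinear
  inputs yield the minimum-norm least-squares solution (a duplicated
  perfect predictor gets weights 0.5/0.5) instead of an exploding inverse.
- Equal singular values keep the ordering produced by the LAPACK SVD of
  the column-ordered input, so results are deterministic for a fixed input.
- Constant (zero-variance) columns are rejected with an error naming the
  variable rather than silently dropped: a zero-σ z-score is undefined and
  silent dropping would change the model dimension behind the user's back.
- A target not on the proxy grid is linearly interpolated in time; a
  monthly target already aligned passes through untouched.

### Truncation guidance

`suggest_truncation` recommends the smallest level that (a) retains less
than 70% of the singular-value mass (the empirical inflection point for
well-conditioned coral arrays; configurable) and (b) reduces the total
Monte-Carlo parameter uncertainty relative to the previous level. A flat
singular spectrum has no inflection and yields level 0, and the diagnostic
refuses square or underdetermined systems, where even the smallest singular
value can carry essential climate information.

## Uncertainty model

The standard error of prediction is bootstrap Monte Carlo (default 10 000
iterations): every proxy entry and every target entry is perturbed with its
1σ uncertainty, the model is refit at the same truncation level, and
predictions are stored. Per-time 95% bounds are the 2.5/97.5 percentiles of
the prediction ensemble (percentile method, not normal-theory intervals);
per-time SEP is the mean distance from the ensemble mean to the two bounds
divided by 1.96; the reported SEP averages per-time values over the
calibration window (switchable to the full record), with a 95% interval of
1.96 × their spread across the window. Proxy uncertainties are
variable-level scalars for synthetic data and per-entry standard errors for
real records when a per-entry sigma table is attached. The ensemble reuses
the reference model's truncation level; it never re-selects truncation
adaptively inside an iteration.

Target observational uncertainties default to 0.02 (°C, pH units, or psu),
the in-situ logger / CTD grade.

## Forward proxy models

- Sr/Ca (mmol/mol) = −0.0607·SST + 10.553, the canonical coral thermometer
  sensitivity (coefficient 1σ: 0.0090 and 0.292). The parenthesized
  uncertainties are carried as metadata; the forward map uses the means.
- δ¹⁸O (‰) = −0.22·SST + 0.27·SSS − 8.8839. The two slopes are the organic
  temperature slope and a basin-scale seawater δ¹⁸O–salinity slope; the
  constant offset places the series at a mean of −5.49 ‰ for the reference
  climate means (25.92 °C, 33.69 psu). Because calibration z-scores every
  column, the offset has no effect on fitted models — it only makes
  displayed values resemble coral aragonite.
- δ¹¹B (‰): seawater pH is up-regulated to calcifying-fluid pH by
  pH_cf = 0.49·pH_sw + 4.93 − 0.02·SST; pK_B comes from the empirical
  boric-acid dissociation fit in synthetic seawater (total scale,
  T in kelvin; strictly decreasing in both T and S); and the skeletal δ¹¹B
  follows borate/boric-acid isotope mass balance with δ¹¹B_sw = 39.61 ‰
  and fractionation factor α = 1.0272:

      f = 1 / (1 + 10^(pK_B − pH))
      δ¹¹B = (δ¹¹B_sw − (1 − f)·1000(α − 1)) / (f + (1 − f)·α)

  The closed-form inverse is implemented and exact to 1e−10 over
  pK_B ± 2; δ¹¹B ≥ δ¹¹B_sw or below the low-pH asymptote is a domain
  error. All pH values are on the total scale; no scale conversions are
  performed.

Baseline (analytical) 1σ uncertainties: Sr/Ca 0.009 mmol/mol, δ¹⁸O 0.1 ‰,
δ¹¹B 0.09 ‰.

### Univariate baselines

The Sr/Ca → SST baseline is classical calibration: the proxy is regressed
*on* the climate target over the window and the fitted line is inverted.
This direction puts the measurement error on the regression's response
side, so heavy proxy noise widens the inverted predictions (SEP grows
linearly with noise) instead of attenuating the slope toward a spuriously
tight mean-reverting estimate — the behavior a practitioner expects from a
single-proxy thermometer. The δ¹¹B → pH baseline is mechanistic: mass
balance inverted at the pK_B implied by observed SST and SSS, then the
calcifying-fluid up-regulation is undone.

## Synthetic climate emulator

The emulator produces monthly SST, SSS, and pH over a configurable span
(default 101 years from 1900-01) and emulates the statistical structure of
a 20th-century western Coral Sea record:

| series | construction | matched statistics |
|---|---|---|
| SST | seasonal harmonic (amp 2.5 °C, austral-summer peak) + AR(1) interannual term (φ = 0.85) + linear trend | mean 25.92 °C, sd 1.91, OLS trend 0.08 °C/decade — all matched *exactly* by detrending/rescaling the stochastic part |
| pH | two-segment trend (−0.004/decade before 1950, −0.014 after) + SST-coupled AR(1) anomaly (target coupling r = −0.85 on the anomaly component) | mean 8.16 exactly; sd ≈ 0.03 |
| SSS | lagged seasonal + AR(1) background + Poisson-timed, gamma-magnitude freshening excursions with 2-month recovery | mean 33.69 psu and sd 0.43 exactly; sample corr(SST, SSS) = −0.68 exactly (mixing coefficient solved per realization); negative skewness |

Noise convention: a noise increment of x% RSD adds Gaussian noise with
1σ = x% of the variable's long-term mean, on top of the baseline
analytical σ (so +0.1% on Sr/Ca with mean 8.98 adds 0.009 mmol/mol, and
+1.9% brings the total to ≈ 0.180). AR(1) noise scales its innovations by
√(1 − φ²) so the marginal sd is independent of φ.

What the emulator does **not** reproduce: the exact extremes and spectral
details of the original reanalysis series (the pK_B and δ¹¹B ranges are
therefore matched only to within a few hundredths), ENSO-like
quasi-periodicity, age-model error, and any nonlinearity between proxies
and climate. Passing synthetic tests therefore demonstrates correctness of
the calibration machinery and its qualitative noise behavior, not skill on
real corals.

## Experiment harnesses

In the noise experiments the proxy *values* stay idealized; the noise
increment raises each measurement's 1σ, which the Monte-Carlo ensemble
propagates into confidence bands, SEP, and parameter spread. Consequently a
cell's minimum RMSE is the skill of the mean-value reconstruction (the
no-noise limit reachable with unlimited repeat analyses) and its maximum
RMSE averages the skill of the upper- and lower-band reconstructions.
Under this design, autocorrelated noise of fixed marginal sd shows up
almost entirely as *parameter* instability at high lag-1 values (φ > 0.9)
rather than as wider prediction bands, consistent with red noise mimicking
slow climate-like structure.

The calibration-length sweep uses the first N years of the record
(configurable to the last N or a random block — which segment the
experiment should use is not determined by the method itself). Subset
enumeration is deterministic: by size, then lexicographic by variable
name. Per-cell seeds are derived from the master seed through a seed
sequence, so every sweep is bit-reproducible.

Cross-core transfer applies a donor core's x† to a receiving core. By
default the receiver is z-scored with its *own* window statistics
(`stats_mode="receiver"`), which makes the transfer a test of coefficient —
not unit-scale — reproducibility; `stats_mode="donor"` applies the donor's
stored statistics instead. The two modes differ whenever the cores' means
or variances differ, and the choice is surfaced prominently in the API.

## Bundled fixture

`smite.io.make_fixture` builds a deterministic 40-month (June 2010 –
September 2013), 7-variable synthetic coral dataset: the three mechanistic
pseudoproxies plus four elemental-ratio variables (B/Ca, Li/Ca, Mg/Ca,
U/Ca) constructed with prescribed loadings on standardized SST and pH and
independent noise, in plausible native units with LA-ICP-MS-grade
analytical σ. The shipped CSVs regenerate bit-identically from the stored
seed; ground-truth climate is included. It is synthetic by construction
and stands in for unreleased reef records.

## Problem sizes

Default test and script sizes were chosen so the whole suite exercises the
full pipeline at desk scale: Monte-Carlo cells in tests use 120–2000
iterations (the library default is 10 000), sweeps in tests run on 20-year
emulations or the 40-month fixture, and the noise-sweep acceptance check
runs the full 20-increment grid on a century of climate at 1000 iterations.

## Known limitations

- One target per model; no joint multi-target fitting.
- No internal variable transformations; linearity is the user's
  responsibility.
- No full carbonate-system solver: pH enters as a series, never computed
  from pCO₂/alkalinity.
- The SEP is Monte Carlo only; no analytic (delta-method) approximation is
  provided.
- Truncation guidance is a heuristic; on systems whose trailing singular
  values carry real climate information it will under-truncate or
  mis-recommend, and users should inspect the per-level diagnostics it
  returns rather than trust the single recommended integer.
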