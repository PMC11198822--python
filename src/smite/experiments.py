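"""Pseudoproxy experiment harnesses: noise, autocorrelation, calibration
length, variable combinations, truncation, and cross-core transfer.

All sweeps are pure functions of their inputs and a master seed.  In the
noise experiments the pseudoproxy *values* stay idealized (the measured mean
is assumed to carry the true relationship); what grows with the noise
increment is each measurement's 1-sigma uncertainty, which the Monte-Carlo
ensemble propagates into confidence bounds, SEP, and parameter spread.  The
minimum RMSE of a sweep cell is therefore the skill of the mean-value
reconstruction, and the maximum RMSE averages the skill of the upper- and
lower-confidence-bound reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .climate import NoiseSpec
from .core import (
    ClimateSeries,
    ProxyMatrix,
    SchemaError,
    SmiteModel,
    fit_smite,
    predict,
    resample_to_grid,
    zscore,
)
from .forward import d11b_baseline_phsw, generate_pseudoproxies, pseudoproxy_sigmas
from .metrics import (
    EvalReport,
    MonteCarloConfig,
    _perturb_refit_ensemble,
    _sep_from_predictions,
    evaluate,
    rmse,
)

__all__ = [
    "SweepResult",
    "sweep_noise",
    "sweep_ar1",
    "sweep_calibration_length",
    "sweep_combinations",
    "sweep_truncation",
    "cross_transfer",
]

#: Baseline target for each reconstructed climate variable: the classical
#: univariate estimator it is compared against.
BASELINE_PROXY = {"SST": "SrCa", "pH_sw": "d11B"}


@dataclass
class SweepResult:
    """Tidy result of one experiment sweep.

    ``table`` holds one row per (grid value, target, method) with skill
    columns; ``params`` holds the model-parameter trajectories (ensemble
    mean with 95% CI) where the sweep computes them; ``manifest`` records
    configuration and seeds for reproducibility.
    """

    param_name: str
    grid: list
    table: pd.DataFrame
    params: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _cell_seed(master: int, idx: int) -> int:
    """Deterministic per-cell seed below 2^31 derived from the master seed."""
    return int(np.random.SeedSequence([master, idx]).generate_state(1)[0] % (2**31))


def _mc_cell(A, b, window, k_trunc, cfg, noise_phi=0.0):
    """Shared per-cell computation: point skill, band RMSEs, SEP, parameters."""
    ref, x_draws, preds, b_grid, in_win = _perturb_refit_ensemble(
        A, b, window, k_trunc, cfg, noise_phi=noise_phi, store_predictions=True
    )
    _, lo, hi, sep_t = _sep_from_predictions(preds, cfg.tail)
    truth = b_grid.data.to_numpy(dtype=float)
    point = predict(ref, A).data.to_numpy(dtype=float)
    r_val, _ = evaluate(
        pd.Series(point[in_win], index=A.times[in_win]),
        pd.Series(truth[in_win], index=A.times[in_win]),
    )
    rmse_min = rmse(point[in_win], truth[in_win])
    rmse_max = 0.5 * (rmse(hi[in_win], truth[in_win]) + rmse(lo[in_win], truth[in_win]))
    sep = float(sep_t[in_win].mean())
    sep_ci = float(sep_t[in_win].std(ddof=1) * 1.96)
    tail = cfg.tail
    params = pd.DataFrame(
        {
            "x_ref": ref.x_dagger,
            "x_mean": x_draws.mean(axis=0),
            "lo95": np.percentile(x_draws, tail, axis=0),
            "hi95": np.percentile(x_draws, 100 - tail, axis=0),
        },
        index=ref.variables,
    )
    return {
        "r": r_val,
        "rmse_min": rmse_min,
        "rmse_max": rmse_max,
        "sep": sep,
        "sep_ci": sep_ci,
    }, params


def _univariate_inverse_cell(A, var, b, window, cfg, noise_phi=0.0):
    """Monte-Carlo skill of a classical-calibration univariate baseline.

    The proxy is regressed *on* the climate target over the window (errors
    live in the proxy, so this direction avoids attenuation) and the fitted
    line is inverted to predict the target — the conventional way a single
    coral thermometer is calibrated.  Both fields are perturbed with their
    1-sigma uncertainties at each iteration before the refit.
    """
    from .climate import ar1_series
    from .forward import ols_univariate

    x = A.data[var].to_numpy(dtype=float)
    sig = float(A.sigma[var])
    b_grid = resample_to_grid(b, A.times)
    truth = b_grid.data.to_numpy(dtype=float)
    win = window if window is not None else (str(A.times[0]), str(A.times[-1]))
    in_win = np.asarray(
        (A.times >= pd.Period(win[0], "M")) & (A.times <= pd.Period(win[1], "M"))
    )
    rng = np.random.default_rng(cfg.seed)
    n = len(x)
    preds = np.empty((cfg.n_iter, n))
    for i in range(cfg.n_iter):
        if noise_phi == 0.0:
            x_p = x + rng.normal(0.0, sig, size=n)
        else:
            x_p = x + ar1_series(n, noise_phi, sig, rng)
        t_p = truth + rng.normal(0.0, b.sigma, size=n)
        slope, intercept, _ = ols_univariate(t_p[in_win], x_p[in_win])
        preds[i] = (x_p - intercept) / slope
    slope0, intercept0, _ = ols_univariate(truth[in_win], x[in_win])
    point = (x - intercept0) / slope0
    _, lo, hi, sep_t = _sep_from_predictions(preds, cfg.tail)
    r_val, _ = evaluate(
        pd.Series(point[in_win], index=A.times[in_win]),
        pd.Series(truth[in_win], index=A.times[in_win]),
    )
    return {
        "r": r_val,
        "rmse_min": rmse(point[in_win], truth[in_win]),
        "rmse_max": 0.5
        * (rmse(hi[in_win], truth[in_win]) + rmse(lo[in_win], truth[in_win])),
        "sep": float(sep_t[in_win].mean()),
        "sep_ci": float(sep_t[in_win].std(ddof=1) * 1.96),
    }


def _d11b_baseline_cell(A, climate, window, cfg, noise_phi=0.0):
    """Monte-Carlo skill of the mechanistic univariate d11B -> pH_sw baseline.

    Perturbs the d11B measurements with their 1-sigma noise and the SST/SSS
    series (needed for pK_B) and the pH target with their observational
    uncertainties, then inverts the isotope mass balance at each iteration.
    """
    d11b = A.data["d11B"].to_numpy(dtype=float)
    sig = float(A.sigma["d11B"]) if not isinstance(A.sigma, pd.DataFrame) else None
    sst = climate["SST"].data.reindex(A.times).to_numpy(dtype=float)
    sss = climate["SSS"].data.reindex(A.times).to_numpy(dtype=float)
    truth_series = resample_to_grid(climate["pH_sw"], A.times)
    truth = truth_series.data.to_numpy(dtype=float)
    win = window if window is not None else (str(A.times[0]), str(A.times[-1]))
    in_win = np.asarray(
        (A.times >= pd.Period(win[0], "M")) & (A.times <= pd.Period(win[1], "M"))
    )
    rng = np.random.default_rng(cfg.seed)
    n = len(d11b)
    preds = np.empty((cfg.n_iter, n))
    from .climate import ar1_series

    for i in range(cfg.n_iter):
        if noise_phi == 0.0:
            d11b_p = d11b + rng.normal(0.0, sig, size=n)
        else:
            d11b_p = d11b + ar1_series(n, noise_phi, sig, rng)
        sst_p = sst + rng.normal(0.0, climate["SST"].sigma, size=n)
        sss_p = sss + rng.normal(0.0, climate["SSS"].sigma, size=n)
        preds[i] = d11b_baseline_phsw(d11b_p, sst_p, sss_p)
    point = d11b_baseline_phsw(d11b, sst, sss)
    _, lo, hi, sep_t = _sep_from_predictions(preds, cfg.tail)
    r_val, _ = evaluate(
        pd.Series(point[in_win], index=A.times[in_win]),
        pd.Series(truth[in_win], index=A.times[in_win]),
    )
    return {
        "r": r_val,
        "rmse_min": rmse(point[in_win], truth[in_win]),
        "rmse_max": 0.5
        * (rmse(hi[in_win], truth[in_win]) + rmse(lo[in_win], truth[in_win])),
        "sep": float(sep_t[in_win].mean()),
        "sep_ci": float(sep_t[in_win].std(ddof=1) * 1.96),
    }


def _best_univariate_r(A: ProxyMatrix, b_vals: np.ndarray) -> float:
    """In-window r of the best single linear predictor (|correlation|)."""
    X = A.data.to_numpy(dtype=float)
    rs = [
        abs(np.corrcoef(X[:, j], b_vals)[0, 1])
        for j in range(X.shape[1])
        if X[:, j].std() > 0
    ]
    return max(rs)


def _noise_like_sweep(
    climate: dict[str, ClimateSeries],
    grid: list,
    cfg: MonteCarloConfig,
    targets,
    seed: int,
    spec_for,
    phi_for,
    param_name: str,
) -> SweepResult:
    ideal = generate_pseudoproxies(climate, noise=None)
    rows = []
    param_rows = []
    for idx, g in enumerate(grid):
        spec = spec_for(g)
        sigmas = pseudoproxy_sigmas(climate, spec)
        A = ProxyMatrix(ideal.data, sigmas)
        phi = phi_for(g)
        cell_cfg = MonteCarloConfig(
            n_iter=cfg.n_iter, seed=_cell_seed(seed, idx), ci_level=cfg.ci_level
        )
        for target in targets:
            b = climate[target]
            stats, params = _mc_cell(A, b, None, 0, cell_cfg, noise_phi=phi)
            rows.append({param_name: g, "target": target, "method": "SMITE", **stats})
            for var in params.index:
                param_rows.append(
                    {
                        param_name: g,
                        "target": target,
                        "variable": var,
                        **params.loc[var].to_dict(),
                    }
                )
            base_var = BASELINE_PROXY[target]
            if base_var == "SrCa":
                base_stats = _univariate_inverse_cell(
                    A, "SrCa", b, None, cell_cfg, noise_phi=phi
                )
            else:
                base_stats = _d11b_baseline_cell(A, climate, None, cell_cfg, noise_phi=phi)
            rows.append(
                {param_name: g, "target": target, "method": base_var, **base_stats}
            )
    table = pd.DataFrame(rows)
    params = pd.DataFrame(param_rows)
    return SweepResult(
        param_name=param_name,
        grid=list(grid),
        table=table,
        params=params,
        manifest={"seed": seed, "n_iter": cfg.n_iter, "targets": list(targets)},
    )


def sweep_noise(
    climate: dict[str, ClimateSeries],
    increments=None,
    cfg: MonteCarloConfig | None = None,
    targets=("SST", "pH_sw"),
    seed: int = 0,
) -> SweepResult:
    """Gaussian-noise sweep: measurement 1-sigma grows by %RSD increments.

    The grid defaults to 0 .. +1.9% of each variable's mean in 0.1% steps on
    top of the baseline analytical uncertainty.
    """
    if increments is None:
        increments = [round(0.1 * i, 1) for i in range(20)]
    if list(increments) != sorted(increments):
        raise ValueError("noise increments must be sorted ascending")
    if cfg is None:
        cfg = MonteCarloConfig(n_iter=1000)
    return _noise_like_sweep(
        climate,
        list(increments),
        cfg,
        targets,
        seed,
        spec_for=lambda g: NoiseSpec(gaussian_rsd_increment=g),
        phi_for=lambda g: 0.0,
        param_name="rsd_increment",
    )


def sweep_ar1(
    climate: dict[str, ClimateSeries],
    phis=(0.0, 0.25, 0.5, 0.75, 0.9, 0.95),
    rsd_increment: float = 0.5,
    cfg: MonteCarloConfig | None = None,
    targets=("SST", "pH_sw"),
    seed: int = 0,
) -> SweepResult:
    """Autocorrelated-noise sweep at fixed marginal RSD, varying lag-1 phi."""
    if any(abs(p) >= 1 for p in phis):
        raise ValueError("|phi| must be < 1")
    if cfg is None:
        cfg = MonteCarloConfig(n_iter=1000)
    return _noise_like_sweep(
        climate,
        list(phis),
        cfg,
        targets,
        seed,
        spec_for=lambda g: NoiseSpec(gaussian_rsd_increment=rsd_increment, ar1_phi=g),
        phi_for=lambda g: g,
        param_name="ar1_phi",
    )


def sweep_calibration_length(
    climate: dict[str, ClimateSeries],
    lengths=None,
    cfg: MonteCarloConfig | None = None,
    targets=("SST", "pH_sw"),
    seed: int = 0,
    segment: str = "first",
) -> SweepResult:
    """Calibration-length sweep at baseline noise, 5 to 100 years by 5.

    ``segment`` chooses which part of the record calibrates: the first N
    years (default), the last N, or a random N-year block per cell.
    """
    if lengths is None:
        lengths = list(range(5, 101, 5))
    if cfg is None:
        cfg = MonteCarloConfig(n_iter=1000)
    ideal = generate_pseudoproxies(climate, noise=None)
    A = ProxyMatrix(ideal.data, dict(ideal.sigma))
    times = A.times
    n_years_total = len(times) // 12
    if max(lengths) > n_years_total:
        raise ValueError("record shorter than the longest requested calibration")
    rows, param_rows = [], []
    for idx, n_years in enumerate(lengths):
        cell_cfg = MonteCarloConfig(
            n_iter=cfg.n_iter, seed=_cell_seed(seed, idx), ci_level=cfg.ci_level
        )
        n_m = n_years * 12
        if segment == "first":
            w0, w1 = times[0], times[n_m - 1]
        elif segment == "last":
            w0, w1 = times[-n_m], times[-1]
        elif segment == "random":
            rng = np.random.default_rng(_cell_seed(seed, 10_000 + idx))
            start = int(rng.integers(0, len(times) - n_m + 1))
            w0, w1 = times[start], times[start + n_m - 1]
        else:
            raise ValueError("segment must be 'first', 'last', or 'random'")
        window = (str(w0), str(w1))
        for target in targets:
            stats, params = _mc_cell(A, climate[target], window, 0, cell_cfg)
            rows.append(
                {"calibration_years": n_years, "target": target, "method": "SMITE", **stats}
            )
            for var in params.index:
                param_rows.append(
                    {
                        "calibration_years": n_years,
                        "target": target,
                        "variable": var,
                        **params.loc[var].to_dict(),
                    }
                )
    return SweepResult(
        param_name="calibration_years",
        grid=list(lengths),
        table=pd.DataFrame(rows),
        params=pd.DataFrame(param_rows),
        manifest={"seed": seed, "n_iter": cfg.n_iter, "segment": segment},
    )


def sweep_combinations(
    A: ProxyMatrix,
    b: ClimateSeries,
    window=None,
    sizes=None,
    cfg: MonteCarloConfig | None = None,
) -> SweepResult:
    """Fit an untruncated model for every variable subset of each size.

    Subsets are enumerated deterministically (by size, then lexicographic by
    variable name).  Monte-Carlo SEP is computed only when ``cfg`` is given;
    the plain fit per subset takes milliseconds, so the full 7-variable
    enumeration (120 subsets) runs in well under a minute without it.
    """
    p = len(A.variables)
    if p < 2:
        raise ValueError("need at least 2 variables")
    if sizes is None:
        sizes = range(2, p + 1)
    names = sorted(A.variables)
    win = window if window is not None else (str(A.times[0]), str(A.times[-1]))
    A_win = A.subset(win)
    b_win = resample_to_grid(b, A_win.times)
    rows = []
    for size in sizes:
        for combo in combinations(names, size):
            sub = A.select(list(combo))
            model = fit_smite(sub, b, window=win, k_trunc=0)
            pred = predict(model, sub.subset(win))
            r_val, rmse_val = evaluate(pred, b_win)
            row = {
                "size": size,
                "variables": "+".join(combo),
                "target": b.name,
                "r": r_val,
                "rmse": rmse_val,
                "best_univariate_r": _best_univariate_r(
                    sub.subset(win), b_win.data.to_numpy(dtype=float)
                ),
            }
            if cfg is not None:
                stats, _ = _mc_cell(sub, b, win, 0, cfg)
                row["sep"] = stats["sep"]
                row["sep_ci"] = stats["sep_ci"]
            rows.append(row)
    return SweepResult(
        param_name="variables",
        grid=[r["variables"] for r in rows],
        table=pd.DataFrame(rows),
        manifest={"sizes": list(sizes), "window": list(win)},
    )


def sweep_truncation(
    A: ProxyMatrix,
    b: ClimateSeries,
    window=None,
    cfg: MonteCarloConfig | None = None,
) -> SweepResult:
    """Skill and parameter uncertainty at every truncation level 0..p-2."""
    p = len(A.variables)
    if p < 3:
        raise ValueError("need at least 3 variables to truncate")
    if cfg is None:
        cfg = MonteCarloConfig(n_iter=1000)
    win = window if window is not None else (str(A.times[0]), str(A.times[-1]))
    rows, param_rows = [], []
    for k in range(0, p - 1):
        cell_cfg = MonteCarloConfig(n_iter=cfg.n_iter, seed=cfg.seed, ci_level=cfg.ci_level)
        stats, params = _mc_cell(A, b, win, k, cell_cfg)
        rows.append({"k_trunc": k, "target": b.name, "method": "SMITE", **stats})
        for var in params.index:
            param_rows.append(
                {"k_trunc": k, "target": b.name, "variable": var, **params.loc[var].to_dict()}
            )
    return SweepResult(
        param_name="k_trunc",
        grid=list(range(0, p - 1)),
        table=pd.DataFrame(rows),
        params=pd.DataFrame(param_rows),
        manifest={"seed": cfg.seed, "n_iter": cfg.n_iter, "window": list(win)},
    )


def cross_transfer(
    model: SmiteModel,
    B: ProxyMatrix,
    b_B: ClimateSeries,
    stats_mode: str = "receiver",
    window=None,
) -> tuple[EvalReport, ClimateSeries]:
    """Apply a donor core's parameters to a receiving core's measurements.

    ``stats_mode='receiver'`` (default) z-scores the receiving core with its
    own window statistics and back-transforms with the receiving target's
    moments — the donor contributes only the parameter vector.  NOTE: this
    choice materially affects transferred reconstructions whenever the two
    cores' means or variances differ; ``stats_mode='donor'`` applies the
    donor's stored statistics to the receiver instead.
    """
    missing = [v for v in model.variables if v not in B.data.columns]
    if missing:
        raise SchemaError(f"receiver lacks model variables: {missing}")
    win = window if window is not None else (str(B.times[0]), str(B.times[-1]))
    if stats_mode == "donor":
        pred = predict(model, B)
    elif stats_mode == "receiver":
        from .core import NormalizationStats

        B_win = B.subset(win)
        b_win = resample_to_grid(b_B, B_win.times)
        stats = NormalizationStats.from_window(
            B_win.data[model.variables], b_win.data
        )
        Z = zscore(B.data[model.variables], stats)
        vals = Z.to_numpy() @ model.x_dagger * stats.sd_b + stats.mu_b
        pred = ClimateSeries(model.target, pd.Series(vals, index=B.times), sigma=0.0)
    else:
        raise ValueError("stats_mode must be 'receiver' or 'donor'")
    b_grid = resample_to_grid(b_B, B.times)
    r_val, rmse_val = evaluate(pred, b_grid)
    report = EvalReport(r=r_val, rmse=rmse_val, sep=0.0, sep_ci=0.0)
    return report, pred
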