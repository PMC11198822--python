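"""Reconstruction skill metrics and bootstrap Monte-Carlo uncertainty.

Skill is summarized by three numbers: the Pearson correlation r, the
root-mean-square error (accuracy, in target units), and the standard error
of prediction SEP (precision).  The SEP propagates the measurement
uncertainty of every proxy entry and every climate-target entry through the
whole calibration: at each Monte-Carlo iteration both fields are resampled
from normal distributions centered on the measured values, the model is
refit, and predictions are stored.  The per-time 95% interval comes from the
2.5/97.5 percentiles of that prediction distribution; the per-time SEP is
the mean distance from the ensemble mean to the two bounds divided by 1.96;
the reported SEP averages the per-time values over the calibration window,
with a 95% interval of 1.96 times their spread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .climate import ar1_series
from .core import (
    ClimateSeries,
    ProxyMatrix,
    SmiteModel,
    fit_smite,
    predict,
    resample_to_grid,
    zscore,
)

__all__ = [
    "MonteCarloConfig",
    "EvalReport",
    "pearson_r",
    "rmse",
    "evaluate",
    "monte_carlo_sep",
    "parameter_uncertainty",
]


@dataclass
class MonteCarloConfig:
    n_iter: int = 10000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_iter < 100:
            raise ValueError("n_iter must be at least 100 for stable tail percentiles")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")

    @property
    def tail(self) -> float:
        return (1 - self.ci_level) / 2 * 100


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)


def rmse(pred, truth) -> float:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if len(pred) != len(truth):
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


@dataclass
class EvalReport:
    """Skill of a reconstruction against truth, with Monte-Carlo precision."""

    r: float
    rmse: float
    sep: float
    sep_ci: float
    table: pd.DataFrame | None = None  # per-time columns pred, lo95, hi95, sep

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.sep < 0:
            raise ValueError("rmse and sep must be non-negative")

    def to_json(self) -> str:
        return json.dumps(
            {"r": self.r, "rmse": self.rmse, "sep": self.sep, "sep_ci": self.sep_ci},
            indent=2,
        )

    def table_to_csv(self, path) -> None:
        if self.table is None:
            raise ValueError("no per-time table attached")
        out = self.table.copy()
        out.insert(0, "date", out.index.astype(str))
        out.to_csv(path, index=False)


def evaluate(pred: ClimateSeries | pd.Series, truth: ClimateSeries | pd.Series) -> tuple[float, float]:
    """(r, RMSE) of a reconstruction against a truth series on shared months."""
    p = pred.data if isinstance(pred, ClimateSeries) else pred
    t = truth.data if isinstance(truth, ClimateSeries) else truth
    common = p.index.intersection(t.index)
    return (
        pearson_r(p.loc[common], t.loc[common]),
        rmse(p.loc[common], t.loc[common]),
    )


def _perturb_refit_ensemble(
    A: ProxyMatrix,
    b: ClimateSeries,
    window,
    k_trunc: int,
    cfg: MonteCarloConfig,
    noise_phi: float = 0.0,
    store_predictions: bool = True,
):
    """Perturb-and-refit ensemble shared by the SEP and parameter-CI paths.

    Every proxy entry and every target entry is resampled from a normal law
    centered on the measured value with its 1-sigma uncertainty, the model
    is refit on the window (same truncation as the reference model), and the
    parameter vector (and optionally full-record predictions) is stored.
    ``noise_phi`` gives the proxy perturbations lag-1 autocorrelation while
    preserving their marginal sd.
    """
    ref = fit_smite(A, b, window=window, k_trunc=k_trunc)
    sig = A.sigma_matrix().to_numpy(dtype=float)
    vals = A.data.to_numpy(dtype=float)
    n_t, p = vals.shape
    b_grid = resample_to_grid(b, A.times)
    b_vals = b_grid.data.to_numpy(dtype=float)
    win = window if window is not None else (str(A.times[0]), str(A.times[-1]))
    in_win = np.asarray(
        (A.times >= pd.Period(win[0], "M")) & (A.times <= pd.Period(win[1], "M"))
    )
    rng = np.random.default_rng(cfg.seed)
    x_draws = np.empty((cfg.n_iter, p))
    preds = np.empty((cfg.n_iter, n_t)) if store_predictions else None
    keep = p - k_trunc
    rtol = 1e-10
    for i in range(cfg.n_iter):
        if noise_phi == 0.0:
            pert = vals + rng.normal(0.0, 1.0, size=vals.shape) * sig
        else:
            noise = np.column_stack(
                [ar1_series(n_t, noise_phi, 1.0, rng) for _ in range(p)]
            )
            pert = vals + noise * sig
        b_pert = b_vals + rng.normal(0.0, 1.0, size=n_t) * b.sigma
        # Numpy re-implementation of the fit/predict path for speed; it must
        # mirror fit_smite/predict exactly (window stats, ddof=1, rtol cut).
        Aw = pert[in_win]
        bw = b_pert[in_win]
        mu = Aw.mean(axis=0)
        sd = Aw.std(axis=0, ddof=1)
        mu_b = bw.mean()
        sd_b = bw.std(ddof=1)
        Zw = (Aw - mu) / sd
        ba = (bw - mu_b) / sd_b
        U, S, Vh = np.linalg.svd(Zw, full_matrices=False)
        mask = S[:keep] > rtol * (S[0] if S[0] > 0 else 1.0)
        Uk = U[:, :keep][:, mask]
        Vk = Vh[:keep][mask].T
        x = Vk @ ((Uk.T @ ba) / S[:keep][mask])
        x_draws[i] = x
        if store_predictions:
            Z = (pert - mu) / sd
            preds[i] = (Z @ x) * sd_b + mu_b
    return ref, x_draws, preds, b_grid, in_win


def _sep_from_predictions(preds: np.ndarray, tail: float):
    mean = preds.mean(axis=0)
    lo = np.percentile(preds, tail, axis=0)
    hi = np.percentile(preds, 100 - tail, axis=0)
    sep_t = ((hi - mean) + (mean - lo)) / 2.0 / 1.96
    return mean, lo, hi, sep_t


def monte_carlo_sep(
    A: ProxyMatrix,
    b: ClimateSeries,
    window=None,
    k_trunc: int = 0,
    cfg: MonteCarloConfig | None = None,
    sep_scope: str = "window",
    noise_phi: float = 0.0,
) -> EvalReport:
    """Bootstrap Monte-Carlo standard error of prediction for a calibration.

    The reported point skill (r, RMSE) is that of the reference model fit to
    the unperturbed measurements; SEP and the per-time interval come from
    the perturb-and-refit ensemble.  ``sep_scope`` chooses whether the
    reported SEP averages the per-time values over the calibration window
    (default) or the full record.
    """
    if cfg is None:
        cfg = MonteCarloConfig()
    if sep_scope not in ("window", "full"):
        raise ValueError("sep_scope must be 'window' or 'full'")
    ref, _, preds, b_grid, in_win = _perturb_refit_ensemble(
        A, b, window, k_trunc, cfg, noise_phi=noise_phi, store_predictions=True
    )
    _, lo, hi, sep_t = _sep_from_predictions(preds, cfg.tail)
    scope = in_win if sep_scope == "window" else np.ones_like(in_win, dtype=bool)
    sep = float(sep_t[scope].mean())
    sep_ci = float(sep_t[scope].std(ddof=1) * 1.96) if scope.sum() > 1 else 0.0
    point = predict(ref, A)
    r_val, rmse_val = evaluate(
        point.data[in_win], b_grid.data[in_win]
    ) if in_win.sum() >= 3 else (np.nan, np.nan)
    table = pd.DataFrame(
        {"pred": point.data.to_numpy(), "lo95": lo, "hi95": hi, "sep": sep_t},
        index=A.times,
    )
    return EvalReport(r=r_val, rmse=rmse_val, sep=sep, sep_ci=sep_ci, table=table)


def parameter_uncertainty(
    A: ProxyMatrix,
    b: ClimateSeries,
    window=None,
    k_trunc: int = 0,
    cfg: MonteCarloConfig | None = None,
    noise_phi: float = 0.0,
) -> pd.DataFrame:
    """Percentile confidence intervals on each model parameter.

    Returns a DataFrame indexed by variable with columns ``x_ref`` (reference
    fit), ``mean``, ``lo95``, ``hi95`` over the perturb-and-refit ensemble.
    """
    if cfg is None:
        cfg = MonteCarloConfig()
    ref, x_draws, _, _, _ = _perturb_refit_ensemble(
        A, b, window, k_trunc, cfg, noise_phi=noise_phi, store_predictions=False
    )
    lo = np.percentile(x_draws, cfg.tail, axis=0)
    hi = np.percentile(x_draws, 100 - cfg.tail, axis=0)
    return pd.DataFrame(
        {
            "x_ref": ref.x_dagger,
            "mean": x_draws.mean(axis=0),
            "lo95": lo,
            "hi95": hi,
        },
        index=ref.variables,
    )
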