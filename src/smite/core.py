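"""Truncated-SVD pseudoinverse calibration of coral variable fields.

The central object is a linear inverse problem ``A x = b`` where ``A`` is a
time-by-variable matrix of age-modeled coral geochemical measurements and
``b`` is a climate target (SST, pH_sw, ...) on the same monthly grid.  Both
sides are z-scored over a calibration window, ``A`` is factored by singular
value decomposition, and the model parameters are obtained from the
pseudoinverse ``x = V S^-1 U^T b``.  Removing the smallest singular values
("truncation") regularizes the solution exactly as principal-components
regression does, trading in-sample fit for parameter stability — the key
lever when coral variables are strongly collinear.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SmiteError",
    "DegenerateColumnError",
    "RegularizationLimitError",
    "UnderdeterminedError",
    "SchemaError",
    "AdvisoryError",
    "ProxyMatrix",
    "ClimateSeries",
    "NormalizationStats",
    "SVDFactors",
    "SmiteModel",
    "TruncationDiagnostics",
    "zscore",
    "svd_decompose",
    "solve_parameters",
    "fit_smite",
    "predict",
    "suggest_truncation",
    "cumulative_variance",
    "resample_to_grid",
]


class SmiteError(Exception):
    """Base class for calibration errors."""


class DegenerateColumnError(SmiteError):
    """A variable has zero variance over the calibration window."""


class RegularizationLimitError(SmiteError):
    """Requested truncation would leave fewer than two singular values."""


class UnderdeterminedError(SmiteError):
    """Calibration window has fewer rows than the retained rank."""


class SchemaError(SmiteError):
    """Input is missing required variables or has malformed structure."""


class AdvisoryError(SmiteError):
    """The requested diagnostic is not meaningful for this system shape."""


def _as_period_index(times) -> pd.PeriodIndex:
    if isinstance(times, pd.PeriodIndex):
        if times.freqstr not in ("M", "ME"):
            return times.asfreq("M")
        return times
    return pd.PeriodIndex(times, freq="M")


def _parse_window(window) -> tuple[pd.Period, pd.Period]:
    start, end = window
    start = pd.Period(start, freq="M")
    end = pd.Period(end, freq="M")
    if start > end:
        raise ValueError(f"window start {start} is after end {end}")
    return start, end


@dataclass
class ProxyMatrix:
    """Time-by-variable table of coral measurements with 1-sigma uncertainties.

    ``data`` is indexed by a monthly :class:`pandas.PeriodIndex`; ``sigma``
    maps each variable to a scalar analytical 1-sigma uncertainty (same units
    as the variable) or, for real records with per-sample standard errors, to
    a full per-entry DataFrame aligned with ``data``.
    """

    data: pd.DataFrame
    sigma: Mapping[str, float] | pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = _as_period_index(self.data.index)
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate variable names: {dupes}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].astype(str).tolist()
            raise SchemaError(f"duplicate months in index: {dupes}")
        if self.data.isna().any().any():
            raise ValueError("ProxyMatrix contains missing values; interpolate gaps first")
        if isinstance(self.sigma, pd.DataFrame):
            self.sigma = self.sigma.copy()
            self.sigma.index = _as_period_index(self.sigma.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def times(self) -> pd.PeriodIndex:
        return self.data.index

    def sigma_matrix(self) -> pd.DataFrame:
        """Per-entry 1-sigma uncertainties broadcast to the full table."""
        if self.sigma is None:
            raise ValueError("no measurement uncertainties attached")
        if isinstance(self.sigma, pd.DataFrame):
            return self.sigma.reindex(index=self.data.index, columns=self.data.columns)
        missing = [v for v in self.variables if v not in self.sigma]
        if missing:
            raise SchemaError(f"sigma missing for variables: {missing}")
        arr = np.tile([float(self.sigma[v]) for v in self.variables], (len(self.data), 1))
        return pd.DataFrame(arr, index=self.data.index, columns=self.data.columns)

    def subset(self, window) -> "ProxyMatrix":
        start, end = _parse_window(window)
        sub = self.data.loc[start:end]
        sig = self.sigma
        if isinstance(sig, pd.DataFrame):
            sig = sig.loc[start:end]
        return ProxyMatrix(sub, sig)

    def select(self, variables: Sequence[str]) -> "ProxyMatrix":
        missing = [v for v in variables if v not in self.data.columns]
        if missing:
            raise SchemaError(f"variables absent from proxy matrix: {missing}")
        sig = self.sigma
        if isinstance(sig, Mapping):
            sig = {v: sig[v] for v in variables if v in sig}
        elif isinstance(sig, pd.DataFrame):
            sig = sig[list(variables)]
        return ProxyMatrix(self.data[list(variables)], sig)


@dataclass
class ClimateSeries:
    """A monthly climate-target series (the right-hand side ``b``)."""

    name: str
    data: pd.Series
    sigma: float = 0.02  # in-situ logger / CTD grade observational 1-sigma

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = _as_period_index(self.data.index)
        self.data.name = self.name
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def times(self) -> pd.PeriodIndex:
        return self.data.index

    def subset(self, window) -> "ClimateSeries":
        start, end = _parse_window(window)
        return ClimateSeries(self.name, self.data.loc[start:end], self.sigma)


@dataclass
class NormalizationStats:
    """Calibration-window means and standard deviations for both sides."""

    mu: pd.Series
    sd: pd.Series
    mu_b: float
    sd_b: float

    def __post_init__(self) -> None:
        bad = self.sd[self.sd <= 0]
        if len(bad):
            raise DegenerateColumnError(
                f"zero-variance variable(s) in calibration window: {list(bad.index)}"
            )
        if self.sd_b <= 0:
            raise DegenerateColumnError("climate target has zero variance in calibration window")

    @classmethod
    def from_window(cls, A: pd.DataFrame, b: pd.Series) -> "NormalizationStats":
        return cls(mu=A.mean(), sd=A.std(ddof=1), mu_b=float(b.mean()), sd_b=float(b.std(ddof=1)))


def zscore(values: pd.DataFrame | pd.Series, stats: NormalizationStats):
    """Normalize columns (or a target series) with calibration-window stats.

    The stats always come from the calibration window; applying this to data
    outside the window deliberately re-uses the in-window mean and sd so that
    reconstructed anomalies stay on the calibration scale.
    """
    if isinstance(values, pd.Series):
        return (values - stats.mu_b) / stats.sd_b
    mu = stats.mu.reindex(values.columns)
    sd = stats.sd.reindex(values.columns)
    if mu.isna().any():
        raise SchemaError(f"no stats for variables: {list(mu[mu.isna()].index)}")
    return (values - mu) / sd


@dataclass
class SVDFactors:
    """Thin SVD of the normalized calibration matrix: ``Z = U diag(S) V^T``."""

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray  # columns are right singular vectors, p x p

    def reconstruct(self) -> np.ndarray:
        return self.U @ np.diag(self.S) @ self.V.T


def svd_decompose(Z: pd.DataFrame | np.ndarray) -> SVDFactors:
    """Singular value decomposition of the z-scored coral variable field."""
    arr = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite entries in matrix passed to SVD")
    U, S, Vh = np.linalg.svd(arr, full_matrices=False)
    return SVDFactors(U=U, S=S, V=Vh.T)


def solve_parameters(
    factors: SVDFactors,
    b_a: np.ndarray | pd.Series,
    k_trunc: int = 0,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Pseudoinverse solution ``x = V_T S_T^-1 U_T^T b_a`` with truncation.

    ``k_trunc`` removes the smallest singular values and their singular
    vectors before inversion.  Independently of ``k_trunc``, singular values
    below ``rtol * S_max`` are treated as zero, so an exactly collinear
    system yields the minimum-norm least-squares solution instead of an
    exploding inverse.
    """
    b = np.asarray(b_a, dtype=float)
    p = len(factors.S)
    if not 0 <= k_trunc <= max(p - 2, 0):
        raise RegularizationLimitError(
            f"k_trunc={k_trunc} outside [0, {max(p - 2, 0)}]: the two leading "
            "singular values can never be truncated"
        )
    if b.shape[0] != factors.U.shape[0]:
        raise ValueError("target length does not match rows of U")
    keep = p - k_trunc
    S = factors.S[:keep]
    mask = S > rtol * (factors.S[0] if factors.S[0] > 0 else 1.0)
    U = factors.U[:, :keep][:, mask]
    V = factors.V[:, :keep][:, mask]
    return V @ ((U.T @ b) / S[mask])


def resample_to_grid(b: ClimateSeries, grid: pd.PeriodIndex) -> ClimateSeries:
    """Bring the climate target onto the proxy time grid.

    A monthly target already on the grid passes through; a coarser or
    misaligned target is linearly interpolated against time (month ordinals).
    Months of the grid outside the target span cannot be filled.
    """
    if b.times.equals(grid):
        return b
    have = b.data.dropna()
    x = have.index.asi8.astype(float)
    xi = grid.asi8.astype(float)
    if xi.min() < x.min() or xi.max() > x.max():
        raise ValueError("proxy grid extends beyond the climate target span")
    vals = np.interp(xi, x, have.to_numpy(dtype=float))
    return ClimateSeries(b.name, pd.Series(vals, index=grid), b.sigma)


@dataclass
class SmiteModel:
    """A fitted calibration: everything needed to predict and to diagnose."""

    variables: list[str]
    target: str
    window: tuple[str, str]
    stats: NormalizationStats
    k_trunc: int
    x_dagger: np.ndarray
    factors: SVDFactors | None = None
    schema: str = field(default="smite-model/1", repr=False)

    def __post_init__(self) -> None:
        self.x_dagger = np.asarray(self.x_dagger, dtype=float)
        if len(self.x_dagger) != len(self.variables):
            raise ValueError("x_dagger length does not match variable count")

    def to_json(self) -> str:
        doc = {
            "schema": self.schema,
            "variables": self.variables,
            "target": self.target,
            "window": list(self.window),
            "k_trunc": int(self.k_trunc),
            "mu": {v: float(self.stats.mu[v]) for v in self.variables},
            "sd": {v: float(self.stats.sd[v]) for v in self.variables},
            "mu_b": self.stats.mu_b,
            "sd_b": self.stats.sd_b,
            "x_dagger": [float(x) for x in self.x_dagger],
            "singular_values": (
                [float(s) for s in self.factors.S] if self.factors is not None else None
            ),
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SmiteModel":
        doc = json.loads(text)
        if doc.get("schema") != "smite-model/1":
            raise SchemaError(f"unrecognized model schema: {doc.get('schema')!r}")
        variables = list(doc["variables"])
        stats = NormalizationStats(
            mu=pd.Series({v: doc["mu"][v] for v in variables}),
            sd=pd.Series({v: doc["sd"][v] for v in variables}),
            mu_b=doc["mu_b"],
            sd_b=doc["sd_b"],
        )
        return cls(
            variables=variables,
            target=doc["target"],
            window=tuple(doc["window"]),
            stats=stats,
            k_trunc=doc["k_trunc"],
            x_dagger=np.array(doc["x_dagger"], dtype=float),
        )


def fit_smite(
    A: ProxyMatrix,
    b: ClimateSeries,
    window=None,
    k_trunc: int = 0,
    rtol: float = 1e-10,
) -> SmiteModel:
    """Calibrate model parameters over a window.

    Steps: subset both sides to the window, resample the target onto the
    proxy grid, z-score each side with window statistics, decompose the
    normalized matrix, optionally truncate, and solve for the parameters.
    """
    if window is None:
        window = (str(A.times[0]), str(A.times[-1]))
    start, end = _parse_window(window)
    A_c = A.subset(window)
    if len(A_c.data) == 0:
        raise ValueError(f"window {start}:{end} selects no proxy rows")
    b_c = resample_to_grid(b, A_c.times)
    p = len(A_c.variables)
    if len(A_c.data) < p:
        warnings.warn(
            f"calibration window has {len(A_c.data)} rows for {p} variables; "
            "the system is underdetermined",
            stacklevel=2,
        )
    if len(A_c.data) < p - k_trunc:
        raise UnderdeterminedError(
            f"{len(A_c.data)} calibration rows cannot support retained rank {p - k_trunc}"
        )
    stats = NormalizationStats.from_window(A_c.data, b_c.data)
    Z = zscore(A_c.data, stats)
    b_a = zscore(b_c.data, stats)
    factors = svd_decompose(Z)
    x = solve_parameters(factors, b_a.to_numpy(), k_trunc=k_trunc, rtol=rtol)
    return SmiteModel(
        variables=A_c.variables,
        target=b.name,
        window=(str(start), str(end)),
        stats=stats,
        k_trunc=k_trunc,
        x_dagger=x,
        factors=factors,
    )


def predict(model: SmiteModel, A: ProxyMatrix) -> ClimateSeries:
    """Apply a fitted model to a (possibly longer) proxy record.

    The full record is z-scored with the calibration-window statistics stored
    in the model — never refit — then mapped through the parameters and
    back-transformed to target units.
    """
    missing = [v for v in model.variables if v not in A.data.columns]
    if missing:
        raise SchemaError(f"proxy matrix lacks model variables: {missing}")
    Z = zscore(A.data[model.variables], model.stats)
    b_hat_a = Z.to_numpy() @ model.x_dagger
    b_hat = b_hat_a * model.stats.sd_b + model.stats.mu_b
    return ClimateSeries(model.target, pd.Series(b_hat, index=A.times), sigma=0.0)


def cumulative_variance(singular_values: Iterable[float]) -> np.ndarray:
    """Cumulative fraction of variance explained by the leading singular
    values, normalized by the sum of the singular values."""
    s = np.asarray(list(singular_values), dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be non-negative")
    return np.cumsum(s) / s.sum()


@dataclass
class TruncationDiagnostics:
    """Per-level regularization diagnostics and a recommended level."""

    k_levels: np.ndarray
    retained_variance: np.ndarray  # fraction of singular-value mass kept at each level
    uncertainty_total: np.ndarray  # summed 95% CI half-widths of the parameters
    recommended: int


def suggest_truncation(
    A: ProxyMatrix,
    b: ClimateSeries,
    window=None,
    threshold: float = 0.70,
    n_targets: int = 1,
    cfg=None,
) -> TruncationDiagnostics:
    """Recommend a truncation level for an overdetermined system.

    A level becomes a candidate when the singular-value mass it retains first
    drops below ``threshold`` (default 70% cumulative variance explained, the
    empirical inflection point for well-behaved coral arrays) *and* the total
    Monte-Carlo parameter uncertainty decreases relative to the previous
    level.  A flat singular spectrum has no inflection and yields level 0.
    """
    from .metrics import MonteCarloConfig, parameter_uncertainty

    p = len(A.variables)
    if p <= n_targets:
        raise AdvisoryError(
            f"truncation guidance needs an overdetermined system: {p} variables "
            f"for {n_targets} target(s) is square or underdetermined"
        )
    if cfg is None:
        cfg = MonteCarloConfig(n_iter=500, seed=0)
    base = fit_smite(A, b, window=window, k_trunc=0)
    s = base.factors.S
    k_levels = np.arange(0, p - 1)
    retained = np.array([s[: p - k].sum() / s.sum() for k in k_levels])
    unc = np.empty(len(k_levels))
    for i, k in enumerate(k_levels):
        ci = parameter_uncertainty(A, b, window=window, k_trunc=int(k), cfg=cfg)
        unc[i] = float(((ci["hi95"] - ci["lo95"]) / 2).sum())
    recommended = 0
    if (s.max() - s.min()) > 1e-9 * max(s.max(), 1.0):  # flat spectrum -> no inflection
        for i, k in enumerate(k_levels):
            if k == 0:
                continue
            if retained[i] < threshold and unc[i] < unc[i - 1]:
                recommended = int(k)
                break
    return TruncationDiagnostics(
        k_levels=k_levels,
        retained_variance=retained,
        uncertainty_total=unc,
        recommended=recommended,
    )
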