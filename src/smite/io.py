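"""CSV readers/writers, run configuration, and the bundled test fixture.

Time-series files carry a ``date`` column in ``YYYY-MM`` form, one column
per variable, and optional ``<var>_sigma`` sidecar columns holding 1-sigma
measurement uncertainties (a scalar repeated per row, or genuinely per-entry
standard errors).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .climate import EmulatorConfig, emulate_climate
from .core import ClimateSeries, ProxyMatrix, SchemaError
from .forward import BASELINE_SIGMA, generate_pseudoproxies

__all__ = [
    "RunConfig",
    "load_run_config",
    "read_timeseries_csv",
    "read_proxy_matrix",
    "read_climate_series",
    "write_proxy_matrix",
    "write_climate",
    "make_fixture",
    "load_fixture",
    "FIXTURE_SEED",
]


@dataclass
class RunConfig:
    """A full calibration run described in one structured text file."""

    proxies: str
    target: str
    target_name: str = "SST"
    target_sigma: float = 0.02
    variables: list[str] | None = None
    sigma: dict[str, float] | None = None  # overrides sidecar columns
    window: tuple[str, str] | None = None
    k_trunc: int | str = 0  # integer level or "auto"
    n_iter: int = 10000
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.window is not None:
            start, end = self.window
            if pd.Period(start, "M") > pd.Period(end, "M"):
                raise ValueError(f"window start {start} after end {end}")
            self.window = (str(start), str(end))
        if not (self.k_trunc == "auto" or isinstance(self.k_trunc, int)):
            raise ValueError("k_trunc must be an integer or 'auto'")


def load_run_config(path) -> RunConfig:
    """Parse a YAML run configuration, validating windows and truncation."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a mapping at the top level")
    if isinstance(doc.get("window"), str) and ":" in doc["window"]:
        doc["window"] = tuple(doc["window"].split(":", 1))
    elif isinstance(doc.get("window"), list):
        doc["window"] = tuple(doc["window"])
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)

FIXTURE_SEED = 11
_FIXTURE_WINDOW = ("2010-06", "2013-09")  # 40 months


def _parse_dates(raw: pd.Series, path) -> pd.PeriodIndex:
    try:
        idx = pd.PeriodIndex(raw.astype(str), freq="M")
    except Exception as exc:
        bad = []
        for i, v in enumerate(raw):
            try:
                pd.Period(str(v), freq="M")
            except Exception:
                bad.append(i + 2)  # 1-based rows plus header
        raise SchemaError(f"{path}: unparseable date(s) at row(s) {bad}") from exc
    dupes = idx[idx.duplicated()]
    if len(dupes):
        raise SchemaError(f"{path}: duplicated month(s): {sorted(set(dupes.astype(str)))}")
    return idx


def read_timeseries_csv(path) -> tuple[pd.DataFrame, dict[str, float] | pd.DataFrame | None]:
    """Read a monthly time-series CSV into (values, sigma).

    Returns the value columns indexed by month and, if ``<var>_sigma``
    sidecar columns are present, their uncertainties — as a scalar map when
    each sidecar is constant, else as a per-entry DataFrame.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "date" not in df.columns:
        raise SchemaError(f"{path}: no 'date' column")
    idx = _parse_dates(df["date"], path)
    df = df.drop(columns="date")
    df.index = idx
    sigma_cols = [c for c in df.columns if c.endswith("_sigma")]
    values = df.drop(columns=sigma_cols)
    if not sigma_cols:
        return values, None
    sig = df[sigma_cols].rename(columns=lambda c: c[: -len("_sigma")])
    orphan = [c for c in sig.columns if c not in values.columns]
    if orphan:
        raise SchemaError(f"{path}: sigma column(s) without a value column: {orphan}")
    if (sig.nunique() == 1).all():
        return values, {c: float(sig[c].iloc[0]) for c in sig.columns}
    return values, sig.reindex(columns=values.columns.intersection(sig.columns))


def read_proxy_matrix(path) -> ProxyMatrix:
    values, sigma = read_timeseries_csv(path)
    return ProxyMatrix(values, sigma)


def read_climate_series(path, name: str, sigma: float = 0.02) -> ClimateSeries:
    values, sidecar = read_timeseries_csv(path)
    if name not in values.columns:
        raise SchemaError(f"{path}: no column named {name!r}")
    if isinstance(sidecar, dict) and name in sidecar:
        sigma = sidecar[name]
    return ClimateSeries(name, values[name], sigma=sigma)


def _frame_with_sigma(pm: ProxyMatrix) -> pd.DataFrame:
    out = pm.data.copy()
    if isinstance(pm.sigma, pd.DataFrame):
        for c in pm.sigma.columns:
            out[f"{c}_sigma"] = pm.sigma[c]
    elif pm.sigma is not None:
        for c, s in pm.sigma.items():
            out[f"{c}_sigma"] = float(s)
    out.insert(0, "date", out.index.astype(str))
    return out


def write_proxy_matrix(pm: ProxyMatrix, path) -> None:
    _frame_with_sigma(pm).to_csv(path, index=False)


def write_climate(climate: dict[str, ClimateSeries], path, header_comment: str | None = None) -> None:
    first = next(iter(climate.values()))
    df = pd.DataFrame({name: cs.data for name, cs in climate.items()}, index=first.times)
    df.insert(0, "date", df.index.astype(str))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


# --- bundled fixture --------------------------------------------------------

#: Extra noise-bearing variables for the seven-variable fixture: loadings on
#: standardized SST and pH plus independent noise, in plausible native units.
_EXTRA_VARS = {
    # name: (mean, scale, loading_sst, loading_ph, noise_sd, analytical sigma)
    "BCa": (460.0, 25.0, -0.75, 0.15, 0.55, 8.0),
    "LiCa": (6.1, 0.45, -0.80, 0.10, 0.50, 0.12),
    "MgCa": (4.2, 0.35, 0.60, -0.10, 0.75, 0.10),
    "UCa": (1.15, 0.08, -0.55, 0.25, 0.80, 0.03),
}


def make_fixture(seed: int = FIXTURE_SEED) -> tuple[ProxyMatrix, dict[str, ClimateSeries]]:
    """Deterministic 40-month, 7-variable synthetic coral dataset.

    Stands in for an unreleased reef record: a 5-year climate emulation is
    sliced to a June-2010..September-2013 grid (40 months); the three
    mechanistic pseudoproxies are joined by four elemental-ratio variables
    built as prescribed linear loadings on standardized SST and pH plus
    independent noise.  The ground-truth SST, SSS, and pH series are
    returned alongside the proxies.
    """
    cfg = EmulatorConfig(n_years=5, start="2009-01", seed=seed)
    climate = emulate_climate(cfg)
    rng = np.random.default_rng(seed + 1)
    pm = generate_pseudoproxies(climate, noise=None)
    data = pm.data.copy()
    sigma = dict(BASELINE_SIGMA)
    sst = climate["SST"].data
    ph = climate["pH_sw"].data
    z_sst = ((sst - sst.mean()) / sst.std(ddof=1)).to_numpy()
    z_ph = ((ph - ph.mean()) / ph.std(ddof=1)).to_numpy()
    for name, (mean, scale, l_sst, l_ph, noise_sd, sig) in _EXTRA_VARS.items():
        core = l_sst * z_sst + l_ph * z_ph + noise_sd * rng.normal(size=len(z_sst))
        data[name] = mean + scale * core
        sigma[name] = sig
    window = _FIXTURE_WINDOW
    pm_out = ProxyMatrix(data, sigma).subset(window)
    clim_out = {k: v.subset(window) for k, v in climate.items()}
    return pm_out, clim_out


def _data_path(name: str):
    return importlib.resources.files("smite").joinpath("data", name)


def load_fixture() -> tuple[ProxyMatrix, dict[str, ClimateSeries]]:
    """Load the shipped copy of the bundled fixture."""
    with importlib.resources.as_file(_data_path("fixture_proxies.csv")) as p:
        pm = read_proxy_matrix(p)
    with importlib.resources.as_file(_data_path("fixture_climate.csv")) as p:
        values, _ = read_timeseries_csv(p)
    climate = {name: ClimateSeries(name, values[name], sigma=0.02) for name in values.columns}
    return pm, climate


def write_fixture_files(directory) -> None:
    """Regenerate the shipped fixture CSVs (used to refresh package data)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pm, climate = make_fixture(FIXTURE_SEED)
    write_proxy_matrix(pm, directory / "fixture_proxies.csv")
    first = next(iter(climate.values()))
    df = pd.DataFrame({k: v.data for k, v in climate.items()}, index=first.times)
    df.insert(0, "date", df.index.astype(str))
    df.to_csv(directory / "fixture_climate.csv", index=False)
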