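"""Forward proxy-system models, their inversions, and univariate baselines.

Three idealized coral pseudoproxies are generated from known climate series:

* Sr/Ca (mmol/mol): an affine function of SST with the canonical coral
  thermometer sensitivity of about -0.06 mmol/mol per degC.
* delta-18-O (permil): a linear function of SST and SSS (organic temperature
  slope, basin-scale seawater d18O-salinity slope) plus a constant offset
  placing the series in the observed coral aragonite range.
* delta-11-B (permil): the boron-isotope composition of skeletal carbonate,
  computed from the calcifying-fluid pH (itself an affine up-regulation of
  seawater pH with a temperature term) through borate/boric-acid isotope
  mass balance, with the dissociation constant pK_B evaluated from
  temperature and salinity.

Each nonlinear map ships with its closed-form inverse so the classical
univariate d11B -> pH reconstruction is available as a baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import NoiseSpec, add_noise, noise_sigma
from .core import ClimateSeries, ProxyMatrix

__all__ = [
    "ForwardModelParams",
    "srca_from_sst",
    "sst_from_srca",
    "d18o_from_sst_sss",
    "pkb_dickson",
    "phcf_from_phsw",
    "phsw_from_phcf",
    "d11b_from_ph",
    "ph_from_d11b",
    "d11b_baseline_phsw",
    "ols_univariate",
    "generate_pseudoproxies",
    "propagated_sd_srca",
    "propagated_sd_d18o",
    "BASELINE_SIGMA",
]


@dataclass(frozen=True)
class ForwardModelParams:
    """Constants of the pseudoproxy forward models.

    The parenthesized 1-sigma uncertainties on the Sr/Ca thermometer
    coefficients are retained for reference; the forward map uses the means.
    """

    srca_slope: float = -0.0607  # mmol/mol per degC
    srca_slope_sigma: float = 0.0090
    srca_intercept: float = 10.553  # mmol/mol
    srca_intercept_sigma: float = 0.292
    d18o_sst_slope: float = -0.22  # permil per degC
    d18o_sss_slope: float = 0.27  # permil per psu
    d18o_offset: float = -8.8839  # permil; places the mean in the coral range
    phcf_slope: float = 0.49
    phcf_intercept: float = 4.93
    phcf_sst_slope: float = -0.02  # pH_cf units per degC
    d11b_sw: float = 39.61  # permil, seawater boron isotope composition
    alpha: float = 1.0272  # boric acid / borate fractionation factor


PARAMS = ForwardModelParams()

#: Baseline (analytical) 1-sigma uncertainty for each pseudoproxy, in the
#: variable's own units.
BASELINE_SIGMA = {"SrCa": 0.009, "d18O": 0.10, "d11B": 0.09}


def srca_from_sst(sst, params: ForwardModelParams = PARAMS):
    """Sr/Ca (mmol/mol) from SST (degC): the coral thermometer forward map."""
    return params.srca_slope * np.asarray(sst, dtype=float) + params.srca_intercept


def sst_from_srca(srca, params: ForwardModelParams = PARAMS):
    """Invert the Sr/Ca thermometer (exact affine inverse)."""
    return (np.asarray(srca, dtype=float) - params.srca_intercept) / params.srca_slope


def d18o_from_sst_sss(sst, sss, params: ForwardModelParams = PARAMS):
    """Skeletal d18O (permil) from SST (degC) and SSS (psu)."""
    return (
        params.d18o_sst_slope * np.asarray(sst, dtype=float)
        + params.d18o_sss_slope * np.asarray(sss, dtype=float)
        + params.d18o_offset
    )


def pkb_dickson(sst, sss):
    """pK_B of boric acid in seawater (total scale) from SST (degC), SSS (psu).

    Empirical fit for the stoichiometric dissociation constant of boric acid
    in synthetic seawater (Dickson 1990), evaluated at T in kelvin; strictly
    decreasing in both temperature and salinity over oceanographic ranges.
    """
    t = np.asarray(sst, dtype=float)
    s = np.asarray(sss, dtype=float)
    if np.any((t <= -2) | (t >= 40)):
        raise ValueError("SST outside the (-2, 40) degC validity range")
    if np.any((s <= 0) | (s >= 45)):
        raise ValueError("SSS outside the (0, 45) psu validity range")
    tk = t + 273.15
    sqs = np.sqrt(s)
    ln_kb = (
        (-8966.90 - 2890.53 * sqs - 77.942 * s + 1.728 * s * sqs - 0.0996 * s**2) / tk
        + 148.0248
        + 137.1942 * sqs
        + 1.62142 * s
        + (-24.4344 - 25.085 * sqs - 0.2474 * s) * np.log(tk)
        + 0.053105 * sqs * tk
    )
    return -ln_kb / np.log(10.0)


def phcf_from_phsw(ph_sw, sst, params: ForwardModelParams = PARAMS):
    """Calcifying-fluid pH from seawater pH and SST (coral up-regulation)."""
    return (
        params.phcf_slope * np.asarray(ph_sw, dtype=float)
        + params.phcf_intercept
        + params.phcf_sst_slope * np.asarray(sst, dtype=float)
    )


def phsw_from_phcf(ph_cf, sst, params: ForwardModelParams = PARAMS):
    """Exact inverse of the calcifying-fluid up-regulation at fixed SST."""
    return (
        np.asarray(ph_cf, dtype=float)
        - params.phcf_intercept
        - params.phcf_sst_slope * np.asarray(sst, dtype=float)
    ) / params.phcf_slope


def d11b_from_ph(ph, pkb, params: ForwardModelParams = PARAMS):
    """Borate d11B (permil) from pH via isotope mass balance.

    With borate fraction f = 1 / (1 + 10^(pK_B - pH)), mass balance between
    boric acid and borate with fractionation factor alpha gives

        d11B = (d11B_sw - (1 - f) * 1000 * (alpha - 1)) / (f + (1 - f) * alpha)

    which increases strictly with pH and approaches d11B_sw as f -> 1.
    """
    ph = np.asarray(ph, dtype=float)
    pkb = np.asarray(pkb, dtype=float)
    f = 1.0 / (1.0 + 10.0 ** (pkb - ph))
    eps = 1000.0 * (params.alpha - 1.0)
    return (params.d11b_sw - (1.0 - f) * eps) / (f + (1.0 - f) * params.alpha)


def ph_from_d11b(d11b, pkb, params: ForwardModelParams = PARAMS):
    """pH (total scale) from borate d11B: the exact inverse of mass balance.

    pH = pK_B - log10( (d11B_sw - d11B) / (alpha*d11B - d11B_sw + 1000*(alpha-1)) )

    d11B must lie strictly between the low-pH asymptote and d11B_sw.
    """
    d11b = np.asarray(d11b, dtype=float)
    pkb = np.asarray(pkb, dtype=float)
    eps = 1000.0 * (params.alpha - 1.0)
    num = params.d11b_sw - d11b
    den = params.alpha * d11b - params.d11b_sw + eps
    if np.any(num <= 0) or np.any(den <= 0):
        raise ValueError(
            "d11B outside the physical range "
            f"({(params.d11b_sw - eps) / params.alpha:.3f}, {params.d11b_sw}) permil"
        )
    return pkb - np.log10(num / den)


def d11b_baseline_phsw(d11b, sst, sss, params: ForwardModelParams = PARAMS):
    """Univariate d11B -> pH_sw reconstruction (the mechanistic baseline).

    Inverts the isotope mass balance at the pK_B implied by the observed SST
    and SSS, then undoes the calcifying-fluid up-regulation.
    """
    pkb = pkb_dickson(sst, sss)
    ph_cf = ph_from_d11b(d11b, pkb, params)
    return phsw_from_phcf(ph_cf, sst, params)


def ols_univariate(x, y) -> tuple[float, float, np.ndarray]:
    """Ordinary least-squares line of y on x: (slope, intercept, fitted)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    vx = x.var(ddof=1)
    if vx == 0:
        raise ValueError("zero-variance predictor")
    slope = float(np.cov(x, y, ddof=1)[0, 1] / vx)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept, slope * x + intercept


def generate_pseudoproxies(
    climate: dict[str, ClimateSeries],
    noise: NoiseSpec | None = None,
    seed: int = 0,
    params: ForwardModelParams = PARAMS,
) -> ProxyMatrix:
    """Build the three-pseudoproxy matrix (SrCa, d18O, d11B) from climate.

    With ``noise=None`` the columns are the idealized (noise-free) forward
    images of the climate series and the attached sigmas are the baseline
    analytical uncertainties.  With a :class:`NoiseSpec`, noise at the
    specified RSD increment (and lag-1 autocorrelation) is added to each
    column and the attached sigmas reflect the total noise level.
    """
    sst = climate["SST"].data
    sss = climate["SSS"].data
    ph = climate["pH_sw"].data
    if not (sst.index.equals(sss.index) and sst.index.equals(ph.index)):
        raise ValueError("climate series must share one monthly grid")
    srca = srca_from_sst(sst.to_numpy(), params)
    d18o = d18o_from_sst_sss(sst.to_numpy(), sss.to_numpy(), params)
    pkb = pkb_dickson(sst.to_numpy(), sss.to_numpy())
    ph_cf = phcf_from_phsw(ph.to_numpy(), sst.to_numpy(), params)
    d11b = d11b_from_ph(ph_cf, pkb, params)
    df = pd.DataFrame({"SrCa": srca, "d18O": d18o, "d11B": d11b}, index=sst.index)
    sigma = dict(BASELINE_SIGMA)
    if noise is not None:
        rng = np.random.default_rng(seed)
        for var in df.columns:
            mean_ref = float(df[var].mean())
            df[var] = add_noise(
                df[var].to_numpy(),
                mean_ref=mean_ref,
                spec=noise,
                seed=rng,
                baseline_sigma=BASELINE_SIGMA[var],
            )
            sigma[var] = noise_sigma(mean_ref, noise, BASELINE_SIGMA[var])
    return ProxyMatrix(df, sigma)


def pseudoproxy_sigmas(
    climate: dict[str, ClimateSeries], noise: NoiseSpec
) -> dict[str, float]:
    """Total 1-sigma noise level per pseudoproxy at a given RSD increment,
    without perturbing the values (means stay idealized)."""
    ideal = generate_pseudoproxies(climate, noise=None)
    return {
        var: noise_sigma(float(ideal.data[var].mean()), noise, BASELINE_SIGMA[var])
        for var in ideal.variables
    }


def propagated_sd_srca(sd_sst: float, params: ForwardModelParams = PARAMS) -> float:
    """Closed-form sd of noise-free Sr/Ca given the SST sd."""
    return abs(params.srca_slope) * sd_sst


def propagated_sd_d18o(
    sd_sst: float, sd_sss: float, rho: float, params: ForwardModelParams = PARAMS
) -> float:
    """Closed-form sd of noise-free d18O given SST/SSS sds and correlation."""
    a, b = params.d18o_sst_slope, params.d18o_sss_slope
    var = a**2 * sd_sst**2 + b**2 * sd_sss**2 + 2 * a * b * rho * sd_sst * sd_sss
    return float(np.sqrt(var))
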