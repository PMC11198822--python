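"""Experiment harnesses: sweeps and cross-core transfer."""

import numpy as np
import pandas as pd
import pytest

from smite.climate import EmulatorConfig, emulate_climate
from smite.core import ClimateSeries, ProxyMatrix, SchemaError, fit_smite, predict
from smite.experiments import (
    cross_transfer,
    sweep_ar1,
    sweep_calibration_length,
    sweep_combinations,
    sweep_truncation,
)
from smite.forward import generate_pseudoproxies
from smite.metrics import MonteCarloConfig


@pytest.fixture(scope="module")
def short_climate():
    """Twenty emulated years: enough for structure, cheap to Monte-Carlo."""
    return emulate_climate(EmulatorConfig(seed=4, n_years=20))


class TestCombinations:
    def test_three_variables_give_four_fits(self, fixture_dataset):
        pm, clim = fixture_dataset
        res = sweep_combinations(pm.select(["SrCa", "d18O", "d11B"]), clim["SST"])
        assert len(res.table) == 4  # C(3,2) + C(3,3)

    def test_deterministic_ordering(self, fixture_dataset):
        pm, clim = fixture_dataset
        sub = pm.select(["SrCa", "d18O", "d11B"])
        r1 = sweep_combinations(sub, clim["SST"])
        r2 = sweep_combinations(sub, clim["SST"])
        assert r1.table["variables"].tolist() == r2.table["variables"].tolist()
        assert r1.table["variables"].tolist() == sorted(
            r1.table["variables"].tolist(), key=lambda v: (v.count("+"), v)
        )

    def test_full_set_r_bounds_every_subset(self, fixture_dataset):
        pm, clim = fixture_dataset
        res = sweep_combinations(pm, clim["SST"], sizes=[2, 7])
        full_r = res.table[res.table["size"] == 7]["r"].iloc[0]
        assert (res.table["r"] <= full_r + 1e-10).all()

    def test_nesting_beats_best_univariate_everywhere(self, fixture_dataset):
        pm, clim = fixture_dataset
        res = sweep_combinations(pm, clim["SST"], sizes=[2, 3])
        assert (res.table["r"] >= res.table["best_univariate_r"] - 1e-10).all()


class TestTruncationSweep:
    def test_level_count_and_reference_cell(self, fixture_dataset):
        pm, clim = fixture_dataset
        res = sweep_truncation(pm, clim["SST"], cfg=MonteCarloConfig(n_iter=120, seed=0))
        assert res.table["k_trunc"].tolist() == [0, 1, 2, 3, 4, 5]
        model = fit_smite(pm, clim["SST"], k_trunc=0)
        pred = predict(model, pm)
        r0 = np.corrcoef(pred.data, clim["SST"].data)[0, 1]
        assert res.table.iloc[0]["r"] == pytest.approx(r0, abs=1e-12)

    def test_tradeoff_on_trailing_noise_instance(self, trailing_noise_instance):
        A, b = trailing_noise_instance
        res = sweep_truncation(A, b, cfg=MonteCarloConfig(n_iter=250, seed=3))
        rmse_path = res.table["rmse_min"].to_numpy()
        assert np.all(np.diff(rmse_path) >= -1e-12)
        widths = (
            res.params.assign(w=lambda d: d["hi95"] - d["lo95"])
            .groupby("k_trunc")["w"]
            .mean()
            .to_numpy()
        )
        assert np.all(np.diff(widths) <= 1e-12)


class TestCalibrationLengthSweep:
    def test_grid_and_parameter_stability(self, short_climate):
        res = sweep_calibration_length(
            short_climate,
            lengths=[5, 10, 15, 20],
            cfg=MonteCarloConfig(n_iter=150, seed=0),
            targets=("SST",),
        )
        assert res.table["calibration_years"].tolist() == [5, 10, 15, 20]
        p = res.params
        # SST parameters are stable: the spread of each parameter across
        # lengths stays below its average CI half-width.
        for var, grp in p.groupby("variable"):
            spread = grp["x_mean"].std(ddof=1)
            half_width = ((grp["hi95"] - grp["lo95"]) / 2).mean()
            assert spread < half_width

    def test_segment_modes_differ(self, short_climate):
        first = sweep_calibration_length(
            short_climate, lengths=[5], cfg=MonteCarloConfig(n_iter=120, seed=0),
            targets=("SST",), segment="first",
        )
        last = sweep_calibration_length(
            short_climate, lengths=[5], cfg=MonteCarloConfig(n_iter=120, seed=0),
            targets=("SST",), segment="last",
        )
        assert not np.allclose(
            first.params["x_mean"].to_numpy(), last.params["x_mean"].to_numpy()
        )


class TestAr1Sweep:
    def test_degradation_concentrated_at_high_autocorrelation(self, short_climate):
        # Autocorrelated measurement noise of fixed marginal sd barely moves
        # the prediction bands, but it destabilizes the fitted parameters —
        # and sharply so only at very high lag-1 values.
        res = sweep_ar1(
            short_climate,
            phis=(0.0, 0.5, 0.95),
            rsd_increment=0.5,
            cfg=MonteCarloConfig(n_iter=200, seed=0),
            targets=("SST",),
        )
        w = (
            res.params.assign(w=lambda d: d["hi95"] - d["lo95"])
            .groupby("ar1_phi")["w"]
            .mean()
        )
        assert w.loc[0.95] > w.loc[0.5] > w.loc[0.0]
        assert (w.loc[0.95] - w.loc[0.5]) > (w.loc[0.5] - w.loc[0.0])

    def test_reproducible(self, short_climate):
        kw = dict(
            phis=(0.0, 0.5),
            rsd_increment=0.3,
            cfg=MonteCarloConfig(n_iter=120, seed=7),
            targets=("SST",),
            seed=7,
        )
        r1 = sweep_ar1(short_climate, **kw)
        r2 = sweep_ar1(short_climate, **kw)
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestCrossTransfer:
    def test_self_transfer_is_identity(self, fixture_dataset):
        pm, clim = fixture_dataset
        model = fit_smite(pm, clim["SST"])
        report, pred = cross_transfer(model, pm, clim["SST"], stats_mode="receiver")
        native = predict(model, pm)
        assert np.allclose(pred.data.to_numpy(), native.data.to_numpy(), atol=1e-10)
        assert report.r == pytest.approx(1.0, abs=1e-6)

    def test_permuted_columns_identical(self, fixture_dataset):
        pm, clim = fixture_dataset
        model = fit_smite(pm, clim["SST"])
        shuffled = pm.select(list(reversed(pm.variables)))
        _, pred_a = cross_transfer(model, pm, clim["SST"])
        _, pred_b = cross_transfer(model, shuffled, clim["SST"])
        assert np.array_equal(pred_a.data.to_numpy(), pred_b.data.to_numpy())

    def test_missing_variable_schema_error(self, fixture_dataset):
        pm, clim = fixture_dataset
        model = fit_smite(pm, clim["SST"])
        with pytest.raises(SchemaError):
            cross_transfer(model, pm.select(pm.variables[:-1]), clim["SST"])

    def test_two_noisy_cores_transfer_like_natives(self, short_climate):
        # Same climate, independent noise realizations: exchangeability
        # means donor parameters transfer with nearly native skill.
        from smite.climate import NoiseSpec

        spec = NoiseSpec(gaussian_rsd_increment=0.3)
        core_a = generate_pseudoproxies(short_climate, noise=spec, seed=101)
        core_b = generate_pseudoproxies(short_climate, noise=spec, seed=202)
        sst = short_climate["SST"]
        model_a = fit_smite(core_a, sst)
        model_b = fit_smite(core_b, sst)
        native_b = np.corrcoef(predict(model_b, core_b).data, sst.data)[0, 1]
        report, _ = cross_transfer(model_a, core_b, sst, stats_mode="receiver")
        assert report.r == pytest.approx(native_b, abs=0.05)

    def test_donor_stats_mode_runs(self, fixture_dataset):
        pm, clim = fixture_dataset
        model = fit_smite(pm, clim["SST"])
        report, _ = cross_transfer(model, pm, clim["SST"], stats_mode="donor")
        assert report.r == pytest.approx(1.0, abs=1e-6)
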