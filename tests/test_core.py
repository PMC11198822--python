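"""Calibration engine: normalization, SVD, pseudoinverse, truncation."""

import numpy as np
import pandas as pd
import pytest

from smite.core import (
    AdvisoryError,
    ClimateSeries,
    DegenerateColumnError,
    NormalizationStats,
    ProxyMatrix,
    RegularizationLimitError,
    SchemaError,
    SmiteModel,
    cumulative_variance,
    fit_smite,
    predict,
    solve_parameters,
    suggest_truncation,
    svd_decompose,
    zscore,
)


def _grid(n, start="2000-01"):
    return pd.period_range(start, periods=n, freq="M")


def _random_instance(rng, t=100, p=4):
    idx = _grid(t)
    X = rng.standard_normal((t, p)) @ rng.standard_normal((p, p)) + rng.normal(0, 1, p)
    A = ProxyMatrix(pd.DataFrame(X, index=idx, columns=[f"v{j}" for j in range(p)]))
    y = X @ rng.standard_normal(p) + 0.3 * rng.standard_normal(t)
    b = ClimateSeries("SST", pd.Series(y, index=idx))
    return A, b


class TestZscore:
    def test_window_columns_become_standard(self, rng):
        A, b = _random_instance(rng)
        stats = NormalizationStats.from_window(A.data, b.data)
        Z = zscore(A.data, stats)
        assert np.allclose(Z.mean(), 0, atol=1e-12)
        assert np.allclose(Z.std(ddof=1), 1, atol=1e-12)

    def test_constant_column_rejected(self):
        idx = _grid(10)
        df = pd.DataFrame({"flat": np.ones(10), "ok": np.arange(10.0)}, index=idx)
        with pytest.raises(DegenerateColumnError, match="flat"):
            NormalizationStats.from_window(df, pd.Series(np.arange(10.0), index=idx))

    def test_out_of_window_rows_use_window_stats(self):
        # Two-segment series: the second segment is shifted, so normalizing
        # it with first-segment stats must differ from self-normalization.
        idx = _grid(24)
        vals = np.concatenate([np.arange(12.0), np.arange(12.0) + 10])
        df = pd.DataFrame({"v": vals}, index=idx)
        first = df.iloc[:12]
        stats = NormalizationStats.from_window(first, pd.Series(np.arange(12.0), index=idx[:12]))
        z = zscore(df, stats)
        hand = (vals - first["v"].mean()) / first["v"].std(ddof=1)
        assert np.allclose(z["v"].to_numpy(), hand)
        assert abs(z["v"].iloc[-1]) > 3  # far outside the window distribution


class TestSVD:
    def test_identity_matrix_unit_singular_values(self):
        f = svd_decompose(np.eye(2))
        assert np.allclose(f.S, [1.0, 1.0])

    def test_duplicate_columns_are_rank_one(self, rng):
        col = rng.standard_normal(30)
        col = (col - col.mean()) / col.std(ddof=1)
        f = svd_decompose(np.column_stack([col, col]))
        assert f.S[1] <= 1e-10 * f.S[0]

    def test_frobenius_norm_identity(self, rng):
        X = rng.standard_normal((20, 3))
        f = svd_decompose(X)
        assert np.isclose((f.S**2).sum(), (X**2).sum())

    def test_reconstruction_and_ordering(self, rng):
        X = rng.standard_normal((40, 5))
        f = svd_decompose(X)
        assert np.allclose(f.reconstruct(), X, atol=1e-10 * np.abs(X).max())
        assert np.all(np.diff(f.S) <= 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            svd_decompose(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestSolveParameters:
    def test_self_regression(self, rng):
        y = rng.standard_normal(50)
        f = svd_decompose(y[:, None])
        x = solve_parameters(f, y)
        assert np.allclose(x, [1.0])

    def test_duplicated_predictor_minimum_norm(self, rng):
        y = rng.standard_normal(50)
        f = svd_decompose(np.column_stack([y, y]))
        x = solve_parameters(f, y)
        assert np.allclose(x, [0.5, 0.5], atol=1e-10)

    def test_matches_normal_equations(self, rng):
        X = rng.standard_normal((60, 3))
        y = rng.standard_normal(60)
        f = svd_decompose(X)
        x = solve_parameters(f, y)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(x, oracle, atol=1e-8)

    def test_truncation_limit(self, rng):
        f = svd_decompose(rng.standard_normal((30, 4)))
        with pytest.raises(RegularizationLimitError):
            solve_parameters(f, rng.standard_normal(30), k_trunc=3)

    def test_sign_flip_invariance(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        f = svd_decompose(X)
        x_ref = solve_parameters(f, y, k_trunc=1)
        for j in range(4):
            g = svd_decompose(X)
            g.U[:, j] *= -1
            g.V[:, j] *= -1
            assert np.allclose(solve_parameters(g, y, k_trunc=1), x_ref, atol=1e-12)


class TestFitPredict:
    def test_perfect_single_proxy_roundtrip(self, rng):
        idx = _grid(48)
        y = pd.Series(25 + 2 * np.sin(np.arange(48) / 4) + 0.1 * rng.standard_normal(48), index=idx)
        A = ProxyMatrix(pd.DataFrame({"v": y.to_numpy()}, index=idx))
        b = ClimateSeries("SST", y)
        model = fit_smite(A, b)
        pred = predict(model, A)
        assert np.allclose(pred.data.to_numpy(), y.to_numpy(), atol=1e-10)

    def test_matches_multiple_ols_in_and_out_of_window(self, rng):
        A, b = _random_instance(rng, t=180, p=7)
        window = (str(A.times[0]), str(A.times[99]))
        model = fit_smite(A, b, window=window)
        pred = predict(model, A)
        # Independent oracle: OLS of the z-scored target on z-scored
        # predictors, both normalized with window stats.
        Aw = A.data.iloc[:100]
        bw = b.data.iloc[:100]
        Zw = (Aw - Aw.mean()) / Aw.std(ddof=1)
        yw = (bw - bw.mean()) / bw.std(ddof=1)
        beta = np.linalg.lstsq(Zw.to_numpy(), yw.to_numpy(), rcond=None)[0]
        Z_all = (A.data - Aw.mean()) / Aw.std(ddof=1)
        oracle = Z_all.to_numpy() @ beta * bw.std(ddof=1) + bw.mean()
        assert np.allclose(pred.data.to_numpy(), oracle, atol=1e-8)

    def test_max_truncation_uses_two_leading_triplets(self, rng):
        A, b = _random_instance(rng, t=120, p=7)
        model = fit_smite(A, b, k_trunc=5)
        f = model.factors
        stats = model.stats
        b_a = (b.data - stats.mu_b) / stats.sd_b
        manual = f.V[:, :2] @ ((f.U[:, :2].T @ b_a.to_numpy()) / f.S[:2])
        assert np.allclose(model.x_dagger, manual, atol=1e-12)

    def test_pcr_equivalence_any_truncation(self, rng):
        # Independent oracle: principal-components regression built from the
        # eigendecomposition of the correlation matrix.
        A, b = _random_instance(rng, t=150, p=6)
        for k in (0, 1, 3, 4):
            model = fit_smite(A, b, k_trunc=k)
            Z = ((A.data - A.data.mean()) / A.data.std(ddof=1)).to_numpy()
            y = ((b.data - b.data.mean()) / b.data.std(ddof=1)).to_numpy()
            corr = Z.T @ Z
            evals, evecs = np.linalg.eigh(corr)
            order = np.argsort(evals)[::-1]
            keep = order[: 6 - k]
            scores = Z @ evecs[:, keep]
            gamma = np.linalg.lstsq(scores, y, rcond=None)[0]
            pcr_pred = scores @ gamma
            smite_pred = Z @ model.x_dagger
            assert np.allclose(smite_pred, pcr_pred, atol=1e-8)

    def test_in_sample_r2_monotone_in_nested_subsets(self, rng):
        A, b = _random_instance(rng, t=100, p=5)
        names = A.variables
        last_r2 = -np.inf
        for j in range(1, 6):
            sub = A.select(names[:j])
            model = fit_smite(sub, b)
            pred = predict(model, sub)
            r = np.corrcoef(pred.data, b.data)[0, 1]
            assert r**2 >= last_r2 - 1e-12
            last_r2 = r**2

    def test_back_transform_mean_conservation(self, rng):
        A, b = _random_instance(rng, t=90, p=4)
        model = fit_smite(A, b)
        pred = predict(model, A)
        assert np.isclose(pred.data.mean(), model.stats.mu_b, atol=1e-10)

    def test_missing_variable_schema_error(self, rng):
        A, b = _random_instance(rng, t=50, p=3)
        model = fit_smite(A, b)
        with pytest.raises(SchemaError, match="v2"):
            predict(model, A.select(["v0", "v1"]))

    def test_zero_anomaly_predicts_target_mean(self, rng):
        A, b = _random_instance(rng, t=50, p=3)
        model = fit_smite(A, b)
        flat = ProxyMatrix(
            pd.DataFrame(
                np.tile(model.stats.mu.to_numpy(), (10, 1)),
                index=_grid(10, "2030-01"),
                columns=A.variables,
            )
        )
        pred = predict(model, flat)
        assert np.allclose(pred.data, model.stats.mu_b)

    def test_underdetermined_window_raises(self, rng):
        A, b = _random_instance(rng, t=24, p=6)
        with pytest.raises(Exception, match="rows"):
            with pytest.warns(UserWarning):
                fit_smite(A, b, window=("2000-01", "2000-04"))


class TestSerialization:
    def test_json_roundtrip_bit_identical(self, rng):
        A, b = _random_instance(rng, t=80, p=5)
        model = fit_smite(A, b, k_trunc=2)
        text = model.to_json()
        clone = SmiteModel.from_json(text)
        assert clone.variables == model.variables
        assert clone.window == model.window
        assert clone.k_trunc == model.k_trunc
        assert np.array_equal(clone.x_dagger, model.x_dagger)
        assert clone.to_json() == SmiteModel.from_json(clone.to_json()).to_json()
        pred_a = predict(model, A).data
        pred_b = predict(clone, A).data
        assert np.array_equal(pred_a.to_numpy(), pred_b.to_numpy())

    def test_unknown_schema_rejected(self):
        with pytest.raises(SchemaError):
            SmiteModel.from_json('{"schema": "other/9"}')


class TestTruncationGuidance:
    def test_cumulative_variance_normalized_by_sum(self):
        cv = cumulative_variance([10, 5, 1, 0.1])
        assert np.allclose(cv, [0.621, 0.932, 0.994, 1.0], atol=5e-4)

    def test_square_system_advisory_error(self, rng):
        A, b = _random_instance(rng, t=60, p=3)
        with pytest.raises(AdvisoryError):
            suggest_truncation(A, b, n_targets=3)

    def test_flat_spectrum_recommends_no_truncation(self):
        # Fourier harmonics are exactly orthogonal with zero mean and equal
        # norms, so the z-scored matrix has a perfectly flat singular
        # spectrum: no inflection point, hence no truncation.
        n = 72
        idx = _grid(n)
        t = np.arange(n)
        cols = {
            "c1": np.cos(2 * np.pi * t / n),
            "s1": np.sin(2 * np.pi * t / n),
            "c2": np.cos(4 * np.pi * t / n),
            "s2": np.sin(4 * np.pi * t / n),
        }
        df = pd.DataFrame(cols, index=idx)
        A = ProxyMatrix(df, {v: 0.01 for v in cols})
        b = ClimateSeries("SST", pd.Series(df.to_numpy() @ np.ones(4), index=idx), sigma=0.01)
        from smite.metrics import MonteCarloConfig

        diag = suggest_truncation(A, b, cfg=MonteCarloConfig(n_iter=150, seed=0))
        assert np.allclose(diag.retained_variance[0], 1.0)
        assert diag.recommended == 0

    def test_recommendation_needs_variance_drop_and_uncertainty_drop(
        self, trailing_noise_instance
    ):
        from smite.metrics import MonteCarloConfig

        A, b = trailing_noise_instance
        diag = suggest_truncation(
            A, b, threshold=0.70, cfg=MonteCarloConfig(n_iter=150, seed=0)
        )
        k = diag.recommended
        assert 0 <= k <= len(A.variables) - 2
        if k > 0:
            assert diag.retained_variance[k] < 0.70
            assert diag.uncertainty_total[k] < diag.uncertainty_total[k - 1]
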