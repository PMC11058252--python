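import numpy as np
import pytest

from colim import (
    ModelSpec,
    MonodParams,
    bootstrap_fit,
    build_matrix,
    compare_models,
    default_fit_spec,
    growth_rate_multiplicative,
    nls_fit,
    param_significance,
    predict_map,
    predicted_vs_observed,
)
from colim.fitting import resample_conditions
from colim.growth_extraction import GrowthRateMatrix, GrowthRateRecord
from colim.synthetic_data import simulate_rate_matrices


@pytest.fixture(scope="module")
def noise_free_matrix(noise_free_series, env):
    return build_matrix(noise_free_series, env, background=100.0)


def matrix_with_se(env, params, se_value, mu_offset=0.0, rep="R1"):
    records = {}
    for r in range(env.n_rows):
        for c in range(env.n_cols):
            mu = growth_rate_multiplicative(env.par_at(c), env.nitrogen_at(r), params)
            records[(rep, r, c)] = GrowthRateRecord(
                replicate_id=rep, row=r, col=c, mu=mu + mu_offset,
                se=se_value, window_center_time_h=84.0, n_window=9,
            )
    return GrowthRateMatrix(records=records, env=env)


class TestNlsFit:
    def test_noise_free_recovery_of_free_parameters(self, noise_free_matrix,
                                                    fitted_params):
        fit = nls_fit(noise_free_matrix)
        assert fit.converged
        assert fit.free_values["L0"] == pytest.approx(fitted_params.L0, rel=1e-6)
        assert fit.free_values["K_L"] == pytest.approx(fitted_params.K_L, rel=1e-6)
        assert fit.free_values["K_N"] == pytest.approx(fitted_params.K_N, rel=1e-6)

    def test_basic_form_fits_only_three_parameters(self, noise_free_matrix):
        spec = ModelSpec(
            form="multiplicative_basic",
            free_params=frozenset({"mu_0", "K_L", "K_N"}),
        )
        fit = nls_fit(noise_free_matrix, spec)
        assert set(fit.free_values) == {"mu_0", "K_L", "K_N"}
        assert fit.params.L0 == 0.0 and fit.params.N0 == 0.0

    def test_underdetermined_single_condition_rejected(self, env, fitted_params):
        m = matrix_with_se(env, fitted_params, 0.1)
        one = GrowthRateMatrix(
            records={k: v for k, v in list(m.records.items())[:1]}, env=env
        )
        with pytest.raises(ValueError):
            nls_fit(one)

    def test_identical_observations_rejected(self, env):
        records = {
            ("R1", r, c): GrowthRateRecord("R1", r, c, 1.0, 0.1, 84.0, 9)
            for r in range(8) for c in range(8)
        }
        with pytest.raises(ValueError, match="degenerate|identical"):
            nls_fit(GrowthRateMatrix(records=records, env=env))

    def test_deterministic_given_data_and_init(self, noise_free_matrix):
        f1 = nls_fit(noise_free_matrix)
        f2 = nls_fit(noise_free_matrix)
        assert f1.free_values == f2.free_values


class TestBootstrap:
    def test_degenerate_identical_replicates_collapse_to_point_fit(
        self, noise_free_matrix, env
    ):
        # three byte-identical replicates, all se = 0: every bootstrap
        # draw is the same matrix, so sds vanish and means equal the fit
        reps = []
        for i in range(3):
            recs = {
                (f"R{i+1}", r, c): v
                for (rep, r, c), v in noise_free_matrix.records.items()
                if rep == "R1"
            }
            reps.append(GrowthRateMatrix(records=recs, env=env))
        res = bootstrap_fit(reps, B=20, seed=0)
        point = nls_fit(reps[0])
        for p in res.means:
            assert res.sds[p] == pytest.approx(0.0, abs=1e-12)
            assert res.means[p] == pytest.approx(point.free_values[p], rel=1e-12)

    def test_selection_weights_follow_inverse_squared_se(self, env, fitted_params):
        # se ratio 1:3 -> weights 1 : 1/9 -> replicate 1 picked w.p. 0.9
        m1 = matrix_with_se(env, fitted_params, 0.1, rep="R1")
        m2 = matrix_with_se(env, fitted_params, 0.3, rep="R2")
        rng = np.random.default_rng(77)
        picks = []
        B = 1000
        for _ in range(B):
            _, chosen = resample_conditions([m1, m2], rng)
            picks.append(chosen)
        freq1 = np.mean(np.concatenate(picks) == 0)
        n = B * 64
        sigma = np.sqrt(0.9 * 0.1 / n)
        assert abs(freq1 - 0.9) < 3 * sigma

    def test_zero_se_takes_largest_finite_weight(self, env, fitted_params):
        m1 = matrix_with_se(env, fitted_params, 0.0, rep="R1")
        m2 = matrix_with_se(env, fitted_params, 0.1, rep="R2")
        rng = np.random.default_rng(3)
        _, chosen = resample_conditions([m1, m2], rng)
        # equal weights -> both replicates appear over 64 conditions
        assert set(np.unique(chosen)) == {0, 1}

    def test_recovery_under_noise(self, env, fitted_params):
        mats = simulate_rate_matrices(env, fitted_params, noise_sd=0.1,
                                      n_replicates=3, seed=42)
        res = bootstrap_fit(mats, B=100, seed=7)
        truth = {"L0": 50.8, "K_L": 57.2, "K_N": 2.8}
        for p, v in truth.items():
            assert abs(res.means[p] - v) / v < 0.25

    def test_missing_condition_warns_and_drops(self, env, fitted_params):
        m = matrix_with_se(env, fitted_params, 0.1)
        del m.records[("R1", 0, 0)]
        with pytest.warns(UserWarning, match="no record"):
            res = bootstrap_fit([m], B=5, seed=0)
        assert res.B == 5


class TestSignificance:
    def _result_from_samples(self, samples, seed=0):
        import pandas as pd

        from colim.fitting import BootstrapResult, FitResult

        spec = default_fit_spec()
        means = {p: float(np.mean(s)) for p, s in samples.items()}
        sds = {p: float(np.std(s, ddof=1)) for p, s in samples.items()}
        point = FitResult(
            params=MonodParams(2.4, max(means.get("L0", 0.0), 0.0),
                               means["K_L"], 0.0, means["K_N"]),
            free_values=means, sse=0.0, r2=1.0, n_obs=64, converged=True,
            spec=spec,
        )
        return BootstrapResult(
            samples={p: np.asarray(s) for p, s in samples.items()},
            means=means, sds=sds,
            correlations=pd.DataFrame(samples).corr(),
            B=len(next(iter(samples.values()))), seed=seed, spec=spec,
            point_fit=point,
        )

    def test_mean_at_null_gives_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, 1000)
        s = s - s.mean()
        res = self._result_from_samples(
            {"L0": s, "K_L": s + 57, "K_N": s * 0.1 + 2.8}
        )
        out = param_significance(res, "L0", 0.0)
        assert out["p_wald"] == pytest.approx(1.0)

    def test_wald_p_value_at_1_96_sigma(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0, 1, 200_000)
        s = (s - s.mean()) / s.std(ddof=1) + 1.96
        res = self._result_from_samples(
            {"L0": s, "K_L": s + 57, "K_N": s * 0.1 + 2.8}
        )
        out = param_significance(res, "L0", 0.0)
        assert out["p_wald"] == pytest.approx(0.05, abs=0.001)

    def test_one_sided_samples_bound_tail_p(self):
        s = np.abs(np.random.default_rng(2).normal(5, 1, 1000)) + 0.1
        res = self._result_from_samples(
            {"L0": s, "K_L": s + 57, "K_N": s * 0.1 + 2.8}
        )
        out = param_significance(res, "L0", 0.0)
        assert out["p_tail"] <= 2 / 1000


class TestCompareModels:
    def test_multiplicative_data_favours_multiplicative_form(self, env,
                                                             fitted_params):
        mats = simulate_rate_matrices(env, fitted_params, noise_sd=0.1,
                                      n_replicates=3, seed=5)
        specs = [
            default_fit_spec(),
            ModelSpec("liebig_min", frozenset({"L0", "K_L", "K_N"}),
                      {"mu_max": 2.4, "N0": 0.0}),
        ]
        table = compare_models(mats, specs, B=20, seed=5, n_starts=3)
        assert table.loc["multiplicative_storage", "sse_mean"] <= table.loc[
            "liebig_min", "sse_mean"
        ]
        assert table.loc["multiplicative_storage", "rank_sse"] == 1

    def test_nested_storage_form_never_worse_than_basic(self, env, fitted_params):
        # storage form with free mu_max and L0 contains the basic form
        # (mu_0 = mu_max, L0 = 0), so its optimal SSE cannot be larger
        mats = simulate_rate_matrices(env, fitted_params, noise_sd=0.1,
                                      n_replicates=3, seed=9)
        storage = ModelSpec(
            "multiplicative_storage",
            frozenset({"mu_max", "L0", "K_L", "K_N"}),
            {"N0": 0.0},
        )
        basic = ModelSpec(
            "multiplicative_basic", frozenset({"mu_0", "K_L", "K_N"})
        )
        rng = np.random.default_rng(11)
        for _ in range(5):
            m, _ = resample_conditions(mats, rng)
            f_storage = nls_fit(m, storage)
            f_basic = nls_fit(m, basic)
            assert f_storage.sse <= f_basic.sse * (1 + 1e-6) + 1e-9

    def test_single_spec_gives_unranked_single_row(self, env, fitted_params):
        mats = simulate_rate_matrices(env, fitted_params, noise_sd=0.1, seed=1)
        table = compare_models(mats, [default_fit_spec()], B=5, seed=1, n_starts=2)
        assert len(table) == 1
        assert "rank_sse" not in table.columns


class TestPrediction:
    def test_map_saturates_at_mu_max_and_is_monotone(self, fitted_params):
        L = np.array([0.0, 10.0, 45.0, 1e12])
        N = np.array([0.0, 5.0, 35.0, 1e12])
        grid = predict_map(fitted_params, L, N)
        assert grid.values[-1, -1] == pytest.approx(2.4, rel=1e-9)
        assert np.all(np.diff(grid.values, axis=0) >= -1e-12)
        assert np.all(np.diff(grid.values, axis=1) >= -1e-12)

    def test_lake_conditions_are_ordered_and_finite(self, fitted_params):
        # deep, turbid lake (0.1 PAR, 93 µM N) vs clear lake (100 PAR, 17 µM)
        grid = predict_map(fitted_params, np.array([0.1, 100.0]),
                           np.array([17.0, 93.0]))
        cayuga = grid.loc[93.0, 0.1]
        hemlock = grid.loc[17.0, 100.0]
        assert 0 < cayuga < 2.4 and 0 < hemlock < 2.4
        assert hemlock > cayuga

    def test_scalar_grid(self, fitted_params):
        grid = predict_map(fitted_params, np.array([10.0]), np.array([5.0]))
        assert grid.shape == (1, 1)

    def test_predicted_vs_observed_identity_on_self_fit(self, noise_free_matrix,
                                                        fitted_params):
        pred, obs, r2 = predicted_vs_observed(noise_free_matrix, fitted_params)
        assert np.allclose(pred, obs, atol=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_shuffled_observations_degrade_r2(self, noise_free_matrix, env,
                                              fitted_params):
        rng = np.random.default_rng(0)
        keys = sorted(noise_free_matrix.records)
        mus = [noise_free_matrix.records[k].mu for k in keys]
        rng.shuffle(mus)
        shuffled = GrowthRateMatrix(
            records={
                k: GrowthRateRecord(k[0], k[1], k[2], mu, 0.0, 84.0, 9)
                for k, mu in zip(keys, mus)
            },
            env=env,
        )
        _, _, r2 = predicted_vs_observed(shuffled, fitted_params)
        assert r2 < 0.5

    def test_r2_matches_algebraic_definition(self, noise_free_matrix,
                                             fitted_params):
        pred, obs, r2 = predicted_vs_observed(noise_free_matrix, fitted_params)
        sse = np.sum((obs - pred) ** 2)
        sst = np.sum((obs - obs.mean()) ** 2)
        assert r2 == pytest.approx(1 - sse / sst, abs=1e-12)
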