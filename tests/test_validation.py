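import numpy as np
import pytest
from scipy import stats

from freundlich_qsar import (
    acceptance_check,
    coefficient_tests,
    external_validation,
    fit_ols,
    q2_lmo,
    q2_loo,
    vif,
    y_randomization,
)
from freundlich_qsar.model_build import FitMetrics
from freundlich_qsar.validation import ValidationReport

from conftest import planted_dataset, random_descriptors


def loo_refit_oracle(X, y, subset):
    """Explicit n-refit leave-one-out PRESS, independent of the hat
    shortcut."""
    n = X.shape[0]
    Xd = np.column_stack([np.ones(n), X.columns(subset)])
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        beta = np.linalg.solve(
            Xd[mask].T @ Xd[mask], Xd[mask].T @ y[mask]
        )
        press += (y[i] - Xd[i] @ beta) ** 2
    tss = np.sum((y - y.mean()) ** 2)
    return 1.0 - press / tss


class TestQ2Loo:
    def test_perfect_model_gives_one(self):
        X = random_descriptors(15, 2, seed=0)
        y = 1.0 + 2.0 * X.df["d1"].to_numpy()
        fit = fit_ols(X, y, ["d1"])
        assert q2_loo(fit, X, y) == pytest.approx(1.0, abs=1e-10)

    def test_hat_shortcut_equals_explicit_refits(self):
        for seed in range(10):
            X = random_descriptors(20, 3, seed=seed)
            y = np.random.default_rng(seed).standard_normal(20)
            fit = fit_ols(X, y, X.descriptor_names)
            assert q2_loo(fit, X, y) == pytest.approx(
                loo_refit_oracle(X, y, X.descriptor_names), abs=1e-10
            )

    def test_q2_never_exceeds_r2(self):
        for seed in range(20):
            X = random_descriptors(25, 4, seed=seed)
            y = np.random.default_rng(seed + 500).standard_normal(25)
            fit = fit_ols(X, y, X.descriptor_names)
            assert q2_loo(fit, X, y) <= fit.metrics.r_squared + 1e-12

    def test_pure_noise_mean_q2_negative(self):
        # under the null, LOO Q^2 is negative in expectation
        q2s = []
        for seed in range(500):
            X = random_descriptors(30, 5, seed=seed)
            y = np.random.default_rng(seed + 10_000).standard_normal(30)
            fit = fit_ols(X, y, X.descriptor_names)
            q2s.append(q2_loo(fit, X, y))
        assert np.mean(q2s) < 0

    def test_exact_leverage_point_raises(self):
        X = random_descriptors(5, 1, seed=1)
        # one point isolated far from the others creates h ~ 1 only in
        # pathological designs; force it with a duplicated-row design
        X.df["d1"] = [0.0, 0.0, 0.0, 0.0, 1.0]
        y = np.array([1.0, 1.1, 0.9, 1.0, 5.0])
        fit = fit_ols(X, y, ["d1"])
        with pytest.raises(ZeroDivisionError, match="h=1"):
            q2_loo(fit, X, y)


class TestQ2Lmo:
    def test_exact_linear_data_every_repeat_one(self):
        X = random_descriptors(20, 2, seed=0)
        y = 0.5 - X.df["d2"].to_numpy()
        fit = fit_ols(X, y, ["d2"])
        res = q2_lmo(fit, X, y, leave_fraction=0.3, repeats=20, seed=1)
        np.testing.assert_allclose(res.per_repeat, 1.0, atol=1e-10)

    def test_exhaustive_leave_one_reproduces_loo(self):
        X = random_descriptors(18, 3, seed=2)
        y = np.random.default_rng(3).standard_normal(18)
        fit = fit_ols(X, y, X.descriptor_names)
        groups = [[i] for i in range(18)]
        res = q2_lmo(fit, X, y, groups=groups)
        assert res.pooled == pytest.approx(q2_loo(fit, X, y), abs=1e-12)

    def test_same_seed_identical_repeats(self):
        X, y = planted_dataset(seed=5)
        fit = fit_ols(X, y, ["E_LUMO", "sum_q(O+N)"])
        a = q2_lmo(fit, X, y, 0.3, 30, seed=9)
        b = q2_lmo(fit, X, y, 0.3, 30, seed=9)
        np.testing.assert_array_equal(a.per_repeat, b.per_repeat)

    def test_infeasible_fraction_errors(self):
        X = random_descriptors(10, 3, seed=4)
        y = np.arange(10.0)
        fit = fit_ols(X, y, X.descriptor_names)
        with pytest.raises(ValueError):
            q2_lmo(fit, X, y, leave_fraction=0.99, repeats=5)


class TestExternalValidation:
    def _fit(self):
        X = random_descriptors(30, 2, seed=0)
        y = 1.0 + X.df["d1"].to_numpy() * 2.0
        return fit_ols(X, y, ["d1"]), X, y

    def test_perfect_predictions_all_one(self):
        fit, X, y = self._fit()
        Xt = random_descriptors(8, 2, seed=1)
        yt = fit.predict(Xt)
        ext = external_validation(fit, Xt, yt, y)
        for v in (ext.r2_ext, ext.q2_f1, ext.q2_f2, ext.q2_f3):
            assert v == pytest.approx(1.0, abs=1e-10)

    def test_uninformative_predictor_near_zero_f1(self):
        # a model carrying no signal predicts ~ the training mean, which
        # scores ~0 under Q^2_F1 when test matches training in mean and
        # spread (the metric's reference point)
        g = np.random.default_rng(7)
        X_train = random_descriptors(500, 1, seed=2)
        y_train = g.standard_normal(500)  # independent of d1
        fit = fit_ols(X_train, y_train, ["d1"])
        X_test = random_descriptors(400, 1, seed=3)
        y_test = g.standard_normal(400)
        ext = external_validation(fit, X_test, y_test, y_train)
        assert ext.q2_f1 == pytest.approx(0.0, abs=0.05)

    def test_anticorrelated_predictions_distinguish_metrics(self):
        # r^2 is sign-blind; Q^2_F1 is not
        fit, X, y = self._fit()
        Xt = random_descriptors(10, 2, seed=5)
        y_obs = -fit.predict(Xt)  # exactly anti-correlated
        ext = external_validation(fit, Xt, y_obs, y)
        assert ext.r2_ext == pytest.approx(1.0, abs=1e-10)
        assert ext.q2_f1 < 0

    def test_empty_test_set_errors(self):
        fit, X, y = self._fit()
        empty = random_descriptors(0, 2, seed=6)
        with pytest.raises(ValueError, match="empty"):
            external_validation(fit, empty, np.array([]), y)


class TestYRandomization:
    def test_scrambling_destroys_planted_signal(self):
        X, y = planted_dataset(seed=8, noise_sd=0.0)
        subset = ["sum_q(O+N)", "q(CH+)_max", "E_LUMO", "Fukui(-)_max",
                  "Wiberg(C-C)_min"]
        original = fit_ols(X, y, subset).metrics.r_squared
        res = y_randomization(X, y, subset, n_perm=300, seed=0)
        assert original == pytest.approx(1.0, abs=1e-10)
        assert res.max_r2 < original
        assert res.mean_r2 < 0.5

    def test_identity_permutation_reproduces_original(self):
        X, y = planted_dataset(seed=9)
        subset = ["E_LUMO", "Fukui(-)_max"]
        original = fit_ols(X, y, subset).metrics.r_squared
        res = y_randomization(
            X, y, subset, permutations=[np.arange(len(y))]
        )
        assert res.r2[0] == pytest.approx(original, abs=1e-12)

    def test_null_data_yrand_matches_fresh_null_draws(self):
        # under exchangeability, scrambled-y R^2 and fresh-noise R^2 are
        # the same distribution; compare their means within MC error
        n, p, reps = 30, 5, 200
        X = random_descriptors(n, p, seed=0)
        g = np.random.default_rng(42)
        y = g.standard_normal(n)
        scr = y_randomization(X, y, X.descriptor_names, n_perm=reps, seed=1)
        fresh = []
        for _ in range(reps):
            yf = g.standard_normal(n)
            fresh.append(fit_ols(X, yf, X.descriptor_names).metrics.r_squared)
        se = np.sqrt(np.var(fresh, ddof=1) / reps + scr.r2.var(ddof=1) / reps)
        assert abs(scr.mean_r2 - np.mean(fresh)) < 4 * se

    def test_seeded_reproducibility(self):
        X, y = planted_dataset(seed=10)
        a = y_randomization(X, y, ["E_LUMO"], n_perm=20, seed=3)
        b = y_randomization(X, y, ["E_LUMO"], n_perm=20, seed=3)
        np.testing.assert_array_equal(a.r2, b.r2)


class TestVif:
    def test_orthogonal_columns_give_unit_vif(self):
        X = random_descriptors(4, 2, seed=0)
        X.df["d1"] = [1.0, 1.0, -1.0, -1.0]
        X.df["d2"] = [1.0, -1.0, 1.0, -1.0]
        out = vif(X, ["d1", "d2"])
        assert out["d1"] == pytest.approx(1.0, abs=1e-10)
        assert out["d2"] == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_column_flags_infinity(self):
        X = random_descriptors(10, 2, seed=1)
        X.df["d2"] = X.df["d1"]
        out = vif(X, ["d1", "d2"])
        assert np.isinf(out["d1"]) and np.isinf(out["d2"])

    def test_vif_at_least_one(self):
        X = random_descriptors(25, 5, seed=2)
        out = vif(X, X.descriptor_names)
        assert all(v >= 1.0 - 1e-12 for v in out.values())

    def test_matches_statsmodels(self):
        from statsmodels.stats.outliers_influence import (
            variance_inflation_factor,
        )

        X = random_descriptors(30, 4, seed=3)
        out = vif(X, X.descriptor_names)
        Xd = np.column_stack([np.ones(30), X.values])
        for j, name in enumerate(X.descriptor_names):
            ref = variance_inflation_factor(Xd, j + 1)
            assert out[name] == pytest.approx(ref, rel=1e-8)


class TestCoefficientTests:
    def test_true_signal_highly_significant(self):
        from conftest import PLANTED_BETA

        X, y = planted_dataset(seed=12, noise_sd=0.01)
        fit = fit_ols(X, y, list(PLANTED_BETA))
        tests = coefficient_tests(fit)
        assert all(sig < 1e-6 for _, sig in tests.values())

    def test_matches_statsmodels_t_and_p(self):
        import statsmodels.api as sm

        X = random_descriptors(25, 3, seed=5)
        y = np.random.default_rng(6).standard_normal(25)
        fit = fit_ols(X, y, X.descriptor_names)
        ref = sm.OLS(y, sm.add_constant(X.values)).fit()
        tests = coefficient_tests(fit)
        for j, name in enumerate(X.descriptor_names):
            t, sig = tests[name]
            assert t == pytest.approx(ref.tvalues[j + 1], rel=1e-8)
            assert sig == pytest.approx(ref.pvalues[j + 1], rel=1e-8)

    def test_noise_descriptor_p_values_uniform(self):
        # the p-value of a pure-noise descriptor is U(0,1) under the null
        sigs = []
        for seed in range(1000):
            X = random_descriptors(20, 2, seed=seed)
            g = np.random.default_rng(seed + 77)
            y = 2.0 * X.df["d1"].to_numpy() + g.standard_normal(20)
            fit = fit_ols(X, y, ["d1", "d2"])
            sigs.append(coefficient_tests(fit)["d2"][1])
        assert stats.kstest(sigs, "uniform").pvalue > 0.01


class TestAcceptanceCheck:
    def _metrics(self, r2):
        return FitMetrics(r2, r2 - 0.03, 1.0, 10.0, 1e-6, 1.0, 1.0, 1.0, 1.0)

    def _report(self, q2=0.722, q2_ext=0.699, vifs=None, sig=0.001):
        from freundlich_qsar.validation import ExternalValidation

        vifs = vifs or {
            "a": 3.675, "b": 4.138, "c": 1.531, "d": 1.248, "e": 1.173
        }
        return ValidationReport(
            q2_loo=q2,
            external=ExternalValidation(0.7, q2_ext, q2_ext, q2_ext),
            vif=vifs,
            coef_tests={k: (5.0, sig) for k in vifs},
        )

    def test_good_model_passes(self):
        verdict = acceptance_check(self._metrics(0.801), self._report())
        assert verdict.passed and not verdict.reasons

    def test_low_r2_fails_with_named_reason(self):
        verdict = acceptance_check(self._metrics(0.55), self._report())
        assert not verdict.passed
        assert any("R²" in r for r in verdict.reasons)

    def test_high_vif_fails(self):
        verdict = acceptance_check(
            self._metrics(0.8), self._report(vifs={"a": 7.0, "b": 1.2})
        )
        assert not verdict.passed
        assert any("VIF" in r for r in verdict.reasons)

    def test_insignificant_coefficient_fails(self):
        verdict = acceptance_check(self._metrics(0.8), self._report(sig=0.2))
        assert not verdict.passed
        assert any("sig" in r for r in verdict.reasons)
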