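import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from freundlich_qsar import (
    correlation_screen,
    fit_ols,
    stepwise_ladder,
)
from freundlich_qsar.model_build import apply_transform, friedman_lof

from conftest import PLANTED_BETA, planted_dataset, random_descriptors


def normal_equations_oracle(Xd, y):
    """Textbook OLS: beta = (X'X)^-1 X'y, independent of the fit path."""
    xtx = Xd.T @ Xd
    return np.linalg.solve(xtx, Xd.T @ y)


class TestCorrelationScreen:
    def test_self_correlation_is_one(self):
        X = random_descriptors(10, 3, seed=0)
        y = X.df["d2"].to_numpy()
        screen = correlation_screen(X, y)
        assert screen.r("d2") == pytest.approx(1.0)

    def test_anti_correlation_is_minus_one(self):
        X = random_descriptors(10, 3, seed=1)
        screen = correlation_screen(X, -X.df["d1"].to_numpy())
        assert screen.r("d1") == pytest.approx(-1.0)

    def test_constant_column_flagged_with_zero_r(self):
        X = random_descriptors(10, 3, seed=2)
        X.df["d3"] = 5.0
        screen = correlation_screen(X, X.df["d1"].to_numpy())
        assert screen.r("d3") == 0.0
        row = screen.table[screen.table["descriptor"] == "d3"]
        assert bool(row["constant"].iloc[0])

    def test_ranked_by_absolute_r(self):
        X = random_descriptors(30, 5, seed=3)
        y = X.df["d4"].to_numpy() + 0.1 * X.df["d1"].to_numpy()
        screen = correlation_screen(X, y)
        rs = screen.table["r"].abs().to_numpy()
        assert (np.diff(rs) <= 1e-12).all()
        assert screen.table["descriptor"].iloc[0] == "d4"

    def test_length_mismatch_errors(self):
        X = random_descriptors(10, 2, seed=4)
        with pytest.raises(ValueError, match="response length"):
            correlation_screen(X, np.zeros(9))


class TestFitOls:
    def test_hand_computed_simple_regression(self):
        # y=(1,2,2,3) on x=(1,2,3,4): slope 0.6, intercept 0.5, R^2=0.9
        X = random_descriptors(4, 1, seed=0)
        X.df["d1"] = [1.0, 2.0, 3.0, 4.0]
        fit = fit_ols(X, np.array([1.0, 2.0, 2.0, 3.0]), ["d1"])
        assert fit.coefficients["d1"] == pytest.approx(0.6)
        assert fit.intercept == pytest.approx(0.5)
        assert fit.metrics.r_squared == pytest.approx(0.9)

    def test_exact_linear_data_interpolates(self):
        X = random_descriptors(12, 3, seed=1)
        y = 2.0 + X.df["d1"].to_numpy() - 3.0 * X.df["d3"].to_numpy()
        fit = fit_ols(X, y, ["d1", "d3"])
        assert fit.metrics.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.metrics.rss_tr == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-9)

    def test_constant_response_convention(self):
        X = random_descriptors(10, 2, seed=2)
        fit = fit_ols(X, np.full(10, 3.0), ["d1"])
        assert fit.metrics.r_squared == 0.0
        assert fit.metrics.f_stat == 0.0

    def test_matches_normal_equations_oracle(self):
        for seed in range(20):
            X = random_descriptors(20, 6, seed=seed)
            g = np.random.default_rng(seed + 1000)
            y = g.standard_normal(20)
            fit = fit_ols(X, y, X.descriptor_names)
            Xd = np.column_stack([np.ones(20), X.values])
            beta = normal_equations_oracle(Xd, y)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-9)
            for j, name in enumerate(X.descriptor_names):
                assert fit.coefficients[name] == pytest.approx(
                    beta[j + 1], abs=1e-9
                )

    def test_residuals_sum_to_zero(self):
        X = random_descriptors(25, 4, seed=3)
        y = np.random.default_rng(9).standard_normal(25)
        fit = fit_ols(X, y, ["d1", "d2", "d4"])
        assert abs(fit.residuals.sum()) < 1e-9

    def test_metric_identities(self):
        X = random_descriptors(30, 3, seed=4)
        y = np.random.default_rng(5).standard_normal(30)
        m = fit_ols(X, y, X.descriptor_names).metrics
        assert m.rmse_tr == pytest.approx(np.sqrt(m.rss_tr / 30))
        assert m.r_squared_adj <= m.r_squared
        assert 0 <= m.r_squared <= 1
        # F consistent with R^2: F = (R2/p)/((1-R2)/(n-p-1))
        n, p = 30, 3
        f_from_r2 = (m.r_squared / p) / ((1 - m.r_squared) / (n - p - 1))
        assert m.f_stat == pytest.approx(f_from_r2, rel=1e-9)

    def test_singular_design_names_collinear_columns(self):
        X = random_descriptors(15, 3, seed=5)
        X.df["d3"] = 2.0 * X.df["d1"]
        y = np.random.default_rng(1).standard_normal(15)
        with pytest.raises(np.linalg.LinAlgError, match="d1|d3"):
            fit_ols(X, y, ["d1", "d2", "d3"])

    def test_transforms(self):
        y = np.array([1.0, 100.0, 10000.0])
        np.testing.assert_allclose(apply_transform(y, "log10"), [0, 2, 4])
        np.testing.assert_allclose(apply_transform(y, "sqrt"), [1, 10, 100])
        with pytest.raises(ValueError):
            apply_transform(np.array([-1.0]), "log10")
        with pytest.raises(ValueError):
            apply_transform(y, "cubert")

    def test_lof_closed_form(self):
        # LOF = (RSS/n) / (1 - (c + d p)/n)^2 with c = p+1
        assert friedman_lof(10.0, 20, 3, d=0.5) == pytest.approx(
            (10.0 / 20) / (1 - (4 + 1.5) / 20) ** 2
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_r2_adj_never_exceeds_r2(self, seed):
        X = random_descriptors(18, 4, seed=seed)
        y = np.random.default_rng(seed).standard_normal(18)
        m = fit_ols(X, y, X.descriptor_names).metrics
        assert m.r_squared_adj <= m.r_squared + 1e-12


class TestStepwiseLadder:
    def test_dominant_predictor_found_first(self):
        X = random_descriptors(20, 5, seed=0)
        y = 3.0 * X.df["d3"].to_numpy() + 1.0
        ladder = stepwise_ladder(X, y, max_size=2)
        assert ladder[0].descriptor_names == ("d3",)
        assert ladder[0].metrics.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_nested_metrics_monotone(self, planted):
        X, y = planted
        ladder = stepwise_ladder(X, y, max_size=7)
        r2 = [m.metrics.r_squared for m in ladder]
        rss = [m.metrics.rss_tr for m in ladder]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(rss, rss[1:]))

    def test_noiseless_support_recovered_exactly(self):
        X, y = planted_dataset(seed=21, noise_sd=0.0)
        ladder = stepwise_ladder(X, y, max_size=5)
        assert set(ladder[-1].descriptor_names) == set(PLANTED_BETA)
        assert ladder[-1].metrics.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_low_noise_support_recovery_rate(self):
        # planted 5-descriptor signal, n=38, p=31: rung 5 should find the
        # exact support in at least 95 of 100 seeds
        hits = 0
        for seed in range(100):
            X, y = planted_dataset(seed=seed, noise_sd=0.02)
            ladder = stepwise_ladder(X, y, max_size=5)
            hits += set(ladder[-1].descriptor_names) == set(PLANTED_BETA)
        assert hits >= 95

    def test_q2loo_criterion_also_recovers(self):
        X, y = planted_dataset(seed=3, noise_sd=0.02)
        ladder = stepwise_ladder(X, y, max_size=5, criterion="q2loo")
        assert set(ladder[-1].descriptor_names) == set(PLANTED_BETA)

    def test_max_size_bounds_checked(self):
        X = random_descriptors(10, 4, seed=1)
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="exceeds"):
            stepwise_ladder(X, y, max_size=5)
        with pytest.raises(ValueError, match="n_train"):
            stepwise_ladder(random_descriptors(5, 8, seed=2), np.arange(5.0),
                            max_size=6)

    def test_tie_break_is_lexicographic(self):
        # duplicate columns tie exactly; the lexicographically first wins
        X = random_descriptors(12, 3, seed=4)
        X.df["d2"] = X.df["d1"]
        y = X.df["d1"].to_numpy() * 2.0
        ladder = stepwise_ladder(X, y, max_size=1)
        assert ladder[0].descriptor_names == ("d1",)
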