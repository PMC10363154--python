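import itertools

import numpy as np
import pytest
from scipy import stats

import haystack as hs
from haystack.significance import log10_pvals_adjust
from haystack.types import HaystackError


def _activity(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return hs.ActivityMatrix(
        values,
        [f"f{i}" for i in range(values.shape[0])],
        [f"s{i}" for i in range(values.shape[1])],
    )


class TestCV:
    def test_constant_feature_has_zero_cv(self):
        assert hs.compute_cv(_activity([2.0, 2.0, 2.0, 2.0]))[0] == 0.0

    def test_half_zero_half_two(self):
        # mean 1, sample sd sqrt(4/3)
        cv = hs.compute_cv(_activity([0.0, 0.0, 2.0, 2.0]))[0]
        assert cv == pytest.approx(2 * np.sqrt(1 / 3), abs=1e-12)

    def test_scale_invariance(self, rng):
        y = rng.exponential(size=40)
        assert hs.compute_cv(_activity(y))[0] == pytest.approx(
            hs.compute_cv(_activity(7 * y))[0], rel=1e-12
        )

    def test_all_zero_feature_is_nan(self):
        assert np.isnan(hs.compute_cv(_activity([0.0, 0.0, 0.0]))[0])

    def test_sparse_matches_dense(self, rng):
        from scipy import sparse

        values = rng.poisson(0.7, size=(20, 50)).astype(float)
        dense = hs.compute_cv(_activity(values))
        sp = hs.compute_cv(
            hs.ActivityMatrix(
                sparse.csr_matrix(values),
                [f"f{i}" for i in range(20)],
                [f"s{i}" for i in range(50)],
            )
        )
        np.testing.assert_allclose(dense, sp, atol=1e-12, equal_nan=True)


class TestReferenceSelection:
    def test_all_features_selected_when_f_equals_m(self):
        cv = np.array([0.5, 1.0, 2.0, 4.0])
        np.testing.assert_array_equal(
            hs.select_reference_features(cv, m=4), np.arange(4)
        )

    def test_linear_spacing_targets_on_integer_grid(self):
        cv = np.arange(1.0, 101.0)
        idx = hs.select_reference_features(cv, m=10, scale="linear")
        np.testing.assert_array_equal(
            cv[idx], [1, 12, 23, 34, 45, 56, 67, 78, 89, 100]
        )

    def test_extremes_always_included(self, rng):
        cv = rng.lognormal(0, 1, size=500)
        idx = hs.select_reference_features(cv, m=50)
        assert np.argmin(cv) in idx and np.argmax(cv) in idx
        assert len(idx) == 50

    def test_deterministic(self, rng):
        cv = rng.lognormal(0, 1, size=300)
        np.testing.assert_array_equal(
            hs.select_reference_features(cv, m=30),
            hs.select_reference_features(cv, m=30),
        )

    def test_fewer_eligible_than_requested_uses_all(self):
        cv = np.array([0.5, np.nan, 0.0, 2.0])
        idx = hs.select_reference_features(cv, m=10)
        np.testing.assert_array_equal(idx, [0, 3])


class TestRandomizeDKL:
    def test_constant_activity_always_zero(self, small_grid):
        _, grid = small_grid
        reps = hs.randomize_DKL(grid.density, np.full(400, 2.0), n_perm=5, rng=0)
        np.testing.assert_allclose(reps, 0.0, atol=1e-12)

    def test_replicates_nonnegative(self, small_grid, rng):
        _, grid = small_grid
        y = rng.poisson(1.0, 400).astype(float)
        reps = hs.randomize_DKL(grid.density, y, n_perm=20, rng=rng)
        assert np.all(reps >= -1e-12)

    def test_replicates_within_enumerated_permutation_set(self):
        """n=4: brute-force all 24 permutations; samples must fall in that set."""
        coords = np.array([[0.0], [1.0], [2.0], [3.0]])
        grid_pts = np.array([[0.5], [2.5]])
        h = hs.compute_bandwidth(coords, grid_pts)
        density = hs.compute_density(coords, grid_pts, h)
        q = hs.compute_Q(density)
        y = np.array([0.0, 1.0, 2.0, 5.0])
        universe = {
            round(hs.compute_DKL(hs.compute_Pf(density, np.array(p)), q), 12)
            for p in itertools.permutations(y)
        }
        reps = hs.randomize_DKL(density, y, n_perm=50, rng=7)
        assert all(round(r, 12) in universe for r in reps)

    def test_reproducible_given_seed(self, small_grid, rng):
        _, grid = small_grid
        y = rng.poisson(2.0, 400).astype(float)
        r1 = hs.randomize_DKL(grid.density, y, n_perm=10, rng=3)
        r2 = hs.randomize_DKL(grid.density, y, n_perm=10, rng=3)
        np.testing.assert_array_equal(r1, r2)

    def test_single_permutation_rejected(self, small_grid):
        _, grid = small_grid
        with pytest.raises(HaystackError):
            hs.randomize_DKL(grid.density, np.ones(400), n_perm=1, rng=0)


def _simulated_null_inputs(a, b, sd, m=100, n_perm=200, seed=0):
    rng = np.random.default_rng(seed)
    logcv = np.linspace(-2.0, 1.0, m)
    reps = np.exp(rng.normal(a + b * logcv[:, None], sd, size=(m, n_perm)))
    return logcv, reps


class TestFitNullModel:
    def test_recovers_linear_mean_and_constant_sd(self):
        a, b, sd = -3.0, 1.5, 0.3
        logcv, reps = _simulated_null_inputs(a, b, sd)
        model = hs.fit_null_model(logcv, reps, seed=0)
        grid = np.linspace(-2, 1, 40)
        slope, intercept = np.polyfit(grid, model.mean_curve(grid), 1)
        assert slope == pytest.approx(b, rel=0.05)
        assert intercept == pytest.approx(a, rel=0.05)
        np.testing.assert_allclose(model.sd_curve(grid), sd, rtol=0.10)

    def test_identical_statistics_give_constant_df1_curve(self):
        rng = np.random.default_rng(1)
        logcv = np.linspace(-1, 1, 60)
        one_row = np.exp(rng.normal(-2.0, 0.2, size=150))
        reps = np.tile(one_row, (60, 1))  # every feature: identical statistics
        model = hs.fit_null_model(logcv, reps, seed=1)
        assert model.df_mean == 1
        pred = model.mean_curve(np.linspace(-1, 1, 5))
        assert np.ptp(pred) < 1e-8

    def test_pure_noise_statistics_give_nearly_flat_curve(self):
        rng = np.random.default_rng(1)
        logcv = np.linspace(-1, 1, 60)
        reps = np.exp(rng.normal(-2.0, 0.2, size=(60, 150)))
        model = hs.fit_null_model(logcv, reps, seed=1)
        pred = model.mean_curve(np.linspace(-1, 1, 9))
        assert np.ptp(pred) < 0.15

    def test_refit_same_seed_identical(self):
        logcv, reps = _simulated_null_inputs(-2, 1, 0.4, seed=5)
        m1 = hs.fit_null_model(logcv, reps, seed=9)
        m2 = hs.fit_null_model(logcv, reps, seed=9)
        assert (m1.df_mean, m1.df_sd) == (m2.df_mean, m2.df_sd)
        x = np.linspace(-2, 1, 7)
        np.testing.assert_array_equal(m1.mean_curve(x), m2.mean_curve(x))

    def test_all_degenerate_replicates_rejected(self):
        with pytest.raises(HaystackError):
            hs.fit_null_model(np.linspace(0, 1, 20), np.zeros((20, 50)))


@pytest.fixture(scope="module")
def model():
    logcv, reps = _simulated_null_inputs(-3.0, 1.5, 0.3, seed=2)
    return hs.fit_null_model(logcv, reps, seed=2)


class TestPredictPvalues:
    def test_dkl_at_predicted_mean_gives_p_half(self, model):
        cv = np.array([np.exp(-0.5)])
        mu = model.mean_curve(np.array([-0.5]))[0]
        res = hs.predict_pvalues(model, cv, np.array([np.exp(mu)]))
        assert res.table["log10_pval"].iloc[0] == pytest.approx(
            np.log10(0.5), abs=1e-6
        )

    def test_extreme_z_stays_finite_in_log_space(self, model):
        cv = np.array([np.exp(-0.5)])
        mu = model.mean_curve(np.array([-0.5]))[0]
        sd = model.sd_curve(np.array([-0.5]))[0]
        dkl = np.exp(mu + 40 * sd)
        res = hs.predict_pvalues(model, cv, np.array([dkl]))
        lp = res.table["log10_pval"].iloc[0]
        assert np.isfinite(lp) and lp < -300
        # asymptotic tail: log10 sf(z) ~ -(z^2/2 + ln z + ln sqrt(2pi))/ln 10
        expected = stats.norm.logsf(40.0) / np.log(10)
        assert lp == pytest.approx(expected, rel=1e-6)

    def test_zero_divergence_flagged_with_p_one(self, model):
        res = hs.predict_pvalues(
            model, np.array([0.0, 1.0]), np.array([0.0, 0.05])
        )
        assert res.table["flag"].tolist() == ["zero_cv", "ok"]
        assert res.table["log10_pval"].iloc[0] == 0.0
        assert res.table["rank"].iloc[1] == 1

    def test_nan_inputs_flagged_all_zero(self, model):
        res = hs.predict_pvalues(model, np.array([np.nan, 1.0]), np.array([0.1, 0.1]))
        assert res.table["flag"].iloc[0] == "all_zero"
        assert np.isnan(res.table["rank"].iloc[0])

    def test_monotone_in_dkl_at_fixed_cv(self, model):
        cv = np.full(50, 1.0)
        dkl = np.linspace(0.01, 2.0, 50)
        res = hs.predict_pvalues(model, cv, dkl)
        lp = res.table["log10_pval"].to_numpy()
        assert np.all(np.diff(lp) <= 1e-12)

    def test_out_of_span_cv_clamped(self, model, caplog):
        lo, hi = model.logcv_span
        res = hs.predict_pvalues(
            model,
            np.array([np.exp(lo - 5), np.exp(hi + 5)]),
            np.array([0.01, 0.01]),
        )
        assert np.all(np.isfinite(res.table["log10_pval"]))

    def test_adjusted_never_more_significant(self, model, rng):
        cv = rng.lognormal(0, 0.5, 200)
        dkl = rng.exponential(0.05, 200)
        res = hs.predict_pvalues(model, cv, dkl)
        t = res.table
        assert np.all(t["log10_pval_adj"] >= t["log10_pval"] - 1e-12)
        ok = t[t["flag"] == "ok"]
        assert sorted(ok["rank"]) == list(range(1, len(ok) + 1))


class TestBHAdjustment:
    def test_matches_statsmodels_on_linear_scale(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=37)
        adj = 10 ** log10_pvals_adjust(np.log10(p))
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, expected, rtol=1e-10)
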