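import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import seagrassrs as sg
from seagrassrs.trends import AnnualSeries


def series(values, years=None, seasons=None):
    values = np.asarray(values, dtype=float)
    if years is None:
        years = np.arange(len(values))
    return AnnualSeries(years, values, seasons)


# --------------------------------------------------------------------------
# Mann-Kendall
# --------------------------------------------------------------------------


class TestMannKendall:
    def test_strictly_increasing_tau_one(self):
        mk = sg.mann_kendall(series(np.arange(10.0)))
        assert mk.tau == 1.0
        assert mk.p_value < 0.001

    def test_constant_series_no_trend(self):
        mk = sg.mann_kendall(series(np.full(8, 3.0)))
        assert mk.tau == 0.0
        assert mk.p_value == 1.0

    def test_small_n_exact_vs_brute_force_permutation_oracle(self):
        vals = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 2.0])

        # independent oracle: S by double loop, exact p by full enumeration
        def s_stat(v):
            return sum(np.sign(v[j] - v[i])
                       for i in range(len(v)) for j in range(i + 1, len(v)))

        s_obs = s_stat(vals)
        hits = total = 0
        for perm in itertools.permutations(vals):
            total += 1
            if abs(s_stat(np.array(perm))) >= abs(s_obs):
                hits += 1

        mk = sg.mann_kendall(series(vals), method="exact")
        assert mk.s == s_obs
        assert mk.tau == pytest.approx(s_obs / 15, abs=1e-12)
        assert mk.p_value == pytest.approx(hits / total, abs=1e-9)

    def test_tau_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=15)
        mk = sg.mann_kendall(series(vals))
        tau_ref, _ = stats.kendalltau(np.arange(15), vals)
        assert mk.tau == pytest.approx(tau_ref, abs=1e-12)

    def test_seasonal_blocks_combine(self):
        years = np.repeat(np.arange(2000, 2008), 2)
        seasons = np.tile(["autumn", "summer"], 8)
        vals = years + np.where(seasons == "summer", 0.5, 0.0)
        mk = sg.mann_kendall(AnnualSeries(years, vals, seasons))
        assert mk.tau == 1.0  # monotone inside each season block

    def test_tie_corrected_variance(self):
        vals = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        mk = sg.mann_kendall(series(vals))
        n = 5
        expected_var = n * (n - 1) * (2 * n + 5) / 18 - 2 * 1 * 9 / 18
        assert mk.var_s == pytest.approx(expected_var)


def test_mann_kendall_type_i_error_near_nominal():
    """Empirical false-positive rate at alpha = 0.05 on trendless white-noise
    series of the study's length (n = 31)."""
    rng = np.random.default_rng(1234)
    years = np.arange(1990, 2021)
    rejections = sum(
        sg.mann_kendall(series(rng.normal(size=31), years=years)).p_value < 0.05
        for _ in range(2000))
    assert 0.035 <= rejections / 2000 <= 0.065


# --------------------------------------------------------------------------
# Theil-Sen and change rates
# --------------------------------------------------------------------------


class TestTheilSen:
    def test_exact_line(self):
        years = np.arange(2000, 2010)
        assert sg.theil_sen(series(2.0 * years + 1.0, years=years)) == 2.0

    def test_constant_series_zero(self):
        assert sg.theil_sen(series(np.full(6, 4.0))) == 0.0

    def test_small_n_enumeration_oracle(self):
        years = np.array([0.0, 1.0, 2.0, 3.0])
        vals = np.array([5.0, 1.0, 4.0, 2.0])
        slopes = [(vals[j] - vals[i]) / (years[j] - years[i])
                  for i, j in itertools.combinations(range(4), 2)]
        assert sg.theil_sen(series(vals, years=years)) == np.median(slopes)

    def test_matches_scipy_theilslopes(self):
        rng = np.random.default_rng(2)
        years = np.arange(20.0)
        vals = 0.5 * years + rng.normal(size=20)
        ours = sg.theil_sen(series(vals, years=years))
        ref = stats.theilslopes(vals, years).slope
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_robust_to_contamination(self):
        rng = np.random.default_rng(3)
        years = np.arange(30.0)
        vals = 1.5 * years + rng.normal(0, 0.3, 30)
        outliers = rng.choice(30, size=6, replace=False)  # 20% corrupted
        vals[outliers] += rng.normal(0, 30, 6)
        slope = sg.theil_sen(series(vals, years=years))
        assert abs(slope - 1.5) / 1.5 < 0.10

    def test_duplicate_year_pairs_skipped(self):
        s = AnnualSeries(np.array([0, 0, 1, 2]), np.array([0.0, 9.0, 1.0, 2.0]))
        assert np.isfinite(sg.theil_sen(s))


class TestPercentChange:
    def test_zero_slope(self):
        assert sg.percent_change(0.0, series([1.0, 2.0, 3.0])) == 0.0

    def test_scalar_division(self):
        s = series(np.full(4, 23.0))
        assert sg.percent_change(0.23, s) == pytest.approx(1.0)

    def test_sign_follows_slope(self):
        s = series([10.0, 11.0, 12.0])
        assert sg.percent_change(-0.5, s) < 0 < sg.percent_change(0.5, s)

    def test_zero_mean_undefined(self):
        assert math.isnan(sg.percent_change(1.0, series([-1.0, 1.0])))


class TestPercentDecline:
    @pytest.mark.parametrize("before, after, expected", [
        (27.0, 26.0, 4), (26.0, 16.0, 38), (22.0, 18.0, 18)])
    def test_storm_decline_arithmetic(self, before, after, expected):
        assert round(sg.percent_decline(before, after)) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            sg.percent_decline(0.0, 1.0)


class TestGamma:
    def test_zero_slope_undefined(self):
        s = series([1.0, 3.0, 2.0, 4.0, 1.0])
        assert math.isnan(sg.gamma_years(s, 0.0))

    def test_scalar_evaluation(self):
        # sigma_N = 1, phi = 0, slope = 0.1 -> 33^(2/3) = 10.29 years
        from seagrassrs.trends import gamma_from_parameters
        assert gamma_from_parameters(1.0, 0.0, 0.1) == pytest.approx(
            33.0 ** (2.0 / 3.0), abs=1e-12)
        assert gamma_from_parameters(1.0, 0.0, 0.1) == pytest.approx(10.29,
                                                                     abs=0.01)

    def test_estimator_recovers_closed_form_on_trended_noise(self):
        rng = np.random.default_rng(8)
        years = np.arange(200.0)
        vals = 0.1 * years + rng.normal(0, 1.0, 200)
        est = sg.gamma_years(series(vals, years=years), 0.1)
        assert est == pytest.approx(33.0 ** (2.0 / 3.0), rel=0.15)

    def test_monotone_decreasing_in_slope_magnitude(self):
        from seagrassrs.trends import gamma_from_parameters
        gammas = [gamma_from_parameters(1.0, 0.2, sl)
                  for sl in (0.05, 0.1, 0.2, 0.5, 1.0)]
        assert all(a > b for a, b in zip(gammas, gammas[1:]))

    def test_detectability_consistency(self):
        """The annual-sampling detectability horizon (noise-to-trend factor
        (z_0.975 + z_0.90) * sqrt(12)) marks 90%-power design territory:
        Mann-Kendall power sits near 0.9 at that record length and clears it
        comfortably a third beyond it."""
        sigma, slope = 1.0, 0.25
        factor = (1.96 + 1.28) * math.sqrt(12.0)
        from seagrassrs.trends import gamma_from_parameters
        n_star = gamma_from_parameters(sigma, 0.0, slope, factor=factor)

        def power(n, reps=400, seed=10):
            rng = np.random.default_rng(seed)
            years = np.arange(float(n))
            hits = sum(
                sg.mann_kendall(series(slope * years
                                       + rng.normal(0, sigma, n),
                                       years=years)).p_value < 0.05
                for _ in range(reps))
            return hits / reps

        assert power(math.ceil(n_star)) >= 0.8  # at the design boundary
        assert power(math.ceil(1.33 * n_star)) >= 0.9


@given(tau=st.floats(min_value=-1.0, max_value=1.0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_strength_label_thresholds(tau):
    label = sg.strength_label(tau)
    a = abs(tau)
    expected = ("strong" if a >= 0.5 else "moderate" if a >= 0.3
                else "weak" if a >= 0.1 else "none")
    assert label == expected


def test_strength_label_paper_style_cases():
    assert sg.strength_label(0.09) == "none"
    assert sg.strength_label(-0.5) == "strong"
    assert sg.strength_label(0.3) == "moderate"


def test_trend_summary_is_internally_consistent():
    rng = np.random.default_rng(11)
    years = np.arange(1990, 2021)
    vals = 23 + rng.normal(0, 2.5, 31)
    res = sg.trend_summary(series(vals, years=years))
    assert res.n == 31
    assert -1 <= res.tau <= 1 and 0 <= res.p_value <= 1
    assert res.strength_label == sg.strength_label(res.tau)
    # percent change carries the slope's sign and scale
    assert res.percent_change_per_year == pytest.approx(
        100 * res.sen_slope / vals.mean())
    assert res.gamma_years > 0 or math.isnan(res.gamma_years)


# --------------------------------------------------------------------------
# frequency map
# --------------------------------------------------------------------------


class TestFrequencyMap:
    def _maps(self, labels_list, masks=None):
        masks = masks or [None] * len(labels_list)
        return [sg.ClassMap(np.asarray(l), m) for l, m in zip(labels_list, masks)]

    def test_always_and_never_present(self):
        always = np.full((2, 2), sg.SEAGRASS)
        never = np.full((2, 2), sg.SAND)
        grid = sg.frequency_map(self._maps([always, always, always]))
        assert np.all(grid.frequency == 1.0)
        grid = sg.frequency_map(self._maps([never, never]))
        assert np.all(grid.frequency == 0.0)

    def test_thirteen_of_thirty_one(self):
        maps = self._maps([np.full((1, 1), sg.SEAGRASS)] * 13
                          + [np.full((1, 1), sg.SAND)] * 18)
        grid = sg.frequency_map(maps)
        assert grid.frequency[0, 0] == pytest.approx(13 / 31)
        assert grid.n_scenes == 31

    def test_masked_scenes_excluded_from_both_sides(self):
        labels = np.full((1, 1), sg.SEAGRASS)
        masked = sg.ClassMap(labels.copy(), np.ones((1, 1), dtype=bool))
        grid = sg.frequency_map([sg.ClassMap(labels),
                                 sg.ClassMap(np.full((1, 1), sg.SAND)), masked])
        assert grid.frequency[0, 0] == pytest.approx(0.5)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(12)
        maps = [sg.ClassMap(rng.integers(0, 5, size=(6, 6)).astype(np.int16))
                for _ in range(7)]
        a = sg.frequency_map(maps).frequency
        b = sg.frequency_map(maps[::-1]).frequency
        assert np.array_equal(a, b, equal_nan=True)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            sg.frequency_map([])


# --------------------------------------------------------------------------
# climate-driver regression
# --------------------------------------------------------------------------


class TestMLR:
    def _covariates(self, n=31, seed=0):
        return sg.make_covariates(range(1990, 1990 + n), seed=seed)

    def test_exact_fit_recovers_beta(self):
        cov = self._covariates()
        y = 2.0 * cov["enso"].to_numpy()
        res = sg.mlr_drivers(series(y, years=cov["year"].to_numpy()), cov)
        assert res.beta["enso"] == pytest.approx(2.0, abs=1e-9)
        assert res.beta["nao"] == pytest.approx(0.0, abs=1e-9)
        assert res.adjusted_r2 == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        cov = self._covariates(seed=5)
        rng = np.random.default_rng(5)
        y = 23 + 0.9 * cov["enso"].to_numpy() + rng.normal(0, 2, 31)
        res = sg.mlr_drivers(series(y, years=cov["year"].to_numpy()), cov)
        x = np.column_stack([np.ones(31), cov["enso"], cov["nao"]])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.beta["enso"] == pytest.approx(beta[1], abs=1e-10)
        assert res.beta["nao"] == pytest.approx(beta[2], abs=1e-10)

    def test_null_p_values_uniform(self):
        """With an outcome independent of the climate indices, coefficient
        p-values over replicates are uniform (KS, alpha = 0.01)."""
        rng = np.random.default_rng(6)
        cov = self._covariates(seed=6)
        years = cov["year"].to_numpy()
        pvals = np.array([
            sg.mlr_drivers(series(rng.normal(size=31), years=years), cov)
            .p["enso"] for _ in range(1000)])
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_collinear_predictors_named(self):
        cov = self._covariates()
        cov["nao"] = 2.0 * cov["enso"]
        with pytest.raises(ValueError, match="collinear"):
            sg.mlr_drivers(series(np.zeros(31), years=cov["year"].to_numpy()),
                           cov)

    def test_too_short_series_rejected(self):
        cov = self._covariates(n=3)
        with pytest.raises(ValueError):
            sg.mlr_drivers(series(np.zeros(3), years=cov["year"].to_numpy()),
                           cov)
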