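"""ML generalized least squares, AR(1) errors, and the likelihood-ratio pseudo-R^2."""

import math

import numpy as np
import pandas as pd
import pytest

from lodiag.fossil_data import ValidationError
from lodiag.regression import (
    ComparisonSpec,
    fit_gls,
    pseudo_r2,
    run_comparisons,
)


def ols_closed_form(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = (resid**2).sum() / (n - 2)
    se = math.sqrt(s2 / sxx)
    t = slope / se
    from scipy import stats

    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, intercept, t, p


class TestOLSEquivalence:
    def test_textbook_example_slope(self):
        r = fit_gls([1, 2, 3], [1, 2, 4])
        assert r.slope == pytest.approx(1.5, abs=1e-12)

    def test_matches_closed_form_on_fixed_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(0, 2, 25)
            y = 1.0 + 0.7 * x + rng.normal(0, 1, 25)
            r = fit_gls(x, y)
            slope, intercept, t, p = ols_closed_form(x, y)
            assert r.slope == pytest.approx(slope, abs=1e-8)
            assert r.intercept == pytest.approx(intercept, abs=1e-8)
            assert r.t_value == pytest.approx(t, abs=1e-8)
            assert r.p_value == pytest.approx(p, abs=1e-8)

    def test_matches_statsmodels_loglik(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 40)
        y = 2 - 0.3 * x + rng.normal(0, 0.5, 40)
        r = fit_gls(x, y)
        m = sm.OLS(y, sm.add_constant(x)).fit()
        assert r.loglik_model == pytest.approx(m.llf, abs=1e-8)
        assert r.t_value == pytest.approx(m.tvalues[1], abs=1e-8)

    def test_constant_response_gives_flat_fit(self):
        r = fit_gls([1, 2, 3, 4], [5, 5, 5, 5])
        assert r.slope == 0.0 and r.t_value == 0.0

    def test_zero_variance_predictor_is_an_error(self):
        with pytest.raises(ValidationError, match="zero variance"):
            fit_gls([2, 2, 2], [1, 2, 3])

    def test_too_few_points_is_an_error(self):
        with pytest.raises(ValidationError, match=">= 3"):
            fit_gls([1, 2], [1, 2])


def simulate_ar1(rng, n, rho, sigma=1.0):
    e = np.empty(n)
    u = rng.normal(0, sigma * math.sqrt(1 - rho**2), n)
    e[0] = rng.normal(0, sigma)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + u[t]
    return e


class TestAR1:
    def test_rho_recovery_within_sampling_error(self):
        rng = np.random.default_rng(2021)
        x = rng.normal(0, 1, 200)
        y = 1.0 + 0.5 * x + simulate_ar1(rng, 200, rho=0.6)
        r = fit_gls(x, y, correlation="ar1")
        assert abs(r.rho - 0.6) < 0.15

    def test_rho_zero_reduces_to_iid_loglik(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 60)
        y = 2 + x + rng.normal(0, 1, 60)
        iid = fit_gls(x, y, correlation="none")
        from lodiag.regression import _fit_given_rho

        X = np.column_stack([np.ones(60), x])
        *_, ll_rho0 = _fit_given_rho(X, y, 0.0)
        assert abs(iid.loglik_model - ll_rho0) < 1e-6

    def test_ar1_loglik_never_below_iid(self):
        # iid is nested in AR(1) (rho = 0), so ML over rho can only improve
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 50)
        y = 1 + 0.2 * x + simulate_ar1(rng, 50, rho=0.5)
        iid = fit_gls(x, y, correlation="none")
        ar1 = fit_gls(x, y, correlation="ar1")
        assert ar1.loglik_model >= iid.loglik_model - 1e-8


class TestPseudoR2:
    def test_equal_logliks_give_zero(self):
        assert pseudo_r2(-10.0, -10.0, 12) == 0.0

    def test_direct_evaluation(self):
        assert pseudo_r2(-5.0, -10.0, 10) == pytest.approx(1 - math.exp(-1.0))

    def test_strictly_increasing_in_delta_and_below_one(self):
        values = [pseudo_r2(-10.0 + d, -10.0, 20) for d in (0.1, 1.0, 5.0, 50.0, 150.0)]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert values[-1] < 1.0

    def test_negative_delta_warns(self):
        with pytest.warns(UserWarning, match="below the nested null"):
            v = pseudo_r2(-11.0, -10.0, 10)
        assert v < 0

    def test_adjusted_variant_rescales(self):
        ll_null = -8.0
        raw = pseudo_r2(-5.0, ll_null, 10)
        adj = pseudo_r2(-5.0, ll_null, 10, adjusted=True)
        assert adj == pytest.approx(raw / (1 - math.exp(2 / 10 * ll_null)))


class TestLogTransform:
    def test_nonpositive_pairs_dropped_with_warning(self):
        x = [0.0, 1.0, 10.0, 100.0, 1000.0]
        y = [5.0, 1.0, 10.0, 100.0, 1000.0]
        with pytest.warns(UserWarning, match="dropped 1"):
            r = fit_gls(x, y, log_transform=True)
        assert r.n == 4 and r.n_dropped == 1
        assert r.slope == pytest.approx(1.0, abs=1e-12)

    def test_x_only_mode_logs_predictor_side(self):
        x = [1.0, 10.0, 100.0]
        y = [0.0, 1.0, 2.0]
        r = fit_gls(x, y, log_transform="x")
        assert r.slope == pytest.approx(1.0, abs=1e-12)


class TestRunComparisons:
    def test_missing_column_fails_alone_others_proceed(self):
        table = pd.DataFrame({"lod": [1.0, 2.0, 4.0, 8.0], "mni": [1, 2, 3, 4]})
        specs = [
            ComparisonSpec("ok", "species", "lod", "mni"),
            ComparisonSpec("bad", "species", "lod", "missing_col"),
        ]
        results, errors = run_comparisons({"species": table}, specs)
        assert [r.comparison_id for r in results] == ["ok"]
        assert "missing_col" in errors["bad"]

    def test_type_i_error_calibration_small(self):
        """Under a true null the OLS p-value is approximately uniform."""
        rng = np.random.default_rng(10)
        rejections = sum(
            fit_gls(rng.normal(0, 1, 40), rng.normal(0, 1, 40)).p_value < 0.05
            for _ in range(200)
        )
        assert 0.01 <= rejections / 200 <= 0.10
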