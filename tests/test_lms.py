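import numpy as np
import pandas as pd
import pytest

from reachdev.lms import (
    DEFAULT_LEVELS,
    LMSModel,
    bccg_rvs,
    fit_lms,
    percentile_curve,
    select_family,
)

AGE_RANGE = (36.0, 216.0)


def uniform_ages(rng, n):
    return rng.uniform(*AGE_RANGE, n)


class TestNormalFamily:
    def test_flat_fit_recovers_moments(self):
        rng = np.random.default_rng(21)
        age = uniform_ages(rng, 2000)
        y = rng.normal(10.0, 2.0, 2000)
        m = LMSModel(family="NO", df_mu=0, df_sigma=0).fit(age, y)
        lam, mu, sigma = m.curves([120.0])
        assert lam[0] == 1.0
        assert mu[0] == pytest.approx(10.0, abs=0.15)
        assert sigma[0] == pytest.approx(2.0, abs=0.15)

    def test_flat_median_equals_sample_mean(self):
        rng = np.random.default_rng(3)
        age = uniform_ages(rng, 500)
        y = rng.normal(5.0, 1.0, 500)
        m = LMSModel(family="NO", df_mu=0, df_sigma=0).fit(age, y)
        p50 = m.centiles([100.0], levels=[50])["p50"].iloc[0]
        assert p50 == pytest.approx(y.mean(), abs=1e-6)

    def test_centile_examples(self):
        rng = np.random.default_rng(4)
        age = uniform_ages(rng, 3000)
        y = rng.normal(10.0, 2.0, 3000)
        m = LMSModel(family="NO", df_mu=0, df_sigma=0).fit(age, y)
        tab = m.centiles([120.0], levels=[50, 97.7])
        assert tab["p50"].iloc[0] == pytest.approx(10.0, abs=0.15)
        assert tab["p97.7"].iloc[0] == pytest.approx(14.0, abs=0.3)  # mu + 2 sigma


class TestBCCG:
    def test_lambda_one_reduces_to_normal(self):
        rng = np.random.default_rng(11)
        age = uniform_ages(rng, 1500)
        y = np.clip(rng.normal(20.0, 2.0, 1500), 0.5, None)
        no = LMSModel("NO", df_mu=0, df_sigma=0).fit(age, y)
        bc = LMSModel("BCCG", df_mu=0, df_sigma=0, df_lambda=0).fit(age, y)
        m_no = no.centiles([120.0], [50])["p50"].iloc[0]
        m_bc = bc.centiles([120.0], [50])["p50"].iloc[0]
        assert m_bc == pytest.approx(m_no, abs=0.1)

    def test_constant_parameter_recovery(self):
        rng = np.random.default_rng(17)
        age = uniform_ages(rng, 2000)
        y = bccg_rvs(rng, 2000, 0.5, 20.0, 0.15)
        m = LMSModel("BCCG", df_mu=0, df_sigma=0, df_lambda=0).fit(age, y)
        lam, mu, sigma = m.curves([120.0])
        assert mu[0] == pytest.approx(20.0, rel=0.02)
        assert sigma[0] == pytest.approx(0.15, rel=0.10)
        # lambda's sampling sd is ~0.12 at this n; a loose per-dataset
        # sanity band (tight recovery is the acceptance-suite simulation)
        assert lam[0] == pytest.approx(0.5, abs=0.4)

    def test_nonpositive_response_falls_back_to_normal(self):
        rng = np.random.default_rng(6)
        age = uniform_ages(rng, 200)
        y = rng.normal(5.0, 3.0, 200)
        y[0] = -1.0
        with pytest.warns(UserWarning, match="NO family"):
            m = LMSModel("BCCG").fit(age, y)
        assert m.family_used_ == "NO"


class TestCentiles:
    def fit_skewed(self, df=(1, 3, 3)):
        rng = np.random.default_rng(31)
        age = uniform_ages(rng, 1200)
        mu = 10.0 + 8.0 * (age - 36.0) / 180.0  # rising median with age
        y = mu * np.exp(rng.normal(0, 0.25, age.size))
        return fit_lms(age, y, "BCCG", df), age, y

    def test_curves_never_cross_on_monthly_grid(self):
        m, age, _ = self.fit_skewed()
        grid = np.arange(np.ceil(age.min()), np.floor(age.max()) + 1.0)
        tab = m.centiles(grid, DEFAULT_LEVELS)
        vals = tab[[f"p{l:g}" for l in DEFAULT_LEVELS]].to_numpy()
        assert np.all(np.isfinite(vals))
        assert np.all(np.diff(vals, axis=1) > 0)

    def test_level_validation_and_grid_range(self):
        m, age, _ = self.fit_skewed()
        with pytest.raises(ValueError, match="outside"):
            m.centiles([100.0], levels=[0.0])
        with pytest.raises(ValueError, match="fitted range"):
            m.centiles([1000.0])

    def test_functional_wrapper(self):
        m, age, _ = self.fit_skewed()
        a = percentile_curve(m, [100.0, 150.0])
        pd.testing.assert_frame_equal(a, m.centiles([100.0, 150.0]))


class TestFamilySelection:
    def test_skewed_data_selects_bccg(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            age = uniform_ages(rng, 500)
            y = np.exp(rng.normal(2.5, 0.5, 500))
            best, report = select_family(age, y)
            wins += best.family_used_ == "BCCG"
            assert set(report["family"]) == {"NO", "BCCG"}
        assert wins >= 18

    def test_normal_data_selects_no_in_majority(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(700 + seed)
            age = uniform_ages(rng, 500)
            y = rng.normal(10.0, 2.0, 500)
            best, _ = select_family(age, y)
            wins += best.family_used_ == "NO"
        assert wins >= 12

    def test_negative_value_forces_normal(self):
        rng = np.random.default_rng(2)
        age = uniform_ages(rng, 100)
        y = rng.normal(5.0, 3.0, 100)
        y[10] = -0.5
        with pytest.warns(UserWarning):
            best, report = select_family(age, y, ("NO", "BCCG"))
        assert best.family_used_ == "NO"


class TestDiagnostics:
    def test_residual_count_and_calibration_under_true_model(self):
        rng = np.random.default_rng(8)
        age = uniform_ages(rng, 1500)
        y = bccg_rvs(rng, 1500, 0.5, 20.0, 0.15)
        m = fit_lms(age, y, "BCCG", (0, 1, 0))
        r = m.quantile_residuals(age, y)
        assert r.size == age.size
        mom = m.residual_moments(age, y)
        assert len(mom) == 9
        assert mom["n"].sum() == age.size

    def test_misspecified_fit_shows_skewness(self):
        """A normal fit to log-normal data leaves skewness in the
        quantile residuals of most age groups."""
        rng = np.random.default_rng(14)
        age = uniform_ages(rng, 1800)
        y = np.exp(rng.normal(2.0, 0.6, 1800))
        m = fit_lms(age, y, "NO", (0, 1, 1))
        mom = m.residual_moments(age, y)
        assert (mom["z_skewness"].abs() > 2).sum() >= 5


def test_deviance_monotone_over_nested_df():
    """Widening a nested spline basis can only improve the maximized
    likelihood (AIC then arbitrates the df trade-off)."""
    rng = np.random.default_rng(55)
    age = uniform_ages(rng, 800)
    y = (10.0 + 0.03 * age) * np.exp(rng.normal(0, 0.2, 800))
    devs = [
        LMSModel("BCCG", df_mu=df, df_sigma=0, df_lambda=0).fit(age, y).deviance_
        for df in (0, 1, 2, 3, 4)
    ]
    assert all(b <= a + 1e-6 for a, b in zip(devs, devs[1:]))


def test_aic_bookkeeping():
    rng = np.random.default_rng(9)
    age = uniform_ages(rng, 400)
    y = np.abs(rng.normal(10, 2, 400)) + 0.1
    m = fit_lms(age, y, "NO", (0, 2, 1))
    assert m.edf_ == (2 + 1) + (1 + 1)  # mu df=2, sigma df=1; lambda fixed adds 0
    assert m.aic_ == pytest.approx(-2.0 * m.loglik_ + 2.0 * m.edf_)
    bc = fit_lms(age, y, "BCCG", (1, 2, 1))
    assert bc.edf_ == m.edf_ + 2


def test_small_sample_rejected():
    with pytest.raises(ValueError, match="20"):
        LMSModel().fit(np.linspace(40, 200, 10), np.ones(10))


def test_median_coverage_on_synthetic_cohort(pushball_cohort):
    """End to end: about half the cohort falls below the fitted median
    curve of end-of-learning adaptation."""
    from reachdev.epochs import epoch_means

    _, _, epochs = pushball_cohort
    surface = epoch_means(epochs, "initial_angle_deg", "end_learning")
    age = surface["age_mo"].to_numpy()
    y = surface[("initial_angle_deg")].to_numpy()
    best, _ = select_family(age, y)
    frac_below = float(np.mean(best.cdf(age, y) < 0.5))
    # binomial band at n = 80 (about +/- 3 sigma)
    assert 0.33 <= frac_below <= 0.67
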