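"""Marker-model fitting, inversion, meta-analytic combination, and LOO."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from phylodecay import (
    FitError,
    combine_estimates,
    estimate_phyloage,
    fit_marker_model,
    loo_validate,
    predict_age,
    simulate_marker_cohort,
)

AGES8 = np.array([25.0, 29.0, 38.0, 48.0, 63.0, 75.0, 76.0, 81.0])


def exact_cohort(a=0.002, b=0.09, ages=AGES8):
    return a * np.exp(b * np.asarray(ages))


class TestMarkerFit:
    def test_noiseless_identity(self):
        values = exact_cohort(0.002, 0.09)
        m = fit_marker_model(AGES8, values, "alpha")
        assert m.a == pytest.approx(0.002, rel=1e-6)
        assert m.b == pytest.approx(0.09, rel=1e-6)

    def test_noisy_rate_recovery(self):
        """20% multiplicative noise, 8 ages: the median recovered rate b
        across 500 replicates stays within 15% of truth."""
        bs = []
        for rep in range(500):
            df = simulate_marker_cohort(AGES8, cv=0.2, seed=rep)
            m = fit_marker_model(df["age"], df["alpha"], "alpha")
            bs.append(m.b)
        assert abs(np.median(bs) - 0.09) <= 0.15 * 0.09

    def test_all_zero_values_rejected(self):
        with pytest.raises(ValueError):
            fit_marker_model(AGES8, np.zeros(8), "alpha")

    def test_too_few_positive_values_rejected(self):
        values = np.array([0, 0, 0, 0, 0, 0, 0.5, 0.9])
        with pytest.warns(UserWarning, match="non-positive"):
            with pytest.raises(ValueError):
                fit_marker_model(AGES8, values, "alpha")

    def test_decreasing_marker_rejected(self):
        values = exact_cohort(0.5, 0.0) * np.exp(-0.05 * AGES8)
        with pytest.raises(FitError):
            fit_marker_model(AGES8, values, "alpha")


class TestPredictAge:
    @pytest.fixture
    def model(self):
        return fit_marker_model(AGES8, exact_cohort(0.002, 0.09), "alpha")

    def test_value_at_scale_gives_age_zero(self, model):
        age, se = predict_age(model, 0.002)
        assert age == pytest.approx(0.0, abs=1e-6)
        assert se >= 0.0

    @pytest.mark.parametrize("true_age", [10.0, 50.0, 81.0])
    def test_roundtrip_inversion(self, model, true_age):
        value = 0.002 * math.exp(0.09 * true_age)
        age, _ = predict_age(model, value)
        assert age == pytest.approx(true_age, abs=1e-6)

    def test_nonpositive_value_rejected(self, model):
        with pytest.raises(ValueError, match="resolution"):
            predict_age(model, 0.0)


class TestCombine:
    def test_single_estimate_passthrough(self):
        c = combine_estimates([60.0], [5.0])
        assert (c.value, c.se, c.tau2) == (60.0, 5.0, 0.0)

    def test_inverse_variance_mean_equal_ses(self):
        c = combine_estimates([60.0, 70.0], [5.0, 5.0])
        assert c.value == pytest.approx(65.0, abs=0.5)

    def test_identical_estimates_pool_to_se_over_sqrt2(self):
        c = combine_estimates([50.0, 50.0], [4.0, 4.0])
        assert c.value == pytest.approx(50.0)
        assert c.tau2 == pytest.approx(0.0, abs=1e-8)
        assert c.se == pytest.approx(4.0 / math.sqrt(2), rel=1e-6)

    def test_combined_value_within_input_range(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.uniform(20, 90, 2)
            s = rng.uniform(1, 15, 2)
            c = combine_estimates(x, s)
            assert min(x) - 1e-9 <= c.value <= max(x) + 1e-9
            assert c.se <= max(s) + 1e-9 or c.tau2 > 0

    def test_no_finite_se_rejected(self):
        with pytest.raises(ValueError):
            combine_estimates([60.0], [np.inf])

    def test_matches_metafor_ml_estimate(self):
        """Cross-check the ML random-effects pooling against the
        reference implementation in R (metafor::rma, method='ML')."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the metafor cross-check")
        yi = [58.0, 71.0, 49.0, 66.0]
        sei = [4.0, 6.0, 9.0, 3.5]
        script = (
            "suppressMessages(library(metafor));"
            f"r <- rma(yi=c({','.join(map(str, yi))}),"
            f" sei=c({','.join(map(str, sei))}), method='ML');"
            "cat(r$b, r$se, r$tau2)"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            timeout=120, check=True,
        )
        mu_r, se_r, tau2_r = map(float, out.stdout.split())
        c = combine_estimates(yi, sei)
        assert c.value == pytest.approx(mu_r, abs=1e-3)
        assert c.se == pytest.approx(se_r, abs=1e-3)
        assert c.tau2 == pytest.approx(tau2_r, abs=1e-3)


class TestEstimatePhyloAge:
    @pytest.fixture
    def models(self):
        return (
            fit_marker_model(AGES8, exact_cohort(0.002, 0.09), "alpha"),
            fit_marker_model(AGES8, exact_cohort(0.003, 0.08), "beta"),
        )

    def test_noiseless_prediction_and_residual(self, models):
        ma, mb = models
        alpha = 0.002 * math.exp(0.09 * 64.0)
        beta = 0.003 * math.exp(0.08 * 64.0)
        est = estimate_phyloage(alpha, beta, ma, mb, chronological_age=60.0)
        assert est.phylo_age == pytest.approx(64.0, abs=1e-4)
        assert est.residual_age == pytest.approx(4.0, abs=1e-4)
        assert est.abs_residual_age == pytest.approx(4.0, abs=1e-4)

    def test_nonpositive_marker_dropped(self, models):
        ma, mb = models
        beta = 0.003 * math.exp(0.08 * 70.0)
        est = estimate_phyloage(0.0, beta, ma, mb, chronological_age=70.0)
        assert set(est.marker_ages) == {"beta"}
        assert est.phylo_age == pytest.approx(70.0, abs=1e-4)

    def test_both_markers_dropped_reports_censored(self, models):
        ma, mb = models
        est = estimate_phyloage(0.0, -0.1, ma, mb, chronological_age=20.0)
        assert est.below_resolution
        assert est.phylo_age is None
        assert est.upper_bound == pytest.approx(25.0)


class TestLeaveOneOut:
    def test_noiseless_cohort_near_perfect_correlation(self):
        df = pd.DataFrame({
            "id": [f"i{k}" for k in range(8)], "age": AGES8,
            "alpha": exact_cohort(0.002, 0.09),
            "beta": exact_cohort(0.003, 0.08),
        })
        res = loo_validate(df)
        assert res.n_completed == 8
        assert res.correlation > 0.999
        assert res.mean_abs_residual < 0.01

    def test_noisy_cohorts_track_age(self):
        """With 20% marker noise at n = 8, LOO correlation is typically
        above 0.8 (median over replicates)."""
        cors = []
        for rep in range(40):
            df = simulate_marker_cohort(AGES8, cv=0.2, seed=1000 + rep)
            res = loo_validate(df)
            cors.append(res.correlation)
        assert np.median(cors) > 0.8

    def test_cohort_of_three_rejected(self):
        df = simulate_marker_cohort([30.0, 50.0, 70.0], seed=0)
        with pytest.raises(ValueError):
            loo_validate(df)

    def test_residual_age_centered_for_healthy_draws(self):
        """An individual drawn from the fitted model has residualAge with
        |mean| below 2 standard errors over replicates."""
        ma = fit_marker_model(AGES8, exact_cohort(0.002, 0.09), "alpha")
        mb = fit_marker_model(AGES8, exact_cohort(0.003, 0.08), "beta")
        rng = np.random.default_rng(5)
        sigma = math.sqrt(math.log(1.04))
        resid = []
        for _ in range(250):
            age = rng.uniform(30, 80)
            alpha = 0.002 * math.exp(0.09 * age) * rng.lognormal(-sigma**2 / 2, sigma)
            beta = 0.003 * math.exp(0.08 * age) * rng.lognormal(-sigma**2 / 2, sigma)
            est = estimate_phyloage(alpha, beta, ma, mb, chronological_age=age)
            resid.append(est.residual_age)
        resid = np.asarray(resid)
        se = resid.std(ddof=1) / math.sqrt(resid.size)
        assert abs(resid.mean()) <= 2 * se + 0.05
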