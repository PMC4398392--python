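"""Loss-rate regressions, survival arithmetic, inter-annual rates."""

import numpy as np
import pandas as pd
import pytest

from echosurvey.reference_data import (
    INTERANNUAL_GAP_DAYS,
    MEAN_SUMMER_SPAN_DAYS,
    published_fits_table,
)
from echosurvey.trends import (
    TrendFit,
    abundance_ratio_per_halving,
    fit_decline,
    fit_loglinear,
    interannual_rates,
    mean_loss_rate,
    survival,
)

from reference import ref_ols


def published_fits():
    return [
        TrendFit(r.class_label, r.year, r.ln_initial_count, r.slope_per_day, 0.0,
                 r.r_squared, r.p_value, 6)
        for r in published_fits_table().itertuples()
    ]


class TestFitDecline:
    def test_reconstructed_series_recovers_printed_fit(self):
        """Counts rebuilt from a published intercept/slope pair refit to the
        same slope (3 dp) and intercept (2 dp), with near-perfect R^2."""
        t = np.array([0, 7, 8, 20, 23, 32], dtype=float)
        counts = np.round(np.exp(7.423 - 0.067 * t))
        df = pd.DataFrame({"survey_id": np.arange(6), "day": t, "count_4": counts})
        fit = fit_decline(df, 4)
        assert fit.slope_per_day == pytest.approx(-0.067, abs=5e-4)
        assert fit.ln_initial_count == pytest.approx(7.423, abs=0.01)
        assert fit.r_squared > 0.999

    def test_constant_counts_flat_fit(self):
        df = pd.DataFrame({"survey_id": range(4), "day": [0, 5, 10, 15], "count_8": [50] * 4})
        fit = fit_decline(df, 8)
        assert fit.slope_per_day == 0.0
        assert fit.r_squared == 0.0

    def test_day_measured_from_first_survey_by_year(self):
        dates = ["2011-07-26", "2011-08-02", "2011-08-27", "2012-07-28", "2012-08-08", "2012-08-24"]
        c = [100, 80, 40, 90, 60, 40]
        df = pd.DataFrame(
            {"survey_id": range(6), "date": dates, "year": [2011] * 3 + [2012] * 3,
             "count_16": c}
        )
        f11 = fit_decline(df, 16, 2011)
        # intercept is the ln count at the year's own first survey
        assert f11.ln_initial_count == pytest.approx(np.log(100), abs=0.15)

    def test_zero_counts_dropped_with_warning(self):
        df = pd.DataFrame(
            {"survey_id": range(5), "day": [0, 5, 10, 15, 20], "count_4": [100, 60, 0, 20, 12]}
        )
        with pytest.warns(UserWarning):
            fit = fit_decline(df, 4)
        assert fit.n_surveys == 4

    def test_too_few_points_no_fit(self):
        df = pd.DataFrame({"survey_id": range(2), "day": [0, 5], "count_4": [10, 5]})
        assert fit_decline(df, 4) is None

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(4, 12))
            x = np.sort(rng.uniform(0, 40, n))
            x -= x.min()
            y_counts = np.exp(rng.uniform(2, 8) + rng.uniform(-0.08, 0.0) * x + rng.normal(0, 0.2, n))
            fit = fit_loglinear(x, y_counts)
            slope, intercept, r2, se, p = ref_ols(list(x), list(np.log(y_counts)))
            assert fit.slope_per_day == pytest.approx(slope, abs=1e-10)
            assert fit.ln_initial_count == pytest.approx(intercept, abs=1e-10)
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)
            assert fit.p_value == pytest.approx(p, abs=1e-10)
            assert fit.slope_se == pytest.approx(se, abs=1e-10)


class TestSummaries:
    def test_mean_loss_rate_large_classes(self):
        rate = mean_loss_rate(published_fits(), [16, 32, 64])
        assert round(rate, 3) == -0.038

    def test_mean_loss_rate_trivia(self):
        f = published_fits()[:1]
        assert mean_loss_rate(f) == f[0].slope_per_day
        two = [
            TrendFit(4, None, 0, -0.01, 0, 0, 1, 3),
            TrendFit(8, None, 0, -0.03, 0, 0, 1, 3),
        ]
        assert mean_loss_rate(two) == pytest.approx(-0.02)
        with pytest.raises(ValueError):
            mean_loss_rate(two, [128])

    def test_survival(self):
        assert survival(0.0, 100.0) == 1.0
        assert round(survival(-0.001, INTERANNUAL_GAP_DAYS), 2) == 0.71
        rate = mean_loss_rate(published_fits(), [16, 32, 64])
        assert round(survival(rate, MEAN_SUMMER_SPAN_DAYS), 2) == 0.33

    def test_abundance_ratio(self):
        fits_2011 = [f for f in published_fits() if f.year == 2011]
        assert abundance_ratio_per_halving(fits_2011) == pytest.approx(3.31, abs=0.02)
        assert round(abundance_ratio_per_halving(published_fits())) == 3
        flat = [TrendFit(l, None, 5.0, 0, 0, 0, 1, 3) for l in (4, 8, 16)]
        assert abundance_ratio_per_halving(flat) == pytest.approx(1.0)
        two = [TrendFit(4, None, np.log(2), 0, 0, 0, 1, 3), TrendFit(8, None, 0.0, 0, 0, 0, 1, 3)]
        assert abundance_ratio_per_halving(two) == pytest.approx(2.0)


class TestInterannual:
    def test_equal_counts_same_class_zero(self):
        r = interannual_rates({32: 50, 64: 20}, {32: 50, 64: 20}, 336, incremented=False)
        assert r[32] == 0.0 and r[64] == 0.0

    def test_incremented_arithmetic(self):
        r = interannual_rates({32: 100, 64: 50}, {32: 90, 64: 71}, 336)
        assert r[32] == pytest.approx(np.log(0.71) / 336, abs=1e-6)
        assert r[32] == pytest.approx(-0.00102, abs=2e-5)
        assert r[64] == pytest.approx(np.log(71 / 50) / 336)

    def test_mode_difference_identity(self):
        n1 = {16: 200, 32: 100, 64: 40}
        n2 = {16: 150, 32: 80, 64: 30}
        ri = interannual_rates(n1, n2, 100, incremented=True)
        rs = interannual_rates(n1, n2, 100, incremented=False)
        labels = sorted(n1, key=float)
        for i, k in enumerate(labels[:-1]):
            expect = (np.log(n2[labels[i + 1]]) - np.log(n2[k])) / 100
            assert ri[k] - rs[k] == pytest.approx(expect, abs=1e-12)

    def test_zero_count_undefined(self):
        r = interannual_rates({32: 0, 64: 10}, {32: 5, 64: 10}, 336)
        assert np.isnan(r[32])

    def test_small_classes_skipped_by_default(self):
        r = interannual_rates({4: 10, 8: 10, 16: 10, 32: 10, 64: 10},
                              {4: 10, 8: 10, 16: 10, 32: 10, 64: 10}, 100)
        assert set(r) == {16, 32, 64}
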