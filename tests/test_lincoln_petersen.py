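"""Lincoln-Petersen point/variance arithmetic, period means and jackknife pooling."""

import numpy as np
import pytest

from markresight import (
    Dataset,
    EstimationError,
    MarkingRecord,
    SimulationConfig,
    SurveyRecord,
    chapman_point,
    cumulative_estimates,
    lp_point,
    lp_se,
    period_estimate,
    simulate_dataset,
)


def _dataset(surveys_cr, M=2000, period="P", method="SO"):
    """Build a one-period dataset from (C, R) pairs, alternating AM/PM."""
    surveys = []
    for i, (c, r) in enumerate(surveys_cr):
        surveys.append(
            SurveyRecord(
                period, i // 2 + 1, "AM" if i % 2 == 0 else "PM", method, r, c - r
            )
        )
    return Dataset(surveys, [MarkingRecord(period, M)])


class TestPointAndVariance:
    @pytest.mark.parametrize(
        "M,C,R,expected",
        [
            (50, 30, 30, 50.0),  # every sighting marked => N_hat = M
            (2000, 1000, 100, 20000.0),
            (100, 100, 100, 100.0),
        ],
    )
    def test_lp_point(self, M, C, R, expected):
        assert lp_point(M, C, R) == pytest.approx(expected)

    def test_no_marked_resights_is_an_estimation_error(self):
        with pytest.raises(EstimationError, match="no marked resights"):
            lp_point(2000, 1000, 0)

    @pytest.mark.parametrize("M,C,R", [(10, 5, 8), (5, 100, 8)])
    def test_impossible_counts_rejected(self, M, C, R):
        with pytest.raises(ValueError):
            lp_point(M, C, R)

    @pytest.mark.parametrize(
        "M,C,R,expected",
        [
            (2000, 1000, 100, 1897.3665961),
            (2000, 1000, 500, 126.4911064),
            (2000, 1000, 1000, 0.0),  # all counted are marked
        ],
    )
    def test_lp_se(self, M, C, R, expected):
        assert lp_se(M, C, R) == pytest.approx(expected, rel=1e-9)

    def test_lp_se_equals_delta_method_form(self):
        # sqrt(N_hat^2 * C * p(1-p) / R^2) with p = R/C, algebraically the same
        M, C, R = 1500, 800, 90
        n_hat = lp_point(M, C, R)
        p = R / C
        delta = np.sqrt(n_hat**2 * C * p * (1 - p) / R**2)
        assert lp_se(M, C, R) == pytest.approx(delta, rel=1e-12)

    def test_chapman_is_defined_at_zero_recaptures(self):
        assert chapman_point(2000, 1000, 0) == pytest.approx(2001 * 1001 - 1)
        # close to LP when counts are large
        assert chapman_point(2000, 1000, 100) == pytest.approx(
            lp_point(2000, 1000, 100), rel=0.02
        )


class TestPeriodEstimate:
    def test_mean_of_per_survey_estimates_with_sem(self):
        ds = _dataset([(1000, 100), (800, 120)])
        est = period_estimate(ds, "P", "SO")
        e1, e2 = 2000 * 1000 / 100, 2000 * 800 / 120
        assert est.n_hat == pytest.approx((e1 + e2) / 2)
        assert est.se == pytest.approx(np.std([e1, e2], ddof=1) / np.sqrt(2))
        assert est.se == pytest.approx(abs(e1 - e2) / 2)
        assert est.mean_total == pytest.approx(900.0)
        assert est.source == "period_mean"

    def test_single_survey_falls_back_to_analytic_se(self):
        ds = _dataset([(1000, 100)])
        est = period_estimate(ds, "P", "SO")
        assert est.source == "single"
        assert est.n_hat == pytest.approx(lp_point(2000, 1000, 100))
        assert est.se == pytest.approx(lp_se(2000, 1000, 100))

    def test_identical_surveys_have_zero_se(self):
        ds = _dataset([(1000, 100)] * 6)
        assert period_estimate(ds, "P", "SO").se == 0.0

    def test_zero_recapture_surveys_excluded_with_warning(self):
        ds = _dataset([(1000, 100), (500, 0)])
        with pytest.warns(UserWarning, match="no marked resights"):
            est = period_estimate(ds, "P", "SO")
        assert est.n_surveys == 1

    def test_all_zero_recaptures_is_an_error(self):
        ds = _dataset([(1000, 0), (500, 0)])
        with pytest.warns(UserWarning):
            with pytest.raises(EstimationError):
                period_estimate(ds, "P", "SO")

    def test_invariant_to_swapping_count_columns_then_relabelling(self):
        """Swapping marked/unmarked columns and relabelling M accordingly is a no-op."""
        ds = _dataset([(1000, 100), (800, 120)])
        swapped = Dataset(
            [
                SurveyRecord(s.period_id, s.day, s.diel, s.method,
                             s.unmarked_seen, s.marked_seen)
                for s in ds.surveys
            ],
            ds.markings,
        )
        restored = Dataset(
            [
                SurveyRecord(s.period_id, s.day, s.diel, s.method,
                             s.unmarked_seen, s.marked_seen)
                for s in swapped.surveys
            ],
            ds.markings,
        )
        assert period_estimate(restored, "P", "SO").n_hat == pytest.approx(
            period_estimate(ds, "P", "SO").n_hat
        )


class TestCumulative:
    def test_k1_matches_single_survey_lp(self):
        ds = _dataset([(1000, 100), (800, 120)])
        cum = cumulative_estimates(ds, "P", "SO")
        assert cum[0].k == 1
        assert cum[0].n_hat == pytest.approx(lp_point(2000, 1000, 100))
        assert cum[0].width == pytest.approx(2 * 1.959963984540054 * lp_se(2000, 1000, 100))

    def test_k2_pools_counts_before_the_quotient(self):
        ds = _dataset([(1000, 100), (800, 120)])
        cum = cumulative_estimates(ds, "P", "SO")
        assert cum[1].n_hat == pytest.approx(2000 * 900 / 110)

    def test_identical_surveys_collapse_the_jackknife_interval(self):
        ds = _dataset([(1000, 100)] * 6)
        cum = cumulative_estimates(ds, "P", "SO")
        assert all(c.n_hat == pytest.approx(20000.0) for c in cum)
        assert all(c.width == pytest.approx(0.0) for c in cum[1:])

    def test_jackknife_matches_direct_enumeration(self):
        ds = _dataset([(1000, 100), (800, 120), (900, 95), (1100, 130)])
        cum = cumulative_estimates(ds, "P", "SO")
        C = np.array([1000.0, 800, 900, 1100])
        R = np.array([100.0, 120, 95, 130])
        for k in (2, 3, 4):
            loo = np.array(
                [
                    2000
                    * np.delete(C[:k], i).mean()
                    / np.delete(R[:k], i).mean()
                    for i in range(k)
                ]
            )
            var = (k - 1) / k * np.sum((loo - loo.mean()) ** 2)
            assert cum[k - 1].width == pytest.approx(
                2 * 1.959963984540054 * np.sqrt(var)
            )

    def test_surveys_pooled_in_chronological_order(self):
        ds = Dataset(
            [
                SurveyRecord("P", 2, "AM", "SO", 50, 450),
                SurveyRecord("P", 1, "PM", "SO", 100, 900),
                SurveyRecord("P", 1, "AM", "SO", 200, 800),
            ],
            [MarkingRecord("P", 2000)],
        )
        cum = cumulative_estimates(ds, "P", "SO")
        assert cum[0].n_hat == pytest.approx(2000 * 1000 / 200)

    def test_zero_mean_recaptures_is_an_error(self):
        ds = _dataset([(1000, 0)])
        with pytest.raises(EstimationError):
            cumulative_estimates(ds, "P", "SO")


class TestRecoveryProperties:
    def test_lp_unbiased_under_equal_detectability(self):
        """Mean period estimate within 2% of truth (reduced-scale check)."""
        n_hats = []
        for rep in range(40):
            cfg = SimulationConfig(
                periods=["P"],
                methods=("UAV",),
                mark_bias=1.0,
                base_detect=0.15,
                seed=20_000 + rep,
            )
            res = simulate_dataset(cfg)
            n_hats.append(period_estimate(res.dataset, "P", "UAV").n_hat)
        assert abs(np.mean(n_hats) - 20_000) / 20_000 < 0.02

    def test_marked_detection_bias_deflates_the_estimate(self):
        """With SO odds bias kappa, N_hat_SO ~ M + (N-M)/r < N (r = prob ratio)."""
        n_hats = []
        for rep in range(40):
            cfg = SimulationConfig(
                periods=["P"], methods=("SO",), seed=30_000 + rep
            )
            res = simulate_dataset(cfg)
            n_hats.append(period_estimate(res.dataset, "P", "SO").n_hat)
        assert np.mean(n_hats) < 0.75 * 20_000
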