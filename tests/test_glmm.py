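"""Sampler correctness and parameter recovery for the detection GLMM."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from markresight import (
    DetectionGLMM,
    DetectionGLMMResults,
    EstimationError,
    SimulationConfig,
    fit_detection_model,
    hpd_interval,
    simulate_dataset,
    simulate_marked_counts,
)


def _results_from_draws(model, draws: pd.DataFrame) -> DetectionGLMMResults:
    return DetectionGLMMResults(
        model=model, draws=draws, n_chains=1, n_iter=len(draws), n_burn=0
    )


@pytest.fixture(scope="module")
def toy_model():
    ds, _ = simulate_marked_counts(-2.3, {"UAV": -0.3}, n_periods=2,
                                   methods=("SO", "UAV"), seed=99)
    return DetectionGLMM(ds)


class TestSamplerMechanics:
    def test_identical_seed_gives_identical_draws(self):
        ds, _ = simulate_marked_counts(-2.5, {"UAV": -0.4}, seed=4)
        f1 = DetectionGLMM(ds).fit(n_iter=300, n_burn=100, seed=7)
        f2 = DetectionGLMM(ds).fit(n_iter=300, n_burn=100, seed=7)
        assert f1.draws.equals(f2.draws)

    def test_prior_only_run_recovers_prior_moments_of_alpha(self):
        """With the likelihood switched off the chain must sample the prior."""
        ds, _ = simulate_marked_counts(-2.5, seed=5)
        fit = DetectionGLMM(ds, use_likelihood=False).fit(
            n_iter=20_000, n_burn=2_000, seed=3
        )
        a = fit.draws["alpha"]
        assert abs(a.mean()) < 1.0  # prior mean 0, sd 10
        assert 8.8 < a.std() < 11.2

    def test_few_retained_draws_warns(self):
        ds, _ = simulate_marked_counts(-2.5, n_periods=2, seed=6)
        with pytest.warns(UserWarning, match="retained"):
            DetectionGLMM(ds).fit(n_iter=100, n_burn=50, seed=1)

    def test_convergence_across_chains(self):
        ds, _ = simulate_marked_counts(float(logit(0.08)), {"UAV": -0.4}, seed=21)
        fit = DetectionGLMM(ds).fit(n_iter=3_000, n_burn=1_000, n_chains=3, seed=4)
        assert (fit.rhat() < 1.1).all()

    def test_requires_two_methods_and_positive_totals(self):
        ds, _ = simulate_marked_counts(-2.5, methods=("SO",), seed=1)
        with pytest.raises(EstimationError, match="two methods"):
            DetectionGLMM(ds)
        df = pd.DataFrame(
            {
                "period_id": ["P", "P"],
                "day": [1, 1],
                "diel": ["AM", "PM"],
                "method": ["SO", "UAV"],
                "marked_seen": [0, 0],
                "total_seen": [0, 5],
            }
        )
        with pytest.raises(EstimationError, match="total_seen"):
            DetectionGLMM(df)


class TestAgainstFixedEffectsOracle:
    def test_degenerate_model_matches_ml_logistic_fit(self):
        """All sigmas pinned at 0 reduces to a fixed-effects logistic regression."""
        sm = pytest.importorskip("statsmodels.api")
        ds, _ = simulate_marked_counts(
            -2.3, {"UWV": 0.3, "UAV": -0.5},
            sigma_period=0, sigma_day=0, sigma_diel=0, sigma_resid=0,
            n_periods=1, mean_total=2000, seed=11,
        )
        fit = DetectionGLMM(
            ds, sigma_fixed={"period": 0, "day": 0, "diel": 0, "resid": 0}
        ).fit(n_iter=8_000, n_burn=2_000, seed=2)
        df = ds.to_frame()
        X = pd.get_dummies(df["method"]).astype(float)[["UWV", "UAV"]]
        X.insert(0, "const", 1.0)
        glm = sm.GLM(
            np.column_stack([df.marked_seen, df.total_seen - df.marked_seen]),
            X,
            family=sm.families.Binomial(),
        ).fit()
        assert fit.params["alpha"] == pytest.approx(glm.params["const"], abs=0.05)
        assert fit.params["beta_UWV"] == pytest.approx(glm.params["UWV"], abs=0.05)
        assert fit.params["beta_UAV"] == pytest.approx(glm.params["UAV"], abs=0.05)

    def test_exchangeable_methods_centre_beta_at_zero(self):
        rows = []
        for pid in ("A", "B"):
            for day in (1, 2):
                for diel in ("AM", "PM"):
                    for method in ("SO", "UWV", "UAV"):
                        rows.append(
                            {
                                "period_id": pid,
                                "day": day,
                                "diel": diel,
                                "method": method,
                                "marked_seen": 80,
                                "total_seen": 1000,
                            }
                        )
        fit = fit_detection_model(pd.DataFrame(rows), n_iter=2_000, n_burn=500, seed=9)
        for name in ("beta_UWV", "beta_UAV"):
            lo, hi = fit.hpd(name)
            assert lo < 0 < hi


class TestRecovery:
    def test_parameters_recovered_within_credible_intervals(self):
        alpha_true = float(logit(0.065))
        ds, _ = simulate_marked_counts(
            alpha_true, {"UWV": -0.05, "UAV": -0.44},
            sigma_period=1.0, sigma_day=0.05, sigma_diel=0.05, sigma_resid=0.1,
            n_periods=6, mean_total=800, seed=1000,
        )
        fit = DetectionGLMM(ds).fit(n_iter=5_000, n_burn=1_000, seed=0)
        lo, hi = fit.hpd("beta_UAV")
        assert lo <= -0.44 <= hi
        lo, hi = fit.hpd("sigma_period")
        assert lo <= 1.0 <= hi

    def test_marked_proportions_recovered_at_study_scale(self):
        a = float(logit(0.094))
        b = float(logit(0.063)) - a
        ds, _ = simulate_marked_counts(
            a, {"UAV": b, "UWV": -0.2},
            sigma_period=0.2, sigma_day=0.05, sigma_diel=0.05, sigma_resid=0.1,
            mean_total=1000, seed=31,
        )
        fit = DetectionGLMM(ds).fit(n_iter=5_000, n_burn=1_000, seed=5)
        props = fit.marked_proportions().set_index("method")
        assert props.loc["SO", "mean"] == pytest.approx(0.094, abs=0.02)
        assert props.loc["UAV", "mean"] == pytest.approx(0.063, abs=0.02)

    def test_surface_bias_detected_from_individual_based_simulation(self):
        """SO mark-bias in the generative model -> P(prop_SO > prop_UAV) > 0.9."""
        res = simulate_dataset(SimulationConfig(seed=42))
        fit = DetectionGLMM(res.dataset).fit(n_iter=4_000, n_burn=1_000, seed=6)
        d = fit.draws
        p_so = expit(d["alpha"])
        p_uav = expit(d["alpha"] + d["beta_UAV"])
        assert (p_so > p_uav).mean() > 0.9

    def test_period_dominates_variance_partition_when_generated_so(self):
        ds, _ = simulate_marked_counts(
            float(logit(0.08)), {"UAV": -0.4},
            sigma_period=1.0, sigma_day=0.01, sigma_diel=0.01, sigma_resid=0.05,
            mean_total=1000, seed=77,
        )
        fit = DetectionGLMM(ds).fit(n_iter=4_000, n_burn=1_000, seed=7)
        vp = fit.variance_partition().set_index("component")
        assert vp.loc["period", "share_mean"] > 0.8


class TestPosteriorSummaries:
    def test_degenerate_partition_is_all_period(self, toy_model):
        n = 300
        draws = pd.DataFrame(
            {
                "chain": 0,
                "iteration": range(n),
                "alpha": np.zeros(n),
                "beta_UAV": np.zeros(n),
                "sigma_period": np.full(n, 0.7),
                "sigma_day": np.zeros(n),
                "sigma_diel": np.zeros(n),
                "sigma_resid": np.full(n, 0.1),
            }
        )
        vp = _results_from_draws(toy_model, draws).variance_partition()
        vp = vp.set_index("component")
        assert vp.loc["period", "share_mean"] == pytest.approx(1.0)
        assert vp.loc["day", "share_mean"] == pytest.approx(0.0)

    def test_all_zero_draw_gets_uniform_share_with_warning(self, toy_model):
        n = 300
        draws = pd.DataFrame(
            {
                "chain": 0,
                "iteration": range(n),
                "alpha": np.zeros(n),
                "beta_UAV": np.zeros(n),
                "sigma_period": np.r_[0.0, np.full(n - 1, 0.5)],
                "sigma_day": np.zeros(n),
                "sigma_diel": np.zeros(n),
                "sigma_resid": np.zeros(n),
            }
        )
        res = _results_from_draws(toy_model, draws)
        with pytest.warns(UserWarning, match="uniform"):
            vp = res.variance_partition().set_index("component")
        # one uniform draw among n
        assert vp.loc["period", "share_mean"] == pytest.approx(
            ((n - 1) * 1.0 + 1 / 3) / n
        )

    def test_shares_sum_to_one_per_draw(self, toy_model):
        rng = np.random.default_rng(0)
        n = 500
        draws = pd.DataFrame(
            {
                "chain": 0,
                "iteration": range(n),
                "alpha": rng.normal(size=n),
                "beta_UAV": rng.normal(size=n),
                "sigma_period": rng.gamma(2, 1, n),
                "sigma_day": rng.gamma(2, 1, n),
                "sigma_diel": rng.gamma(2, 1, n),
                "sigma_resid": rng.gamma(2, 1, n),
            }
        )
        sig2 = draws[["sigma_period", "sigma_day", "sigma_diel"]].to_numpy() ** 2
        shares = sig2 / sig2.sum(axis=1, keepdims=True)
        assert np.allclose(shares.sum(axis=1), 1.0, atol=1e-12)
        vp = _results_from_draws(toy_model, draws).variance_partition()
        assert vp["share_mean"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_linear_predictor_gives_half(self, toy_model):
        n = 250
        draws = pd.DataFrame(
            {
                "chain": 0,
                "iteration": range(n),
                "alpha": np.zeros(n),
                "beta_UAV": np.zeros(n),
                "sigma_period": np.full(n, 0.3),
                "sigma_day": np.zeros(n),
                "sigma_diel": np.zeros(n),
                "sigma_resid": np.zeros(n),
            }
        )
        props = _results_from_draws(toy_model, draws).marked_proportions()
        assert (props["mean"] == 0.5).all()

    def test_hpd_matches_arviz_on_a_normal_sample(self):
        az = pytest.importorskip("arviz")
        x = np.random.default_rng(1).normal(size=8_000)
        lo, hi = hpd_interval(x, 0.95)
        ref = az.hdi(x, hdi_prob=0.95)
        assert lo == pytest.approx(ref[0], abs=0.05)
        assert hi == pytest.approx(ref[1], abs=0.05)

    def test_summary_lists_every_parameter(self, toy_model):
        fit = toy_model.fit(n_iter=400, n_burn=200, seed=3)
        s = fit.summary()
        assert set(s["parameter"]) == {
            "alpha", "beta_UAV", "sigma_period", "sigma_day",
            "sigma_diel", "sigma_resid",
        }
        assert (s["hpd_low"] <= s["mean"]).all() and (s["mean"] <= s["hpd_high"]).all()
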