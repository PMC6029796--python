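"""DiD GLM tests: recovery, saturated closed forms, standardization, diagnostics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hinhcost import (
    GeneratorConfig,
    LosEffectModel,
    adjusted_means,
    fit_los_model,
    fit_rate_model,
    generate,
    intervention_contrast,
    residual_diagnostics,
)

CELLS = [("control", "pre"), ("control", "post"), ("intervention", "pre"), ("intervention", "post")]


def monthly_frame(counts, exposure=1000.0):
    """One observation per design cell with the given presentation counts."""
    rows = []
    for (h, y), n in zip(CELLS, counts):
        rows.append(
            {
                "hospital": h, "year": y, "month_index": 0,
                "n_presentations": n, "n_admissions": 0, "exposure_beds": exposure,
            }
        )
    return pd.DataFrame(rows)


def episode_frame(cell_means, n_per_cell=200, shape=50.0, seed=0):
    """Gamma episodes with exact multiplicative structure across cells."""
    rng = np.random.default_rng(seed)
    frames = []
    for (h, y), mu in zip(CELLS, cell_means):
        frames.append(
            pd.DataFrame(
                {
                    "hospital": h, "year": y,
                    "ed_los_hours": rng.gamma(shape, mu / shape, size=n_per_cell),
                    "admitted": True,
                    "inpatient_los_hours": rng.gamma(shape, mu / shape, size=n_per_cell),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestRateModel:
    def test_null_data_ratio_near_one(self, null_config):
        config = dataclasses.replace(null_config, months_per_period=60)
        _, monthly = generate(config)
        model = fit_rate_model(monthly)
        row = model.ratios_.loc["x3"]
        assert row["ci_low"] < 1.0 < row["ci_high"]
        assert row["ratio"] == pytest.approx(1.0, abs=0.15)

    def test_recovers_intervention_rate_ratio(self):
        config = GeneratorConfig(months_per_period=50, beds_per_catchment=2000.0, seed=3)
        _, monthly = generate(config)
        model = fit_rate_model(monthly, outcome="admissions")
        row = model.ratios_.loc["x3"]
        assert row["ci_low"] < 0.53 < row["ci_high"]
        assert row["ratio"] == pytest.approx(0.53, abs=0.08)

    def test_saturated_design_reproduces_cell_means(self):
        counts = [120, 90, 100, 40]
        model = fit_rate_model(monthly_frame(counts))
        means = adjusted_means(model, n_draws=200)
        for (h, y), n in zip(CELLS, counts):
            # exposure is 1,000 beds, so the fitted rate equals the count
            assert means.loc[(h, y), "mean"] == pytest.approx(n, rel=1e-6)

    def test_exponentiated_ratios_consistent(self):
        model = fit_rate_model(monthly_frame([120, 90, 100, 40]))
        np.testing.assert_allclose(
            model.ratios_["ratio"], np.exp(model.coefficients_), rtol=1e-12
        )

    def test_doubling_exposure_halves_fitted_rates(self):
        counts = [120, 90, 100, 40]
        m1 = fit_rate_model(monthly_frame(counts, exposure=1000.0))
        m2 = fit_rate_model(monthly_frame(counts, exposure=2000.0))
        a1 = adjusted_means(m1, n_draws=100)["mean"]
        a2 = adjusted_means(m2, n_draws=100)["mean"]
        np.testing.assert_allclose(a2, a1 / 2.0, rtol=1e-6)
        assert m2.coefficients_["x3"] == pytest.approx(m1.coefficients_["x3"], abs=1e-8)

    def test_missing_cell_rejected(self):
        frame = monthly_frame([120, 90, 100, 40]).iloc[:3]
        with pytest.raises(ValueError, match="design cell"):
            fit_rate_model(frame)

    def test_nonpositive_exposure_rejected(self):
        frame = monthly_frame([120, 90, 100, 40], exposure=0.0)
        with pytest.raises(ValueError, match="exposures"):
            fit_rate_model(frame)


class TestLosModel:
    def test_recovers_intervention_los_ratio(self):
        config = GeneratorConfig(
            beds_per_catchment=8000.0,
            baseline_rates={"presentations": 60.0, "admissions": 30.0},
            hospital_rate_ratio=1.0, year_rate_ratio=1.0, intervention_rate_ratio=1.0,
            baseline_los_means={"ed": 13.0, "inpatient": 80.0},
            hospital_los_ratio=1.0, year_los_ratio=1.0,
            intervention_los_ratio={"ed": 0.53, "inpatient": 1.0},
            seed=17,
        )
        episodes = generate(config)[0]
        model = fit_los_model(episodes, outcome="ed")
        row = model.ratios_.loc["x3"]
        assert row["ci_low"] < 0.53 < row["ci_high"]
        assert row["ratio"] == pytest.approx(0.53, abs=0.07)

    def test_constant_los_gives_null_effects(self):
        frame = episode_frame([10.0] * 4, shape=1.0, seed=1)
        frame["ed_los_hours"] = 10.0
        model = LosEffectModel("ed", covariates=()).fit(frame)
        for term in ("x1", "x2", "x3"):
            assert model.coefficients_[term] == pytest.approx(0.0, abs=1e-8)

    def test_doubling_one_cell_doubles_its_ratio(self):
        frame = episode_frame([10.0] * 4, n_per_cell=400, shape=100.0, seed=2)
        mask = (frame["hospital"] == "intervention") & (frame["year"] == "post")
        frame.loc[mask, "ed_los_hours"] *= 2.0
        model = LosEffectModel("ed", covariates=()).fit(frame)
        assert model.ratios_.loc["x3", "ratio"] == pytest.approx(2.0, rel=0.02)

    def test_nonpositive_los_rejected(self):
        frame = episode_frame([10.0] * 4)
        frame.loc[0, "ed_los_hours"] = 0.0
        with pytest.raises(ValueError, match="strictly positive"):
            fit_los_model(frame, outcome="ed")

    def test_inpatient_model_uses_admitted_only(self):
        frame = episode_frame([10.0] * 4)
        frame.loc[:50, "admitted"] = False
        frame.loc[:50, "inpatient_los_hours"] = np.nan
        model = fit_los_model(frame, outcome="inpatient", covariates=())
        assert model.n_obs_ == int(frame["admitted"].sum())


class TestAdjustedMeansAndContrast:
    def test_reference_level_recoding_leaves_means_unchanged(self, default_data):
        _, episodes, _ = default_data
        episodes = episodes.sample(1500, random_state=0).reset_index(drop=True)
        model = fit_los_model(episodes, outcome="ed", n_draws=200)
        means = adjusted_means(model)["mean"]
        recoded = episodes.copy()
        order = ["85-94", "<65", ">=95", "65-74", "75-84"]
        recoded["age_group"] = pd.Categorical(recoded["age_group"], categories=order)
        model2 = fit_los_model(recoded, outcome="ed", n_draws=200)
        means2 = adjusted_means(model2)["mean"]
        np.testing.assert_allclose(means, means2, rtol=1e-8)

    def test_difference_consistent_with_ratio_without_covariates(self):
        model = fit_rate_model(monthly_frame([120, 90, 100, 40]))
        contrast = intervention_contrast(model, n_draws=200)
        beta3 = model.coefficients_["x3"]
        expected = contrast.without.mean * (np.exp(beta3) - 1.0)
        assert contrast.difference.mean == pytest.approx(expected, rel=1e-9)
        assert contrast.difference.mean == pytest.approx(
            contrast.with_.mean - contrast.without.mean, rel=1e-12
        )

    def test_null_interaction_gives_zero_difference(self):
        # cell counts with an exactly multiplicative structure (interaction 1)
        model = fit_rate_model(monthly_frame([100, 80, 50, 40]))
        contrast = intervention_contrast(model, n_draws=200)
        assert model.ratios_.loc["x3", "ratio"] == pytest.approx(1.0, abs=1e-7)
        assert contrast.difference.mean == pytest.approx(0.0, abs=1e-4)

    def test_contrast_p_value_matches_wald(self):
        model = fit_rate_model(monthly_frame([120, 90, 100, 40]))
        contrast = intervention_contrast(model, n_draws=200)
        assert contrast.p_value == model.result_.pvalues["x3"]

    def test_ci_brackets_point_estimate(self, default_data):
        _, _, monthly = default_data
        model = fit_rate_model(monthly, n_draws=2_000)
        contrast = intervention_contrast(model)
        for est in (contrast.without, contrast.with_, contrast.difference):
            assert est.ci_low <= est.mean <= est.ci_high


class TestResidualDiagnostics:
    def test_correctly_specified_gamma_deviance_ratio_near_one(self):
        # gamma with shape 1 (coefficient of variation 1, dispersion 1), n = 2,000
        frame = episode_frame([8.0, 9.0, 12.0, 10.0], n_per_cell=500, shape=1.0, seed=4)
        model = LosEffectModel("ed", covariates=()).fit(frame)
        diag = residual_diagnostics(model)
        assert 0.7 < diag.deviance_ratio < 1.3
        assert 0.7 < diag.pearson_ratio < 1.3

    def test_residual_count_and_centering(self):
        frame = episode_frame([8.0, 9.0, 12.0, 10.0], n_per_cell=300, shape=5.0, seed=5)
        model = LosEffectModel("ed", covariates=()).fit(frame)
        diag = residual_diagnostics(model)
        assert len(diag.residuals) == model.n_obs_ == len(diag.fitted)
        assert abs(diag.residuals.mean()) < 0.2
        assert diag.hist_counts.sum() == model.n_obs_
        assert np.all(np.diff(diag.qq_sample) >= 0)
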