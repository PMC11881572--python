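"""Per-animal fitting, uncertainty sampling and derived PK metrics."""

import numpy as np
import pandas as pd
import pytest

from renalpbpk.config import DoseRegimen
from renalpbpk.estimation import (
    FitSpec,
    derive_pk_metrics,
    fit_animal,
    sample_parameters,
    summarize_cohort,
)
from renalpbpk.kidney import steady_auc_ratio_oracle
from renalpbpk.synthetic import SyntheticDesign, fit_cohort, generate_cohort


@pytest.fixture(scope="module")
def noise_free_fit(physiologies, geometries, drugs):
    """Fit of one noise-free virtual rat (truth at the species medians)."""
    design = SyntheticDesign("rat", "CAZ", n_animals=1, residual_cv=0.0,
                             parameter_cv=0.0, seed=11)
    data, truth = generate_cohort(design)
    fits = fit_cohort(data, design, n_starts=2, seed=11)
    return fits["rat01"], truth.iloc[0], design


class TestFitAnimal:
    def test_noise_free_recovery_within_one_percent(self, noise_free_fit):
        fit, truth, _ = noise_free_fit
        assert fit.estimates["cl_glomerular"] == pytest.approx(
            truth["true_cl_glomerular"], rel=0.01)
        assert fit.estimates["p_interstitium_to_blood"] == pytest.approx(
            truth["true_p_interstitium_to_blood"], rel=0.01)

    def test_refit_from_optimum_is_stationary(self, noise_free_fit, physiologies,
                                              geometries, drugs):
        fit, _, design = noise_free_fit
        spec = FitSpec(free=fit.param_names, initial=dict(fit.estimates), n_starts=1)
        phys, geom = physiologies["rat"], geometries["rat"]
        refit = fit_animal(fit.residuals, phys, geom, drugs[("CAZ", "rat")],
                           DoseRegimen.bolus(6.6), spec, seed=0)
        for name in fit.param_names:
            assert refit.estimates[name] == pytest.approx(fit.estimates[name], rel=1e-6)

    def test_single_probe_with_two_kidney_parameters_warns(
        self, physiologies, geometries, drugs
    ):
        obs = pd.DataFrame({
            "probe_site": ["blood"] * 4,
            "t_start_h": [0.0, 0.5, 1.0, 1.5],
            "t_end_h": [0.5, 1.0, 1.5, 2.0],
            "conc_corrected_mg_L": [5.0, 3.0, 2.0, 1.5],
        })
        spec = FitSpec(free=("cl_glomerular", "p_interstitium_to_blood"),
                       initial={"cl_glomerular": 0.15,
                                "p_interstitium_to_blood": 30e-6},
                       n_starts=1)
        with pytest.warns(RuntimeWarning, match="unidentifiable"):
            fit_animal(obs, physiologies["rat"], geometries["rat"], drugs["CAZ"],
                       DoseRegimen.bolus(6.6), spec)

    def test_ci_width_shrinks_with_noise(self):
        """Proportional-error CIs are monotone in the residual noise level."""
        widths = []
        for cv in (0.15, 0.05):
            design = SyntheticDesign("rat", "CAZ", n_animals=1, residual_cv=cv,
                                     parameter_cv=0.0, seed=3)
            data, _ = generate_cohort(design)
            fit = fit_cohort(data, design, n_starts=2, seed=3)["rat01"]
            lo, hi = fit.ci95("p_interstitium_to_blood")
            widths.append(hi / lo)
        assert widths[1] < widths[0]


class TestSampleParameters:
    def test_zero_covariance_reproduces_point_estimate(self, noise_free_fit):
        fit, _, _ = noise_free_fit
        frozen = sample_parameters(fit, 100, seed=1)
        # noise-free covariance is numerically tiny: draws hug the estimate
        for name in fit.param_names:
            np.testing.assert_allclose(frozen[name], fit.estimates[name], rtol=1e-3)

    def test_seeded_draws_are_reproducible(self, noise_free_fit):
        fit, _, _ = noise_free_fit
        a = sample_parameters(fit, 500, seed=42)
        b = sample_parameters(fit, 500, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = sample_parameters(fit, 500, seed=43)
        assert not a.equals(c)

    def test_lognormal_median_matches_point_estimate(self):
        design = SyntheticDesign("rat", "CAZ", n_animals=1, residual_cv=0.15,
                                 parameter_cv=0.0, seed=5)
        data, _ = generate_cohort(design)
        fit = fit_cohort(data, design, n_starts=2, seed=5)["rat01"]
        draws = sample_parameters(fit, 1000, seed=9)
        for name in fit.param_names:
            assert draws[name].median() == pytest.approx(fit.estimates[name], rel=0.05)


class TestDerivedMetrics:
    def test_single_draw_matches_auc_ratio_oracle(self, physiologies, geometries, drugs):
        drug = drugs[("CAZ", "rat")]
        draws = pd.DataFrame([{"cl_glomerular": drug.cl_glomerular,
                               "p_interstitium_to_blood": drug.p_interstitium_to_blood}])
        metrics = derive_pk_metrics(draws, physiologies["rat"], geometries["rat"],
                                    drug, DoseRegimen.bolus(6.6))
        oracle = steady_auc_ratio_oracle(physiologies["rat"], geometries["rat"], drug)
        assert metrics.per_draw["auc_ratio_cortex"].iloc[0] == pytest.approx(
            oracle, rel=1e-3)
        assert metrics.per_draw["auc_ratio_muscle"].iloc[0] == pytest.approx(
            1.0, abs=1e-3)

    def test_avi_rat_secretion_share(self, physiologies, geometries, drugs):
        """Tubular secretion is 0.0612 of 0.220 L/h total (~27.8%) at the rat
        avibactam medians."""
        drug = drugs[("AVI", "rat")]
        draws = pd.DataFrame([{"p_interstitium_to_blood": drug.p_interstitium_to_blood}])
        metrics = derive_pk_metrics(draws, physiologies["rat"], geometries["rat"],
                                    drug, DoseRegimen.bolus(1.65))
        row = metrics.per_draw.iloc[0]
        share = row["cl_tubular_secretion"] / row["cl_total"]
        assert share == pytest.approx(0.0612 / (0.158 + 0.0612), rel=1e-9)
        assert row["cl_total"] == pytest.approx(
            row["cl_glomerular"] + row["cl_tubular_secretion"] + row["cl_nonrenal"],
            rel=1e-12)

    def test_summaries_have_ordered_quantiles(self, physiologies, geometries, drugs):
        drug = drugs[("CAZ", "rat")]
        rng = np.random.default_rng(0)
        draws = pd.DataFrame({
            "cl_glomerular": drug.cl_glomerular * np.exp(rng.normal(0, 0.1, 20)),
            "p_interstitium_to_blood":
                drug.p_interstitium_to_blood * np.exp(rng.normal(0, 0.1, 20)),
        })
        metrics = derive_pk_metrics(draws, physiologies["rat"], geometries["rat"],
                                    drug, DoseRegimen.bolus(6.6))
        summary = metrics.summary()
        assert (summary["ci_lower"] <= summary["median"]).all()
        assert (summary["median"] <= summary["ci_upper"]).all()


class TestCohortSummary:
    def test_single_animal_cohort_equals_that_animal(self, physiologies, geometries,
                                                     drugs):
        drug = drugs[("CAZ", "rat")]
        draws = pd.DataFrame([{"cl_glomerular": 0.154,
                               "p_interstitium_to_blood": 33.8e-6}] * 3)
        metrics = derive_pk_metrics(draws, physiologies["rat"], geometries["rat"],
                                    drug, DoseRegimen.bolus(6.6))
        cohort = summarize_cohort([metrics])
        pd.testing.assert_series_equal(cohort["median"], metrics.median,
                                       check_names=False)

    def test_identical_animals_share_the_median(self, physiologies, geometries, drugs):
        drug = drugs[("CAZ", "rat")]
        draws = pd.DataFrame([{"cl_glomerular": 0.154,
                               "p_interstitium_to_blood": 33.8e-6}])
        one = derive_pk_metrics(draws, physiologies["rat"], geometries["rat"],
                                drug, DoseRegimen.bolus(6.6))
        cohort = summarize_cohort([one, one, one])
        assert cohort.loc["auc_ratio_cortex", "median"] == pytest.approx(
            one.median["auc_ratio_cortex"])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])
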