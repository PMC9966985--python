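import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from gcompsurv import (
    InputError,
    InterventionSpec,
    ModelSpec,
    RiskCurve,
    apply_intervention,
    contrast,
    estimate_effect,
    expand_person_periods,
    fit_pooled_logistic,
    marginal_risk,
    transform_exposures,
)
from gcompsurv.gformula import estimate_effects_multi


class TestInterventionSpec:
    def test_percentile_resolution(self, small_transformed):
        cohort, anchors = small_transformed
        low = InterventionSpec(exposure="lead", rule="percentile", percentile=5)
        assert low.resolve_value("lead", anchors) == anchors["lead"].p5

    def test_value_rule(self, small_transformed):
        cohort, anchors = small_transformed
        cf = apply_intervention(
            cohort, InterventionSpec(exposure="cadmium", rule="value", value=1.63), anchors
        )
        assert (cf["cadmium_std"] == 1.63).all()
        assert (cf["log2_cadmium"] == np.log2(1.63)).all()
        # non-targeted metal untouched
        pd.testing.assert_series_equal(cf["blood_lead"], cohort["blood_lead"])

    def test_percentile_sets_all_to_anchor(self, small_transformed):
        cohort, anchors = small_transformed
        cf = apply_intervention(
            cohort, InterventionSpec(exposure="lead", rule="percentile", percentile=5), anchors
        )
        assert (cf["blood_lead"] == anchors["lead"].p5).all()

    def test_identity_intervention_leaves_cohort_unchanged(self, small_transformed):
        cohort, anchors = small_transformed
        c2 = cohort.copy()
        c2["blood_lead"] = 3.0
        c2["log2_lead"] = np.log2(3.0)
        cf = apply_intervention(
            c2, InterventionSpec(exposure="lead", rule="value", value=3.0), anchors
        )
        pd.testing.assert_frame_equal(
            cf.drop(columns="lead_quartile"), c2.drop(columns="lead_quartile")
        )

    def test_percentile_without_anchors_errors(self, small_cohort):
        spec = InterventionSpec(exposure="lead", rule="percentile", percentile=5)
        with pytest.raises(InputError):
            spec.resolve_value("lead", None)

    def test_invalid_rules_rejected(self):
        from gcompsurv import ConfigurationError

        with pytest.raises(ConfigurationError):
            InterventionSpec(rule="halve")
        with pytest.raises(ConfigurationError):
            InterventionSpec(rule="percentile", percentile=101)
        with pytest.raises(ConfigurationError):
            InterventionSpec(rule="value", value=-1.0)

    def test_quartile_intervention_sets_label_and_value(self, small_transformed):
        cohort, anchors = small_transformed
        cf = apply_intervention(
            cohort, InterventionSpec(exposure="lead", rule="quartile", quartile=4), anchors
        )
        assert (cf["lead_quartile"] == 4).all()
        assert (cf["blood_lead"] == anchors["lead"].quartile_medians[3]).all()


class TestMarginalRisk:
    def test_constant_hazard_closed_form(self):
        # covariate-free constant-hazard fit: R(T) = 1 - (1-h)^T exactly
        rng = np.random.default_rng(5)
        rows = []
        for i in range(300):
            for t in range(1, 9):
                event = int(rng.random() < 0.15)
                rows.append((i, t, event, 1.0))
                if event:
                    break
        pp = pd.DataFrame(rows, columns=["id", "period", "event", "weight"])
        spec = ModelSpec(
            exposures=(), covariates=[], time_form="none",
            include_time_products=False, weighted=False,
        )
        model = fit_pooled_logistic(pp, spec)
        h = expit(model.params[0])
        baseline = pd.DataFrame({"weight": np.ones(50)})
        curve = marginal_risk(model, baseline, horizon=8, weighting="unweighted")
        expected = 1.0 - (1.0 - h) ** np.arange(1, 9)
        np.testing.assert_allclose(curve.risk, expected, atol=1e-12)

    def test_monotone_and_bounded(self, small_transformed):
        cohort, anchors = small_transformed
        pp = expand_person_periods(cohort, cause="all")
        model = fit_pooled_logistic(pp, ModelSpec(weighted=True), anchors)
        curve = marginal_risk(model, cohort, horizon=27, weighting="weighted")
        assert np.all(np.diff(curve.risk) >= 0)
        assert curve.risk[0] >= 0 and curve.risk[-1] <= 1

    def test_riskcurve_validation(self):
        with pytest.raises(InputError):
            RiskCurve("all", "x", np.array([0.3, 0.2]))  # decreasing
        with pytest.raises(InputError):
            RiskCurve("all", "x", np.array([0.3, 1.2]))  # out of range


def _nonparametric_standardization(cohort, lead_value):
    """Exhaustive standardization oracle: empirical cell risks averaged
    over the covariate distribution."""
    dead = (cohort["status"] == "dead").astype(float)
    risk = 0.0
    for sex, grp in cohort.groupby("sex"):
        cell = cohort[(cohort["blood_lead"] == lead_value) & (cohort["sex"] == sex)]
        risk += (len(grp) / len(cohort)) * (cell["status"] == "dead").mean()
    return risk


class TestStandardizationOracle:
    def test_saturated_gcomputation_equals_exhaustive_standardization(
        self, saturated_cohort
    ):
        cohort, anchors = None, None
        with pytest.warns(UserWarning):  # two-point exposure: degenerate quartiles
            cohort, anchors = transform_exposures(saturated_cohort)
        pp = expand_person_periods(cohort, cause="all")
        spec = ModelSpec(
            exposures=("lead",), covariates=["sex"], time_form="none",
            include_time_products=False, weighted=False,
        )
        model = fit_pooled_logistic(pp, spec, anchors)
        for v in (1.0, 2.0):
            cf = apply_intervention(
                cohort, InterventionSpec(exposure="lead", rule="value", value=v), anchors
            )
            curve = marginal_risk(model, cf, horizon=1, weighting="unweighted")
            oracle = _nonparametric_standardization(saturated_cohort, v)
            assert curve.risk[0] == pytest.approx(oracle, abs=1e-10)


class TestContrast:
    def test_identical_curves_null_effect(self):
        c = RiskCurve("all", "same", np.array([0.1, 0.2, 0.3]))
        eff = contrast(c, RiskCurve("all", "same", np.array([0.1, 0.2, 0.3])))
        np.testing.assert_array_equal(eff.rd, 0.0)
        np.testing.assert_array_equal(eff.rr, 1.0)

    def test_arithmetic(self):
        low = RiskCurve("all", "low", np.array([0.30]))
        high = RiskCurve("all", "high", np.array([0.35]))
        eff = contrast(low, high)
        assert eff.rd[0] == pytest.approx(0.05)
        assert eff.rr[0] == pytest.approx(0.35 / 0.30)

    def test_zero_reference_gives_nan_not_inf(self):
        low = RiskCurve("all", "low", np.array([0.0, 0.1]))
        high = RiskCurve("all", "high", np.array([0.2, 0.2]))
        eff = contrast(low, high)
        assert np.isnan(eff.rr[0])
        assert np.isfinite(eff.rr[1])

    def test_mismatched_curves_rejected(self):
        a = RiskCurve("all", "a", np.array([0.1]))
        b = RiskCurve("cvd", "b", np.array([0.1]))
        with pytest.raises(InputError):
            contrast(a, b)


class TestEstimateEffect:
    def test_direction_convention_harmful_exposure(self, small_cohort):
        # positive exposure coefficients: risk under p95 exceeds risk under p5
        spec = ModelSpec(weighted=False)
        low = InterventionSpec(exposure="cadmium", rule="percentile", percentile=5)
        high = InterventionSpec(exposure="cadmium", rule="percentile", percentile=95)
        eff = estimate_effect(small_cohort, spec, low, high, horizon=27)
        assert eff.rd[-1] > 0
        assert eff.rr[-1] > 1

    def test_identical_interventions_zero_effect(self, small_cohort):
        spec = ModelSpec(weighted=False)
        same = InterventionSpec(exposure="lead", rule="percentile", percentile=50)
        eff = estimate_effect(small_cohort, spec, same, same, horizon=27)
        np.testing.assert_array_equal(eff.rd, 0.0)
        np.testing.assert_allclose(eff.rr, 1.0, atol=1e-14)

    def test_multi_pair_matches_single_pair(self, small_cohort):
        spec = ModelSpec(weighted=True)
        pairs = [
            (
                InterventionSpec(exposure=e, rule="percentile", percentile=5),
                InterventionSpec(exposure=e, rule="percentile", percentile=95),
            )
            for e in ("lead", "cadmium")
        ]
        effs, _, _ = estimate_effects_multi(small_cohort, spec, pairs, 27)
        single = estimate_effect(small_cohort, spec, *pairs[1], horizon=27)
        np.testing.assert_allclose(effs[1].rd, single.rd, atol=1e-12)

    def test_quartile_dummy_contrast(self, small_cohort):
        spec = ModelSpec(exposure_form="quartile", weighted=True)
        low = InterventionSpec(exposure="lead", rule="quartile", quartile=1)
        high = InterventionSpec(exposure="lead", rule="quartile", quartile=4)
        eff = estimate_effect(small_cohort, spec, low, high, horizon=27)
        assert np.all(np.isfinite(eff.rd))
        assert eff.rd[-1] > -1 and eff.rd[-1] < 1
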