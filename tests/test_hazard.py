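import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from gcompsurv import (
    InputError,
    ModelSpec,
    NonConvergenceError,
    PredictionError,
    expand_person_periods,
    fit_pooled_logistic,
    linearity_check,
    rcs_basis,
    transform_exposures,
)
from gcompsurv.hazard import build_design
from gcompsurv.synthetic import GeneratorConfig, generate_cohort


# ---------------------------------------------------------------------------
# Restricted cubic spline basis
# ---------------------------------------------------------------------------


def _rcs_oracle(x, knots):
    """Independent truncated-power natural-spline construction.

    Built from the constraint equations directly: fit the cubic truncated
    powers, then impose zero quadratic/cubic curvature beyond the last knot
    by solving for the last two truncated-power coefficients in terms of the
    earlier ones.  Evaluated pointwise, no vectorized reuse of the package
    code path.
    """
    t = np.asarray(knots, float)
    k = len(t)
    out = np.empty((len(x), k - 1))
    for i, xi in enumerate(x):
        out[i, 0] = xi
        for j in range(k - 2):
            d = lambda a: max(xi - a, 0.0) ** 3
            term = (
                d(t[j])
                - d(t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + d(t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
            )
            out[i, j + 1] = term / (t[k - 1] - t[0]) ** 2
    return out


class TestRcsBasis:
    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200) * 2
        knots = (-1.5, 0.2, 1.8)
        basis = rcs_basis(x, knots)
        np.testing.assert_allclose(basis.values, _rcs_oracle(x, knots), atol=1e-10)

    def test_zero_below_first_knot(self):
        basis = rcs_basis(np.array([-5.0, -1.5]), (-1.5, 0.0, 2.0))
        np.testing.assert_array_equal(basis.values[:, 1], 0.0)

    def test_linear_tails(self):
        # second differences vanish outside the boundary knots
        knots = (0.0, 1.0, 2.0)
        for xs in (np.array([-3.0, -2.9, -2.8]), np.array([5.0, 5.1, 5.2])):
            col = rcs_basis(xs, knots).values[:, 1]
            assert abs((col[2] - col[1]) - (col[1] - col[0])) < 1e-9

    def test_duplicate_knots_rejected(self):
        with pytest.raises(InputError):
            rcs_basis(np.array([0.0]), (0.0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Pooled logistic fitting
# ---------------------------------------------------------------------------


def _constant_hazard_pp(n=400, T=5, p=0.2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        for t in range(1, T + 1):
            event = int(rng.random() < p)
            rows.append((i, t, event, 1.0, 2.0 ** rng.normal(1.5, 0.5)))
            if event:
                break
    pp = pd.DataFrame(rows, columns=["id", "period", "event", "weight", "blood_lead"])
    pp["log2_lead"] = np.log2(pp["blood_lead"])
    return pp


INTERCEPT_ONLY = ModelSpec(
    exposure_form="log2", time_form="none", include_time_products=False,
    exposures=(), covariates=[], weighted=False,
)


class TestFitPooledLogistic:
    def test_intercept_recovers_logit_of_event_fraction(self):
        pp = _constant_hazard_pp()
        model = fit_pooled_logistic(pp, INTERCEPT_ONLY)
        phat = pp["event"].mean()
        assert model.params[0] == pytest.approx(logit(phat), abs=1e-10)
        assert model.grad_norm < 1e-8

    def test_equal_weights_match_unweighted(self):
        pp = _constant_hazard_pp()
        pp["weight"] = 3.7
        spec = ModelSpec(
            exposures=("lead",), covariates=[], time_form="linear", weighted=True
        )
        spec_u = ModelSpec(
            exposures=("lead",), covariates=[], time_form="linear", weighted=False
        )
        m_w = fit_pooled_logistic(pp, spec)
        m_u = fit_pooled_logistic(pp, spec_u)
        np.testing.assert_allclose(m_w.params, m_u.params, atol=1e-9)

    def test_matches_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        pp = _constant_hazard_pp(n=600, seed=4)
        spec = ModelSpec(
            exposures=("lead",), covariates=[], time_form="quadratic", weighted=False
        )
        model = fit_pooled_logistic(pp, spec)
        X = model.design.build(pp)
        ref = sm.GLM(pp["event"].to_numpy(), X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(model.params, ref.params, atol=1e-7)
        np.testing.assert_allclose(model.bse, ref.bse, rtol=1e-5)

    def test_predicted_hazards_in_unit_interval(self, small_transformed):
        cohort, anchors = small_transformed
        pp = expand_person_periods(cohort, cause="all")
        spec = ModelSpec(weighted=True)
        model = fit_pooled_logistic(pp, spec, anchors)
        h = model.predict_hazard(pp)
        assert np.all((h > 0) & (h < 1))
        assert model.grad_norm < 1e-8

    def test_zero_events_rejected(self):
        pp = _constant_hazard_pp(n=20, p=0.0)
        with pytest.raises(InputError):
            fit_pooled_logistic(pp, INTERCEPT_ONLY)

    def test_separation_names_offending_column(self):
        pp = _constant_hazard_pp(n=300, seed=9)
        pp["event"] = (pp["log2_lead"] > 1.5).astype(int)  # perfect separation
        spec = ModelSpec(
            exposures=("lead",), covariates=[], time_form="none",
            include_time_products=False, weighted=False,
        )
        with pytest.raises(NonConvergenceError) as err:
            fit_pooled_logistic(pp, spec)
        assert err.value.column == "log2_lead"

    def test_rank_deficiency_warned_predictions_identified(self):
        pp = _constant_hazard_pp()
        pp["blood_lead"] = 4.0  # constant exposure: column collinear with intercept
        pp["log2_lead"] = 2.0
        spec = ModelSpec(
            exposures=("lead",), covariates=[], time_form="none",
            include_time_products=False, weighted=False,
        )
        with pytest.warns(UserWarning, match="rank deficient"):
            model = fit_pooled_logistic(pp, spec)
        assert model.rank_deficient
        phat = pp["event"].mean()
        np.testing.assert_allclose(model.predict_hazard(pp), phat, atol=1e-8)

    def test_saturated_model_reproduces_cell_fractions(self, saturated_cohort):
        cohort, anchors = transform_exposures(saturated_cohort)
        pp = expand_person_periods(cohort, cause="all")
        spec = ModelSpec(
            exposures=("lead",), covariates=["sex"], time_form="none",
            include_time_products=False, weighted=False,
        )
        model = fit_pooled_logistic(pp, spec, anchors)
        h = model.predict_hazard(pp)
        emp = pp.groupby(["log2_lead", "sex"])["event"].transform("mean")
        np.testing.assert_allclose(h, emp, atol=1e-9)

    def test_unseen_level_raises_prediction_error(self, small_transformed):
        cohort, anchors = small_transformed
        pp = expand_person_periods(cohort, cause="all")
        spec = ModelSpec(weighted=False)
        model = fit_pooled_logistic(pp, spec, anchors)
        other = cohort.copy()
        other.loc[0, "smoking"] = "pipe"
        with pytest.raises(PredictionError, match="pipe"):
            model.hazard_matrix(other, 5)

    def test_coefficient_recovery_on_generated_data(self):
        # moderate-size sanity check; the full-scale recovery run lives in
        # the acceptance suite
        cfg = GeneratorConfig(n_subjects=12000, seed=77)
        cohort = generate_cohort(cfg)
        cohort, anchors = transform_exposures(cohort, weighted=False)
        pp = expand_person_periods(cohort, cause="other")
        spec = ModelSpec(cause="other", weighted=False)
        model = fit_pooled_logistic(pp, spec, anchors)
        truth = cfg.true_coefficients["other"]
        coef, se = model.params, model.bse
        names = model.column_names
        checks = {
            "log2_lead": truth["log2_lead"],
            "log2_cadmium": truth["log2_cadmium"],
            "age": truth["age"],
            "bmi": truth["bmi"],
        }
        for name, true_val in checks.items():
            i = names.index(name)
            assert abs(coef[i] - true_val) < 4 * se[i], name


# ---------------------------------------------------------------------------
# Departure-from-linearity
# ---------------------------------------------------------------------------


class TestLinearityCheck:
    def test_report_structure_and_curve(self, small_transformed):
        cohort, anchors = small_transformed
        pp = expand_person_periods(cohort, cause="all")
        spec = ModelSpec(weighted=False)
        rep = linearity_check(pp, spec, anchors, exposure="lead")
        assert 0 <= rep.p_value <= 1
        assert rep.df >= 1
        assert len(rep.curve) == 25
        # log-odds difference is zero at the reference (median) exposure
        i_ref = (rep.curve["log2_exposure"] - np.log2(anchors["lead"].p50)).abs().idxmin()
        assert abs(rep.curve.loc[i_ref, "log_odds_vs_median"]) < 0.05

    def test_zeroed_nonlinear_coefficients_give_straight_line(self, small_transformed):
        cohort, anchors = small_transformed
        pp = expand_person_periods(cohort, cause="all")
        spec = ModelSpec(weighted=False)
        rep = linearity_check(pp, spec, anchors, exposure="lead")
        spl = rep.spline_model
        params = spl.params.copy()
        for j, name in enumerate(spl.column_names):
            if name.startswith("rcs("):
                params[j] = 0.0
        # with the nonlinear terms removed the dose-response curve must be
        # exactly linear in log2 exposure
        grid = rep.curve["log2_exposure"].to_numpy()
        knots = spl.design.spline_knots["lead"]
        basis = rcs_basis(grid, knots).values
        i_lin = spl.column_names.index("log2_lead")
        curve = basis[:, 0] * params[i_lin]
        resid = np.polyfit(grid, curve, 1, full=True)[1]
        assert float(resid[0]) < 1e-20
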