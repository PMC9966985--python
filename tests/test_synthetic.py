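import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import chi2_contingency, kstest

from gcompsurv import (
    ConfigurationError,
    GeneratorConfig,
    InputError,
    InterventionSpec,
    compute_truth,
    generate_cohort,
    null_exposure_config,
    study_config,
    transform_exposures,
)
from gcompsurv.synthetic import CensoringParams, CovariateParams, ExposureParams


class TestConfigValidation:
    def test_bad_correlation_names_field(self):
        with pytest.raises(ConfigurationError, match="correlation"):
            GeneratorConfig(exposure_params=ExposureParams(correlation=1.5))

    def test_bad_sd_names_field(self):
        with pytest.raises(ConfigurationError, match="lead_log2_sd"):
            GeneratorConfig(exposure_params=ExposureParams(lead_log2_sd=-1))

    def test_bad_probability_vector(self):
        with pytest.raises(ConfigurationError, match="smoking_probs"):
            GeneratorConfig(covariate_params=CovariateParams(smoking_probs=(0.5, 0.5, 0.5)))

    def test_unknown_truth_term(self):
        with pytest.raises(ConfigurationError, match="frobnicate"):
            GeneratorConfig(true_coefficients={"cvd": {"frobnicate": 1.0}})

    def test_nonpositive_sizes(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_subjects=0)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(horizon=0)


class TestGenerateCohort:
    def test_determinism_bit_identical(self):
        cfg = study_config(n_subjects=1000, seed=42)
        a = generate_cohort(cfg).to_csv(index=False)
        b = generate_cohort(study_config(n_subjects=1000, seed=42)).to_csv(index=False)
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_cohort(study_config(n_subjects=500, seed=1))
        b = generate_cohort(study_config(n_subjects=500, seed=2))
        assert not a["blood_lead"].equals(b["blood_lead"])

    def test_schema_and_ranges(self, small_cohort):
        c = small_cohort
        assert (c["blood_lead"] > 0).all()
        assert (c["cadmium_std"] > 0).all()
        assert (c["weight"] > 0).all()
        assert c["followup_years"].between(0, 27, inclusive="right").all()
        assert set(c["status"]) <= {"alive", "dead"}
        dead = c["status"] == "dead"
        assert set(c.loc[dead, "cause"]) <= {"cvd", "cancer", "other"}
        assert (c.loc[~dead, "cause"] == "none").all()

    def test_median_followup_matches_study(self):
        c = generate_cohort(study_config(n_subjects=20000, seed=9))
        assert abs(c["followup_years"].median() - 22.5) < 1.5

    def test_below_lod_lead_imputed_at_lod_over_sqrt2(self, small_cohort):
        flagged = small_cohort["lead_below_lod"]
        assert flagged.any()
        np.testing.assert_allclose(
            small_cohort.loc[flagged, "blood_lead"], 1.0 / np.sqrt(2)
        )

    def test_exposure_moments_match_config_without_loadings(self):
        ep = ExposureParams(
            lead_age=0.0, lead_male=0.0, lead_smoking_current=0.0,
            cadmium_age=0.0, cadmium_male=0.0, cadmium_smoking_current=0.0,
            lead_lod=1e-9, cadmium_lod_ugL=1e-12,  # effectively no imputation
        )
        cfg = GeneratorConfig(n_subjects=100_000, seed=5, exposure_params=ep)
        c = generate_cohort(cfg)
        x = np.log2(c["blood_lead"])
        se_mean = ep.lead_log2_sd / np.sqrt(len(c))
        assert abs(x.mean() - ep.lead_log2_mean) < 3 * se_mean
        assert abs(x.std() - ep.lead_log2_sd) < 0.01
        y = np.log2(c["cadmium_std"])
        r = np.corrcoef(x, y)[0, 1]
        assert abs(r - ep.correlation) < 0.01

    def test_null_config_death_independent_of_exposure_quartile(self):
        c = generate_cohort(null_exposure_config(n_subjects=6000, seed=3))
        c, _ = transform_exposures(c)
        tab = pd.crosstab(c["lead_quartile"], c["status"] == "dead")
        _, p, _, _ = chi2_contingency(tab)
        assert p > 0.01
        # p-values approximately uniform across generator seeds
        ps = []
        for seed in range(40):
            ci = generate_cohort(null_exposure_config(n_subjects=1200, seed=seed))
            ci, _ = transform_exposures(ci)
            tab = pd.crosstab(ci["cadmium_quartile"], ci["status"] == "dead")
            ps.append(chi2_contingency(tab)[1])
        assert kstest(ps, "uniform").pvalue > 0.005

    def test_dropout_option_shortens_followup(self):
        cfg = GeneratorConfig(
            n_subjects=3000, seed=1,
            censoring_params=CensoringParams(dropout_hazard=0.05),
        )
        c = generate_cohort(cfg)
        alive = c[c["status"] == "alive"]
        assert (alive["followup_years"] < 21.0).any()


class TestComputeTruth:
    LOW = InterventionSpec(exposure="lead", rule="value", value=1.0)
    HIGH = InterventionSpec(exposure="lead", rule="value", value=4.0)

    def test_identical_interventions_exact_null(self):
        cfg = study_config(n_subjects=100, seed=0)
        tr = compute_truth(cfg, (self.LOW, self.LOW), cause="all", mc_reps=10**4)
        np.testing.assert_array_equal(tr.rd, 0.0)
        np.testing.assert_allclose(tr.rr, 1.0)

    def test_single_period_closed_form(self):
        cfg = GeneratorConfig(
            n_subjects=10, horizon=1, seed=7,
            true_coefficients={"cvd": {"intercept": -2.0, "log2_lead": 0.5}},
        )
        tr = compute_truth(cfg, (self.LOW, self.HIGH), cause="cvd", mc_reps=2 * 10**5)
        for risk, se, lp in (
            (tr.risk_low[-1], tr.mc_se_low[-1], -2.0),
            (tr.risk_high[-1], tr.mc_se_high[-1], -1.0),
        ):
            assert abs(risk - expit(lp)) < 4 * se

    def test_null_coefficients_rd_within_mc_error(self):
        cfg = null_exposure_config(n_subjects=100, seed=2)
        tr = compute_truth(cfg, (self.LOW, self.HIGH), cause="all", mc_reps=5 * 10**4)
        assert np.all(np.abs(tr.rd) < 3 * tr.rd_se())

    def test_risks_monotone_and_bounded(self):
        cfg = study_config(n_subjects=100, seed=1)
        tr = compute_truth(cfg, (self.LOW, self.HIGH), cause="cancer", mc_reps=2 * 10**4)
        for r in (tr.risk_low, tr.risk_high):
            assert np.all(np.diff(r) >= 0)
            assert np.all((r >= 0) & (r <= 1))
        assert np.all(tr.rd_se() > 0)

    def test_net_risk_exceeds_cif_for_same_cause(self):
        # removing competing causes can only increase the target-cause risk
        cfg = study_config(n_subjects=100, seed=1)
        net = compute_truth(cfg, (self.LOW, self.HIGH), "cvd", 3 * 10**4, convention="net")
        cif = compute_truth(cfg, (self.LOW, self.HIGH), "cvd", 3 * 10**4, convention="cif")
        assert net.risk_high[-1] > cif.risk_high[-1] - 3 * (
            net.mc_se_high[-1] + cif.mc_se_high[-1]
        )

    def test_too_few_reps_rejected(self):
        cfg = study_config(n_subjects=10, seed=0)
        with pytest.raises(ConfigurationError):
            compute_truth(cfg, (self.LOW, self.HIGH), mc_reps=100)

    def test_percentile_rule_requires_cohort(self):
        cfg = study_config(n_subjects=10, seed=0)
        p5 = InterventionSpec(exposure="lead", rule="percentile", percentile=5)
        with pytest.raises(InputError):
            compute_truth(cfg, (p5, self.HIGH), mc_reps=10**4)
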