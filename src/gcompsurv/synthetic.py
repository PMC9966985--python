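"""Seeded synthetic cohorts with a known-truth counterfactual oracle.

The generator emulates the statistical structure of a national
health-survey cohort followed for mortality over a 27-year horizon:

- two right-skewed, correlated exposure biomarkers (blood lead, µg/dL;
  creatinine-standardized urinary cadmium, µg/g) log-normal on the log2
  scale, partially driven by age, sex and smoking (confounding), with
  below-LOD lead values imputed at LOD/sqrt(2);
- baseline covariates: age (truncated normal, 20-90 y), sex, race-ethnicity,
  poverty-income tertile, education years, residence, 3-level smoking, BMI,
  physical-activity category and a continuous diet-quality index;
- three competing causes of death (cardiovascular, cancer, other) generated
  period by period from cause-specific logistic discrete hazards of exactly
  the form the estimation pipeline fits (intercept, t, t^2, log2-exposure
  main effects, exposure x time products, covariate effects);
- administrative censoring only, from an entry-time spread giving censoring
  times uniform on a configurable interval (default 21-27 y, capped at the
  horizon), which reproduces a median follow-up near 22.5 years;
- dispersed log-normal survey weights, independent of the outcome by
  default (so weighted and unweighted estimands coincide) or optionally
  covariate-driven.

Competing causes are resolved symmetrically: in each period every cause's
event indicator is drawn from its own hazard; if several fire, one is
picked uniformly at random.  ``compute_truth`` Monte-Carlo-integrates the
true counterfactual risks implied by the same mechanism, under either the
net-risk convention (competing hazards switched off — the estimand of the
censor-at-competing-death estimator) or the crude cumulative incidence.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import ConfigurationError, InputError
from .prep import CAUSES, impute_below_lod

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ExposureParams:
    """Log2-scale exposure distribution, confounder loadings and LODs.

    Defaults reproduce realistic marginals: geometric-mean blood lead near
    3 µg/dL with ~8% of draws below the 1.0 µg/dL LOD, geometric-mean
    standardized cadmium near 0.36 µg/g, correlation ~0.3 between the two
    metals.  ``*_age``, ``*_male`` and ``*_smoking`` tilt the exposures with
    the covariates that also drive mortality, creating genuine confounding.
    """

    lead_log2_mean: float = 1.57
    lead_log2_sd: float = 0.95
    cadmium_log2_mean: float = -1.47
    cadmium_log2_sd: float = 1.40
    correlation: float = 0.30
    creatinine_log2_mean: float = 0.14  # geometric mean ~1.1 g/L
    creatinine_log2_sd: float = 0.80
    lead_age: float = 0.012  # added to log2 lead per year of age above 48
    lead_male: float = 0.70
    lead_smoking_current: float = 0.55
    cadmium_age: float = 0.020
    cadmium_male: float = -0.35
    cadmium_smoking_current: float = 0.75
    lead_lod: float = 1.0  # µg/dL
    cadmium_lod_ugL: float = 0.03  # µg/L, applied to the unstandardized value


@dataclass
class CovariateParams:
    """Baseline covariate distributions (survey-like defaults)."""

    age_mean: float = 48.0
    age_sd: float = 18.1
    age_min: float = 20.0
    age_max: float = 90.0
    p_male: float = 0.471
    smoking_probs: tuple[float, float, float] = (0.476, 0.313, 0.211)  # never/current/former
    bmi_mean: float = 26.6
    bmi_sd: float = 5.2
    race_probs: tuple[float, float, float, float] = (0.55, 0.18, 0.22, 0.05)
    poverty_probs: tuple[float, float, float] = (0.34, 0.33, 0.33)
    education_mean: float = 11.5
    education_sd: float = 3.5
    p_metro: float = 0.48
    activity_probs: tuple[float, float, float] = (0.205, 0.356, 0.439)  # none/low/high
    diet_mean: float = 0.0
    diet_sd: float = 1.0


@dataclass
class CensoringParams:
    """Administrative censoring from the enrollment-entry spread.

    Censoring times are uniform on [min_years, max_years], capped at the
    horizon; censoring acts at period boundaries (a subject is at risk for
    every whole period begun before the cutoff), matching the discrete-time
    likelihood.  ``dropout_hazard`` adds optional independent per-period
    random loss to follow-up for robustness experiments (0 = none, the
    default: participants without a death record are treated as alive
    throughout).
    """

    min_years: float = 21.0
    max_years: float = 27.0
    dropout_hazard: float = 0.0


@dataclass
class WeightParams:
    """Log-normal survey weights; optionally covariate-driven.

    With ``covariate_dependent`` False (default) the weights are independent
    of everything else, so weighted and unweighted estimands coincide.
    Setting it True tilts log-weights by age and sex to exercise
    weighted/unweighted divergence.
    """

    log_mean: float = 0.0
    log_sd: float = 0.70
    covariate_dependent: bool = False
    age_loading: float = -0.012
    male_loading: float = 0.15


#: Covariate encodings available to the true hazard linear predictor.
#: Continuous covariates enter uncentered, so the fitted model's
#: parameterization matches the generator's term for term.
TRUTH_TERMS = (
    "intercept",
    "t",
    "t2",
    "log2_lead",
    "log2_cadmium",
    "log2_lead_t",
    "log2_cadmium_t",
    "age",
    "sex_male",
    "smoking_current",
    "smoking_former",
    "bmi",
    "education_years",
    "diet_index",
    "residence_metro",
    "activity_none",
    "activity_low",
    # hinge terms give a threshold dose-response: the coefficient multiplies
    # max(0, log2(exposure) - configured log2 mean), zero effect below it
    "log2_lead_hinge",
    "log2_cadmium_hinge",
)

# Calibrated once so the default cohort reproduces the study margins:
# ~36% of subjects dead over follow-up with ~30% / ~22% / ~48% of deaths
# from CVD / cancer / other, and median follow-up ~22.5 years under the
# default censoring spread.
DEFAULT_TRUE_COEFFICIENTS: dict[str, dict[str, float]] = {
    "cvd": {
        "intercept": -11.87, "t": 0.060, "t2": 0.0,
        "log2_lead": 0.10, "log2_cadmium": 0.05,
        "log2_lead_t": 0.003, "log2_cadmium_t": 0.002,
        "age": 0.095, "sex_male": 0.45,
        "smoking_current": 0.55, "smoking_former": 0.20,
        "bmi": 0.020, "education_years": -0.030, "diet_index": -0.10,
    },
    "cancer": {
        "intercept": -11.01, "t": 0.040, "t2": 0.0,
        "log2_lead": 0.12, "log2_cadmium": 0.08,
        "log2_lead_t": 0.0, "log2_cadmium_t": 0.0,
        "age": 0.085, "sex_male": 0.30,
        "smoking_current": 0.70, "smoking_former": 0.30,
        "bmi": 0.005, "education_years": -0.020, "diet_index": -0.08,
    },
    "other": {
        "intercept": -9.71, "t": 0.050, "t2": 0.0,
        "log2_lead": 0.04, "log2_cadmium": 0.10,
        "log2_lead_t": 0.001, "log2_cadmium_t": 0.002,
        "age": 0.090, "sex_male": 0.25,
        "smoking_current": 0.45, "smoking_former": 0.15,
        "bmi": -0.010, "education_years": -0.040, "diet_index": -0.05,
    },
}


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic cohort."""

    n_subjects: int = 14311
    horizon: int = 27
    seed: int = 0
    exposure_params: ExposureParams = field(default_factory=ExposureParams)
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    true_coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_TRUE_COEFFICIENTS.items()}
    )
    censoring_params: CensoringParams = field(default_factory=CensoringParams)
    weight_params: WeightParams = field(default_factory=WeightParams)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.horizon < 1:
            raise ConfigurationError("horizon must be >= 1")
        ep = self.exposure_params
        if not -1.0 < ep.correlation < 1.0:
            raise ConfigurationError("exposure_params.correlation must lie in (-1, 1)")
        for name in ("lead_log2_sd", "cadmium_log2_sd", "creatinine_log2_sd"):
            if getattr(ep, name) <= 0:
                raise ConfigurationError(f"exposure_params.{name} must be > 0")
        cp = self.covariate_params
        for name in ("age_sd", "bmi_sd", "education_sd", "diet_sd"):
            if getattr(cp, name) <= 0:
                raise ConfigurationError(f"covariate_params.{name} must be > 0")
        for name in ("smoking_probs", "race_probs", "poverty_probs", "activity_probs"):
            p = np.asarray(getattr(cp, name), dtype=float)
            if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ConfigurationError(f"covariate_params.{name} must be a probability vector")
        if not 0.0 <= cp.p_male <= 1.0:
            raise ConfigurationError("covariate_params.p_male must lie in [0, 1]")
        cs = self.censoring_params
        if not 0 < cs.min_years <= cs.max_years:
            raise ConfigurationError("censoring_params: need 0 < min_years <= max_years")
        if not 0.0 <= cs.dropout_hazard < 1.0:
            raise ConfigurationError("censoring_params.dropout_hazard must lie in [0, 1)")
        if self.weight_params.log_sd < 0:
            raise ConfigurationError("weight_params.log_sd must be >= 0")
        for cause, coeffs in self.true_coefficients.items():
            if cause not in CAUSES:
                raise ConfigurationError(f"true_coefficients: unknown cause {cause!r}")
            for term in coeffs:
                if term not in TRUTH_TERMS:
                    raise ConfigurationError(
                        f"true_coefficients[{cause!r}]: unknown term {term!r}"
                    )

    def to_dict(self) -> dict:
        return asdict(self)


def study_config(n_subjects: int = 14311, seed: int = 0, **overrides) -> GeneratorConfig:
    """The default study-like configuration (documented emulation targets)."""
    return GeneratorConfig(n_subjects=n_subjects, seed=seed, **overrides)


def null_exposure_config(n_subjects: int = 5000, seed: int = 0) -> GeneratorConfig:
    """Config with zero exposure coefficients and exposure-independent covariates.

    Under this null the metals neither affect mortality nor share causes
    with it (confounder loadings also zeroed), so death is independent of
    exposure both conditionally and marginally.
    """
    coeffs = {c: dict(v) for c, v in DEFAULT_TRUE_COEFFICIENTS.items()}
    for c in coeffs:
        for term in ("log2_lead", "log2_cadmium", "log2_lead_t", "log2_cadmium_t"):
            coeffs[c][term] = 0.0
    ep = ExposureParams(
        lead_age=0.0, lead_male=0.0, lead_smoking_current=0.0,
        cadmium_age=0.0, cadmium_male=0.0, cadmium_smoking_current=0.0,
    )
    return GeneratorConfig(
        n_subjects=n_subjects, seed=seed,
        true_coefficients=coeffs, exposure_params=ep,
    )


def single_cause_config(
    n_subjects: int = 5000, seed: int = 0, cause: str = "other", **coeff_overrides
) -> GeneratorConfig:
    """Config with a single active cause (all-cause fit correctly specified)."""
    base = dict(DEFAULT_TRUE_COEFFICIENTS[cause])
    base["intercept"] = coeff_overrides.pop("intercept", -9.2)
    base.update(coeff_overrides)
    return GeneratorConfig(
        n_subjects=n_subjects, seed=seed, true_coefficients={cause: base}
    )


# ---------------------------------------------------------------------------
# Simulation internals
# ---------------------------------------------------------------------------


def _draw_covariates(rng: np.random.Generator, n: int, cp: CovariateParams) -> pd.DataFrame:
    a = (cp.age_min - cp.age_mean) / cp.age_sd
    b = (cp.age_max - cp.age_mean) / cp.age_sd
    age = truncnorm.rvs(a, b, loc=cp.age_mean, scale=cp.age_sd, size=n, random_state=rng)
    sex = np.where(rng.random(n) < cp.p_male, "male", "female")
    smoking = rng.choice(["never", "current", "former"], size=n, p=cp.smoking_probs)
    bmi = np.clip(rng.normal(cp.bmi_mean, cp.bmi_sd, n), 14.0, 60.0)
    race = rng.choice(
        ["white", "black", "mexican_american", "other"], size=n, p=cp.race_probs
    )
    poverty = rng.choice([1, 2, 3], size=n, p=cp.poverty_probs)
    education = np.clip(rng.normal(cp.education_mean, cp.education_sd, n), 0.0, 22.0)
    residence = np.where(rng.random(n) < cp.p_metro, "metro", "non_metro")
    activity = rng.choice(["none", "low", "high"], size=n, p=cp.activity_probs)
    diet = rng.normal(cp.diet_mean, cp.diet_sd, n)
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "race_ethnicity": race,
            "poverty_tertile": poverty,
            "education_years": education,
            "residence": residence,
            "smoking": smoking,
            "bmi": bmi,
            "physical_activity": activity,
            "diet_index": diet,
        }
    )


def _draw_exposures(rng: np.random.Generator, cov: pd.DataFrame, ep: ExposureParams):
    """Correlated log2-scale biomarkers with confounder loadings and LODs.

    Returns post-imputation blood lead (µg/dL), standardized cadmium (µg/g),
    creatinine (g/L), raw urinary cadmium (µg/L) and below-LOD flags.  The
    confounder loadings shift the log2 means; the stated log2 SDs are the
    residual spreads.
    """
    n = len(cov)
    corr = np.array([[1.0, ep.correlation], [ep.correlation, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], corr, size=n)
    age_c = cov["age"].to_numpy() - 48.0
    male = (cov["sex"].to_numpy() == "male").astype(float)
    current = (cov["smoking"].to_numpy() == "current").astype(float)

    log2_pb = (
        ep.lead_log2_mean
        + ep.lead_age * age_c
        + ep.lead_male * (male - 0.5)
        + ep.lead_smoking_current * (current - 0.3)
        + ep.lead_log2_sd * z[:, 0]
    )
    log2_cd = (
        ep.cadmium_log2_mean
        + ep.cadmium_age * age_c
        + ep.cadmium_male * (male - 0.5)
        + ep.cadmium_smoking_current * (current - 0.3)
        + ep.cadmium_log2_sd * z[:, 1]
    )
    lead_raw = 2.0 ** log2_pb
    cadmium_std_raw = 2.0 ** log2_cd  # µg/g creatinine
    creatinine = 2.0 ** rng.normal(ep.creatinine_log2_mean, ep.creatinine_log2_sd, n)
    cadmium_ugL_raw = cadmium_std_raw * creatinine

    lead_below = lead_raw < ep.lead_lod
    lead = impute_below_lod(lead_raw, ep.lead_lod, lead_below)
    cadmium_below = cadmium_ugL_raw < ep.cadmium_lod_ugL
    cadmium_ugL = impute_below_lod(cadmium_ugL_raw, ep.cadmium_lod_ugL, cadmium_below)
    cadmium_std = cadmium_ugL / creatinine
    return lead, cadmium_std, creatinine, cadmium_ugL, lead_below, cadmium_below


def _covariate_terms(cov: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "age": cov["age"].to_numpy(dtype=float),
        "sex_male": (cov["sex"].to_numpy() == "male").astype(float),
        "smoking_current": (cov["smoking"].to_numpy() == "current").astype(float),
        "smoking_former": (cov["smoking"].to_numpy() == "former").astype(float),
        "bmi": cov["bmi"].to_numpy(dtype=float),
        "education_years": cov["education_years"].to_numpy(dtype=float),
        "diet_index": cov["diet_index"].to_numpy(dtype=float),
        "residence_metro": (cov["residence"].to_numpy() == "metro").astype(float),
        "activity_none": (cov["physical_activity"].to_numpy() == "none").astype(float),
        "activity_low": (cov["physical_activity"].to_numpy() == "low").astype(float),
    }


def _static_lp(coeffs: dict[str, float], log2_pb, log2_cd, terms, ep=None) -> np.ndarray:
    """Time-invariant part of the true linear predictor for one cause."""
    lp = np.full(len(log2_pb), coeffs.get("intercept", 0.0), dtype=float)
    lp += coeffs.get("log2_lead", 0.0) * log2_pb
    lp += coeffs.get("log2_cadmium", 0.0) * log2_cd
    if ep is not None:
        c = coeffs.get("log2_lead_hinge", 0.0)
        if c:
            lp += c * np.maximum(0.0, log2_pb - ep.lead_log2_mean)
        c = coeffs.get("log2_cadmium_hinge", 0.0)
        if c:
            lp += c * np.maximum(0.0, log2_cd - ep.cadmium_log2_mean)
    for term, x in terms.items():
        c = coeffs.get(term, 0.0)
        if c:
            lp += c * x
    return lp


def _time_lp(coeffs: dict[str, float], log2_pb, log2_cd, t: int) -> float | np.ndarray:
    add = coeffs.get("t", 0.0) * t + coeffs.get("t2", 0.0) * t * t
    slope = coeffs.get("log2_lead_t", 0.0) * log2_pb + coeffs.get(
        "log2_cadmium_t", 0.0
    ) * log2_cd
    return add + slope * t


def _simulate_deaths(rng, causes, static_lps, slopes_fn, horizon, at_risk_periods=None):
    """Run the period-by-period competing-cause mechanism.

    ``static_lps``: cause -> (n,) static linear predictor; ``slopes_fn``:
    cause, t -> additive time contribution (scalar or (n,)).  Returns
    (death_period, cause_index) with 0 meaning no death within
    ``at_risk_periods`` (defaults to the full horizon for everyone).
    Competing causes firing in the same period are resolved by a uniform
    pick, a symmetric rule.
    """
    n = len(next(iter(static_lps.values())))
    if at_risk_periods is None:
        at_risk = np.full(n, horizon, dtype=int)
    else:
        at_risk = at_risk_periods
    death_period = np.zeros(n, dtype=int)
    death_cause = np.full(n, -1, dtype=int)
    alive = np.ones(n, dtype=bool)
    for t in range(1, horizon + 1):
        idx = np.flatnonzero(alive & (at_risk >= t))
        if idx.size == 0:
            break
        fired = np.zeros((idx.size, len(causes)), dtype=bool)
        for j, c in enumerate(causes):
            h = expit(static_lps[c][idx] + slopes_fn(c, t, idx))
            fired[:, j] = rng.random(idx.size) < h
        any_fired = fired.any(axis=1)
        if any_fired.any():
            who = idx[any_fired]
            f = fired[any_fired]
            # uniform pick among causes that fired in the same period
            u = rng.random((len(who), len(causes)))
            u[~f] = np.inf
            chosen = np.argmin(u, axis=1)
            death_period[who] = t
            death_cause[who] = chosen
            alive[who] = False
    return death_period, death_cause


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a seeded synthetic baseline cohort.

    Deterministic given ``config.seed``.  Returns one row per participant in
    the canonical column layout (see :data:`gcompsurv.prep.CANONICAL_COLUMNS`)
    plus ``lead_below_lod`` / ``cadmium_below_lod`` flags.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    cov = _draw_covariates(rng, n, config.covariate_params)
    lead, cadmium_std, creatinine, cadmium_ugL, pb_lod, cd_lod = _draw_exposures(
        rng, cov, config.exposure_params
    )
    log2_pb = np.log2(lead)
    log2_cd = np.log2(cadmium_std)
    terms = _covariate_terms(cov)

    causes = sorted(config.true_coefficients)
    static_lps = {
        c: _static_lp(config.true_coefficients[c], log2_pb, log2_cd, terms,
                      config.exposure_params)
        for c in causes
    }

    def slopes(c, t, idx):
        co = config.true_coefficients[c]
        add = co.get("t", 0.0) * t + co.get("t2", 0.0) * t * t
        s = co.get("log2_lead_t", 0.0) * log2_pb[idx] + co.get(
            "log2_cadmium_t", 0.0
        ) * log2_cd[idx]
        return add + s * t

    cs = config.censoring_params
    censor_time = np.minimum(
        rng.uniform(cs.min_years, cs.max_years, n), float(config.horizon)
    )
    at_risk = np.ceil(censor_time).astype(int)
    if cs.dropout_hazard > 0:
        dropout_period = rng.geometric(cs.dropout_hazard, n)
        drop_sooner = dropout_period < at_risk
        at_risk = np.minimum(at_risk, dropout_period)
        censor_time = np.where(drop_sooner, dropout_period.astype(float), censor_time)

    death_period, death_cause = _simulate_deaths(
        rng, causes, static_lps, slopes, config.horizon, at_risk
    )
    dead = death_period > 0
    frac = rng.uniform(0.0, 1.0, n)  # death occurs partway through its period
    followup = np.where(dead, death_period - 1 + frac, np.minimum(censor_time, at_risk))
    followup = np.maximum(followup, 1e-6)

    wp = config.weight_params
    logw = rng.normal(wp.log_mean, wp.log_sd, n)
    if wp.covariate_dependent:
        logw = (
            logw
            + wp.age_loading * (cov["age"].to_numpy() - 48.0)
            + wp.male_loading * (cov["sex"].to_numpy() == "male")
        )
    weight = np.exp(logw)

    cause_label = np.array(["none"] * n, dtype=object)
    cause_label[dead] = np.array(causes, dtype=object)[death_cause[dead]]

    out = pd.DataFrame({"id": np.arange(1, n + 1)})
    out["blood_lead"] = lead
    out["urinary_cadmium"] = cadmium_ugL
    out["urinary_creatinine"] = creatinine
    out["cadmium_std"] = cadmium_std
    out["lead_below_lod"] = pb_lod
    out["cadmium_below_lod"] = cd_lod
    for col in cov.columns:
        out[col] = cov[col].to_numpy()
    out["weight"] = weight
    out["followup_years"] = followup
    out["status"] = np.where(dead, "dead", "alive")
    out["cause"] = cause_label
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo truth oracle
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """True marginal counterfactual risks for an intervention pair.

    ``risk_low`` / ``risk_high`` are per-period cumulative risks for the
    target cause under the two interventions; ``rd`` / ``rr`` their
    contrasts; ``mc_se`` the per-curve binomial Monte-Carlo standard errors.
    ``convention`` records whether competing causes were switched off
    ("net", the estimand of the censor-at-competing-death estimator) or
    active ("cif", crude cumulative incidence); for all-cause risk the two
    coincide.
    """

    cause: str
    low_label: str
    high_label: str
    risk_low: np.ndarray
    risk_high: np.ndarray
    rd: np.ndarray
    rr: np.ndarray
    mc_reps: int
    mc_se_low: np.ndarray
    mc_se_high: np.ndarray
    convention: str = "net"

    @property
    def horizon(self) -> int:
        return len(self.rd)

    def rd_se(self) -> np.ndarray:
        return np.sqrt(self.mc_se_low**2 + self.mc_se_high**2)

    def to_dict(self) -> dict:
        return {
            "cause": self.cause,
            "low": self.low_label,
            "high": self.high_label,
            "convention": self.convention,
            "mc_reps": self.mc_reps,
            "risk_low": self.risk_low.tolist(),
            "risk_high": self.risk_high.tolist(),
            "rd": self.rd.tolist(),
            "rr": self.rr.tolist(),
            "mc_se_low": self.mc_se_low.tolist(),
            "mc_se_high": self.mc_se_high.tolist(),
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _truth_one_intervention(
    rng, config, intervention, cause, mc_reps, anchors, convention
):
    cov = _draw_covariates(rng, mc_reps, config.covariate_params)
    # intervened exposures; a non-targeted metal keeps its natural draw
    lead, cadmium_std, *_ = _draw_exposures(rng, cov, config.exposure_params)
    targets = intervention.targets()
    if "lead" in targets:
        lead = np.full(mc_reps, intervention.resolve_value("lead", anchors))
    if "cadmium" in targets:
        cadmium_std = np.full(mc_reps, intervention.resolve_value("cadmium", anchors))
    log2_pb, log2_cd = np.log2(lead), np.log2(cadmium_std)
    terms = _covariate_terms(cov)

    all_causes = sorted(config.true_coefficients)
    if cause == "all" or convention == "cif":
        causes = all_causes
    else:
        if cause not in config.true_coefficients:
            raise InputError(f"cause {cause!r} not present in true_coefficients")
        causes = [cause]  # net risk: competing hazards switched off

    static_lps = {
        c: _static_lp(config.true_coefficients[c], log2_pb, log2_cd, terms,
                      config.exposure_params)
        for c in causes
    }

    def slopes(c, t, idx):
        co = config.true_coefficients[c]
        add = co.get("t", 0.0) * t + co.get("t2", 0.0) * t * t
        s = co.get("log2_lead_t", 0.0) * log2_pb[idx] + co.get(
            "log2_cadmium_t", 0.0
        ) * log2_cd[idx]
        return add + s * t

    death_period, death_cause = _simulate_deaths(
        rng, causes, static_lps, slopes, config.horizon
    )
    if cause == "all":
        counted = death_period > 0
    else:
        ci = causes.index(cause)
        counted = (death_period > 0) & (death_cause == ci)
    risk = np.zeros(config.horizon)
    for t in range(1, config.horizon + 1):
        risk[t - 1] = np.mean(counted & (death_period <= t))
    se = np.sqrt(np.maximum(risk * (1 - risk), 1e-300) / mc_reps)
    return risk, se


def compute_truth(
    config: GeneratorConfig,
    interventions,
    cause: str = "all",
    mc_reps: int = 10**6,
    cohort: pd.DataFrame | None = None,
    anchors=None,
    convention: str = "net",
    min_reps: int = 10**4,
) -> SyntheticTruth:
    """Monte-Carlo the true counterfactual risks under an intervention pair.

    Simulates ``mc_reps`` fresh counterfactual subjects per intervention with
    the targeted exposure forced to the intervention value and accumulates
    cumulative incidence by period.  ``interventions`` is the (low, high)
    pair.  Percentile/quartile rules need ``anchors`` (or a ``cohort`` from
    which anchors are computed).  Standard errors are binomial.
    """
    if mc_reps < min_reps:
        raise ConfigurationError(f"mc_reps must be >= {min_reps}")
    if convention not in ("net", "cif"):
        raise ConfigurationError(f"unknown competing-risk convention {convention!r}")
    low, high = interventions
    if anchors is None and cohort is not None:
        from .prep import transform_exposures

        _, anchors = transform_exposures(cohort)
    for ispec in (low, high):
        if ispec.rule != "value" and anchors is None:
            raise InputError(
                f"intervention {ispec.label!r} uses rule {ispec.rule!r} but no "
                "cohort/anchors were supplied to resolve the percentile"
            )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20 + 7]))
    risk_low, se_low = _truth_one_intervention(
        rng, config, low, cause, mc_reps, anchors, convention
    )
    same = low.targets() == high.targets() and all(
        low.resolve_value(e, anchors) == high.resolve_value(e, anchors)
        for e in low.targets()
    )
    if same:
        # identical assignments define identical counterfactual worlds:
        # reuse the simulation so RD is exactly 0 and RR exactly 1
        risk_high, se_high = risk_low.copy(), se_low.copy()
    else:
        risk_high, se_high = _truth_one_intervention(
            rng, config, high, cause, mc_reps, anchors, convention
        )
    rd = risk_high - risk_low
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(risk_low > 0, risk_high / np.where(risk_low > 0, risk_low, 1.0), np.nan)
    return SyntheticTruth(
        cause=cause,
        low_label=low.label,
        high_label=high.label,
        risk_low=risk_low,
        risk_high=risk_high,
        rd=rd,
        rr=rr,
        mc_reps=mc_reps,
        mc_se_low=se_low,
        mc_se_high=se_high,
        convention=convention,
    )
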