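"""Bootstrap confidence intervals and stratum-heterogeneity tests.

Confidence intervals for the g-computation effect estimates come from the
nonparametric bootstrap: participants (with all their person-periods) are
resampled with replacement M times (M = 200 by default), the whole
transform -> fit -> g-compute pipeline is re-run per replicate, and the
2.5th / 97.5th percentiles of the replicate estimates bound the interval at
every period.  Percentile anchors for the interventions are re-estimated
inside each replicate by default (fully honest bootstrap); a fixed-anchor
mode is available.

Heterogeneity between strata (men vs women, age < 50 vs >= 50) is assessed
with a two-sample Wald test, z = (theta_A - theta_B) / sqrt(SE_A^2 +
SE_B^2), on the exposure log-odds coefficient evaluated at the
mid-follow-up period (beta_1 + beta_3 * t_bar); p < 0.1 flags significant
heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.stats import norm

from .errors import ConfigurationError, InputError, NonConvergenceError
from .gformula import EffectEstimate, InterventionSpec, estimate_effects_multi
from .hazard import ModelSpec, fit_pooled_logistic
from .prep import expand_person_periods, log2_column, transform_exposures


@dataclass
class BootstrapConfig:
    """Nonparametric bootstrap settings.

    ``replicates`` M >= 2 (200 by default); ``percentiles`` the CI bounds
    (2.5, 97.5); ``workers`` > 1 parallelizes replicates with joblib without
    changing the resample streams (each replicate owns a child seed spawned
    from ``seed``); ``reestimate_anchors`` re-computes intervention anchors
    within each replicate; ``weighted_resampling`` draws participants with
    probability proportional to their survey weight (sensitivity mode —
    default is simple resampling with weights carried along).
    """

    replicates: int = 200
    seed: int = 0
    percentiles: tuple[float, float] = (2.5, 97.5)
    workers: int = 1
    reestimate_anchors: bool = True
    weighted_resampling: bool = False
    max_failure_fraction: float = 0.05

    def __post_init__(self):
        if self.replicates < 2:
            raise ConfigurationError("replicates must be >= 2")
        lo, hi = self.percentiles
        if not (0 < lo < hi < 100):
            raise ConfigurationError("percentiles must be ordered within (0, 100)")


@dataclass
class BootstrapResult:
    """Point estimate with percentile CIs plus replicate diagnostics."""

    effect: EffectEstimate
    rd_replicates: np.ndarray  # (M_ok, T)
    rr_replicates: np.ndarray
    n_requested: int
    n_failed: int
    unstable: bool  # more than max_failure_fraction of replicates failed

    @property
    def n_completed(self) -> int:
        return self.n_requested - self.n_failed

    def rd_se(self) -> np.ndarray:
        return self.rd_replicates.std(axis=0, ddof=1)


def _one_replicate(cohort, spec, pairs, horizon, discretization, anchors, seed,
                   weighted_resampling, start_params):
    rng = np.random.default_rng(seed)
    n = len(cohort)
    if weighted_resampling:
        p = cohort["weight"].to_numpy(dtype=float)
        idx = rng.choice(n, size=n, replace=True, p=p / p.sum())
    else:
        idx = rng.integers(0, n, size=n)
    resampled = cohort.iloc[idx].reset_index(drop=True)
    resampled["id"] = np.arange(1, n + 1)  # duplicates become distinct subjects
    try:
        effects, _, _ = estimate_effects_multi(
            resampled, spec, pairs, horizon,
            anchors=anchors, discretization=discretization,
            start_params=start_params,
        )
        return [(e.rd, e.rr) for e in effects]
    except (NonConvergenceError, InputError):
        return None


def bootstrap_effects_pairs(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    pairs,
    horizon: int,
    bc: BootstrapConfig | None = None,
    discretization: float = 1.0,
) -> list[BootstrapResult]:
    """Bootstrap several intervention pairs off one hazard fit per replicate.

    Resamples participants with replacement; every resampled participant
    carries their full follow-up (person-periods travel together because the
    expansion is re-run on the resampled baseline table).  Replicate fits
    are warm-started at the full-cohort coefficients.  Replicate failures
    (non-convergence) are excluded with a count; a result is flagged
    unstable when more than ``max_failure_fraction`` fail.  Same seed ->
    identical resample streams regardless of worker count (each replicate
    owns a child seed spawned from ``bc.seed``).
    """
    bc = bc or BootstrapConfig()
    points, model, anchors = estimate_effects_multi(
        cohort, spec, pairs, horizon, discretization=discretization
    )
    fixed_anchors = None if bc.reestimate_anchors else anchors
    # carry only the columns the pipeline needs through the resamples
    needed = [
        "id", "weight", "followup_years", "status", "cause",
        "blood_lead", "urinary_cadmium", "urinary_creatinine", "cadmium_std",
        *spec.covariates,
    ]
    cohort = cohort[[c for c in dict.fromkeys(needed) if c in cohort.columns]]
    seeds = [
        s.generate_state(1)[0] % (2**31)
        for s in np.random.SeedSequence(bc.seed).spawn(bc.replicates)
    ]

    args = (cohort, spec, pairs, horizon, discretization, fixed_anchors)
    if bc.workers > 1:
        results = Parallel(n_jobs=bc.workers)(
            delayed(_one_replicate)(*args, s, bc.weighted_resampling, model.params)
            for s in seeds
        )
    else:
        results = [
            _one_replicate(*args, s, bc.weighted_resampling, model.params)
            for s in seeds
        ]

    ok = [r for r in results if r is not None]
    n_failed = bc.replicates - len(ok)
    if not ok:
        raise NonConvergenceError("all bootstrap replicates failed")
    out = []
    lo_p, hi_p = bc.percentiles
    for k, point in enumerate(points):
        rd_mat = np.vstack([r[k][0] for r in ok])
        rr_mat = np.vstack([r[k][1] for r in ok])
        point.rd_lo = np.percentile(rd_mat, lo_p, axis=0)
        point.rd_hi = np.percentile(rd_mat, hi_p, axis=0)
        with np.errstate(invalid="ignore"):
            point.rr_lo = np.nanpercentile(rr_mat, lo_p, axis=0)
            point.rr_hi = np.nanpercentile(rr_mat, hi_p, axis=0)
        out.append(
            BootstrapResult(
                effect=point,
                rd_replicates=rd_mat,
                rr_replicates=rr_mat,
                n_requested=bc.replicates,
                n_failed=n_failed,
                unstable=(n_failed > bc.max_failure_fraction * bc.replicates),
            )
        )
    return out


def bootstrap_effects(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    low: InterventionSpec,
    high: InterventionSpec,
    horizon: int,
    bc: BootstrapConfig | None = None,
    discretization: float = 1.0,
) -> BootstrapResult:
    """Point estimate with bootstrap percentile CIs for RD(t) and RR(t).

    Single-pair convenience wrapper over :func:`bootstrap_effects_pairs`;
    CI at each period t is the empirical 2.5th/97.5th percentile of the
    replicate estimates.
    """
    return bootstrap_effects_pairs(
        cohort, spec, [(low, high)], horizon, bc, discretization
    )[0]


# ---------------------------------------------------------------------------
# Wald heterogeneity across strata
# ---------------------------------------------------------------------------


@dataclass
class HeterogeneityResult:
    """Two-sample Wald comparison of stratum-specific estimates.

    ``scale`` records what the estimates are (e.g. exposure log-odds
    coefficient at the mid-follow-up period, or RD at the horizon).
    Significance is declared at alpha = 0.1.
    """

    label_a: str
    label_b: str
    estimate_a: float
    estimate_b: float
    se_a: float
    se_b: float
    z: float
    p_value: float
    significant: bool
    scale: str = "log-odds"
    alpha: float = 0.1


def wald_heterogeneity(
    estimate_a: float,
    se_a: float,
    estimate_b: float,
    se_b: float,
    label_a: str = "A",
    label_b: str = "B",
    alpha: float = 0.1,
    scale: str = "log-odds",
) -> HeterogeneityResult:
    """Wald z-test for a difference between two independent stratum estimates.

    z = (theta_A - theta_B) / sqrt(SE_A^2 + SE_B^2), two-sided normal p.
    """
    if not (se_a > 0 and se_b > 0):
        raise InputError("stratum standard errors must be > 0")
    z = (estimate_a - estimate_b) / np.hypot(se_a, se_b)
    p = float(2.0 * norm.sf(abs(z)))
    return HeterogeneityResult(
        label_a=label_a,
        label_b=label_b,
        estimate_a=float(estimate_a),
        estimate_b=float(estimate_b),
        se_a=float(se_a),
        se_b=float(se_b),
        z=float(z),
        p_value=p,
        significant=p < alpha,
        scale=scale,
        alpha=alpha,
    )


def _stratum_exposure_effect(cohort, spec, exposure, discretization):
    """Exposure log-odds coefficient beta1 + beta3 * t_bar with its SE."""
    cohort, anchors = transform_exposures(cohort, weighted=spec.weighted)
    pp = expand_person_periods(cohort, cause=spec.cause, years_per_period=discretization)
    model = fit_pooled_logistic(pp, spec, anchors)
    names = model.column_names
    col = log2_column(exposure)
    i1 = names.index(col)
    contrast = np.zeros(len(names))
    contrast[i1] = 1.0
    tbar = float(pp["period"].mean())
    if spec.include_time_products:
        contrast[names.index(f"{col}:t")] = tbar
    est = float(contrast @ model.params)
    se = float(np.sqrt(contrast @ model.cov @ contrast))
    return est, se


def stratified_heterogeneity(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    strata: str,
    exposure: str = "lead",
    discretization: float = 1.0,
    alpha: float = 0.1,
) -> HeterogeneityResult:
    """Fit the hazard model within each stratum and Wald-test the exposure effect.

    ``strata`` is either a two-level column name (e.g. ``sex``) or the
    special value ``"age50"`` splitting at age 50 (< 50 vs >= 50).  The
    compared quantity is the exposure log-odds coefficient at the
    mid-follow-up period; SEs are the model (sandwich for weighted fits)
    standard errors.
    """
    if exposure not in spec.exposures:
        raise ConfigurationError(
            f"strata exposure {exposure!r} is not in the model spec "
            f"(exposures={spec.exposures})"
        )
    work = cohort.copy()
    if strata == "age50":
        work["_stratum"] = np.where(work["age"] < 50, "<50", ">=50")
        col = "_stratum"
    else:
        col = strata
    levels = sorted(pd.unique(work[col]).tolist())
    if len(levels) != 2:
        raise ConfigurationError(
            f"strata column {strata!r} must have exactly 2 levels, got {levels}"
        )
    ests = {}
    for lev in levels:
        sub = work[work[col] == lev].reset_index(drop=True)
        ests[lev] = _stratum_exposure_effect(sub, spec, exposure, discretization)
    (la, (ea, sa)), (lb, (eb, sb)) = ests.items()
    return wald_heterogeneity(
        ea, sa, eb, sb, label_a=str(la), label_b=str(lb), alpha=alpha,
        scale=f"log-odds({exposure}) at mid-follow-up",
    )
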