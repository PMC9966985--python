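"""G-computation: counterfactual risk curves and their contrasts.

The parametric g-formula standardizes a fitted discrete-time hazard model
over the cohort's covariate distribution.  For an intervention that forces
every subject's exposure to a rule-determined value, each subject's hazard
path ĥ_i(t) is predicted from the fitted model with the intervened
exposure, the subject-level cumulative risk is

    R̂_i(T) = 1 − Π_{t=1..T} (1 − ĥ_i(t)),

and the marginal risk is the (survey-weighted) average of R̂_i(T) over the
cohort.  Two interventions are contrasted as a risk difference
RD(t) = R̂_high(t) − R̂_low(t) and a risk ratio RR(t) = R̂_high(t)/R̂_low(t);
the horizon value (t = 27 by default) is the headline summary.  RR > 1
means higher mortality under the high-exposure assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .prep import (
    exposure_column,
    expand_person_periods,
    log2_column,
    quartile_column,
    transform_exposures,
)
from .hazard import FittedHazardModel, ModelSpec, fit_pooled_logistic

RULES = ("value", "percentile", "quartile")


@dataclass(frozen=True)
class InterventionSpec:
    """A rule assigning every subject a counterfactual exposure.

    ``exposure`` is ``"lead"``, ``"cadmium"`` or ``"both"``.  Rules:

    - ``value``: set the concentration to ``value`` (natural units).
    - ``percentile``: set it to the given percentile of the observed
      (optionally survey-weighted) distribution, resolved from the cohort's
      :class:`~gcompsurv.prep.ExposureAnchors` (5, 50 and 95 supported).
    - ``quartile``: place every subject in quartile ``quartile``.  Against a
      quartile-coded hazard model the quartile indicator itself is set
      (``dummy`` mode, the default for quartile analyses); against a
      continuous model each subject receives the within-quartile weighted
      median concentration (``value`` mode).
    """

    exposure: str = "lead"
    rule: str = "percentile"
    value: Optional[float] = None
    percentile: Optional[float] = None
    quartile: Optional[int] = None
    label: str = ""

    def __post_init__(self):
        if self.exposure not in ("lead", "cadmium", "both"):
            raise ConfigurationError(f"unknown intervention exposure {self.exposure!r}")
        if self.rule not in RULES:
            raise ConfigurationError(f"unknown intervention rule {self.rule!r}")
        if self.rule == "value" and not (self.value is not None and self.value > 0):
            raise ConfigurationError("value rule requires value > 0")
        if self.rule == "percentile" and not (
            self.percentile is not None and 0 < self.percentile < 100
        ):
            raise ConfigurationError("percentile rule requires percentile in (0, 100)")
        if self.rule == "quartile" and self.quartile not in (1, 2, 3, 4):
            raise ConfigurationError("quartile rule requires quartile in 1..4")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.rule == "value":
            return f"{self.exposure}={self.value:g}"
        if self.rule == "percentile":
            return f"{self.exposure}@p{self.percentile:g}"
        return f"{self.exposure}@Q{self.quartile}"

    def targets(self) -> tuple[str, ...]:
        return ("lead", "cadmium") if self.exposure == "both" else (self.exposure,)

    def resolve_value(self, exposure: str, anchors) -> float:
        """Concentration this rule assigns for one metal (natural units)."""
        if self.rule == "value":
            return float(self.value)
        if anchors is None or exposure not in anchors:
            raise InputError(
                f"intervention {self.label!r} needs anchors for {exposure!r} "
                "resolved from an observed cohort"
            )
        a = anchors[exposure]
        if self.rule == "percentile":
            return a.percentile(self.percentile)
        return a.quartile_medians[self.quartile - 1]


def apply_intervention(
    cohort: pd.DataFrame, spec: InterventionSpec, anchors=None
) -> pd.DataFrame:
    """Overwrite the targeted exposure column(s) with the intervention value.

    Covariates and any non-targeted metal are untouched.  The concentration,
    its log2 transform and (when anchors are available) the quartile label
    are all updated so any exposure coding in the downstream model sees the
    intervened exposure.
    """
    out = cohort.copy()
    for exposure in spec.targets():
        if spec.rule == "quartile":
            if quartile_column(exposure) in out.columns:
                out[quartile_column(exposure)] = spec.quartile
            v = spec.resolve_value(exposure, anchors) if anchors else None
            if v is not None and np.isfinite(v):
                out[exposure_column(exposure)] = v
                out[log2_column(exposure)] = np.log2(v)
        else:
            v = spec.resolve_value(exposure, anchors)
            out[exposure_column(exposure)] = v
            out[log2_column(exposure)] = np.log2(v)
            if anchors is not None and quartile_column(exposure) in out.columns:
                cuts = np.asarray(anchors[exposure].quartile_cuts)
                out[quartile_column(exposure)] = 1 + int(
                    np.searchsorted(cuts, v, side="right")
                )
    return out


@dataclass
class RiskCurve:
    """Marginal counterfactual cumulative risk per period, t = 1..horizon."""

    cause: str
    intervention: str
    risk: np.ndarray
    weighted: bool = True

    @property
    def horizon(self) -> int:
        return len(self.risk)

    def __post_init__(self):
        r = np.asarray(self.risk, dtype=float)
        if np.any(r < -1e-12) or np.any(r > 1 + 1e-12):
            raise InputError("risks must lie in [0, 1]")
        if np.any(np.diff(r) < -1e-12):
            raise InputError("cumulative risk must be non-decreasing in t")
        self.risk = np.clip(r, 0.0, 1.0)


def marginal_risk(
    model: FittedHazardModel,
    cohort: pd.DataFrame,
    horizon: int,
    weighting: str = "weighted",
    intervention_label: str = "",
) -> RiskCurve:
    """Standardized cumulative risk curve under the cohort's exposures.

    Predicts every subject's hazard at every period t = 1..horizon from the
    fitted model (the cohort will usually already carry intervened
    exposures), converts to subject-level cumulative risks via the
    discrete-time product-limit identity and averages with survey weights
    (``weighting="weighted"``) or equal weights.
    """
    if weighting not in ("weighted", "unweighted"):
        raise ConfigurationError(f"unknown weighting mode {weighting!r}")
    H = model.hazard_matrix(cohort, horizon)  # (n, T)
    risk_i = 1.0 - np.cumprod(1.0 - H, axis=1)
    if weighting == "weighted":
        w = cohort["weight"].to_numpy(dtype=float)
    else:
        w = np.ones(len(cohort))
    marginal = (w[:, None] * risk_i).sum(axis=0) / w.sum()
    return RiskCurve(
        cause=model.design.spec.cause,
        intervention=intervention_label,
        risk=marginal,
        weighted=(weighting == "weighted"),
    )


@dataclass
class EffectEstimate:
    """RD(t) and RR(t) between two counterfactual risk curves.

    ``rd[t-1] = high.risk[t-1] - low.risk[t-1]``; ``rr`` is high/low, NaN
    where the reference risk is zero (never infinity).  CI arrays are filled
    by the bootstrap; NaN until then.
    """

    cause: str
    low_label: str
    high_label: str
    low_risk: np.ndarray
    high_risk: np.ndarray
    rd: np.ndarray
    rr: np.ndarray
    rd_lo: np.ndarray = field(default=None)
    rd_hi: np.ndarray = field(default=None)
    rr_lo: np.ndarray = field(default=None)
    rr_hi: np.ndarray = field(default=None)

    def __post_init__(self):
        T = len(self.rd)
        for name in ("rd_lo", "rd_hi", "rr_lo", "rr_hi"):
            if getattr(self, name) is None:
                setattr(self, name, np.full(T, np.nan))

    @property
    def horizon(self) -> int:
        return len(self.rd)

    def at(self, t: int) -> dict:
        i = t - 1
        return {
            "t": t,
            "risk_low": float(self.low_risk[i]),
            "risk_high": float(self.high_risk[i]),
            "rd": float(self.rd[i]),
            "rr": float(self.rr[i]),
            "rd_lo": float(self.rd_lo[i]),
            "rd_hi": float(self.rd_hi[i]),
            "rr_lo": float(self.rr_lo[i]),
            "rr_hi": float(self.rr_hi[i]),
        }

    def summary(self) -> dict:
        return {"cause": self.cause, "low": self.low_label, "high": self.high_label,
                **self.at(self.horizon)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cause": self.cause,
                "low": self.low_label,
                "high": self.high_label,
                "t": np.arange(1, self.horizon + 1),
                "risk_low": self.low_risk,
                "risk_high": self.high_risk,
                "rd": self.rd,
                "rr": self.rr,
                "rd_lo": self.rd_lo,
                "rd_hi": self.rd_hi,
                "rr_lo": self.rr_lo,
                "rr_hi": self.rr_hi,
            }
        )


def contrast(low: RiskCurve, high: RiskCurve) -> EffectEstimate:
    """RD(t) and RR(t) of the high-exposure curve against the low one."""
    if low.cause != high.cause or low.horizon != high.horizon or low.weighted != high.weighted:
        raise InputError(
            "curves must share cause, horizon and weighting mode to be contrasted"
        )
    rd = high.risk - low.risk
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(low.risk > 0, high.risk / np.where(low.risk > 0, low.risk, 1.0), np.nan)
    return EffectEstimate(
        cause=low.cause,
        low_label=low.intervention,
        high_label=high.intervention,
        low_risk=low.risk.copy(),
        high_risk=high.risk.copy(),
        rd=rd,
        rr=rr,
    )


def estimate_effects_multi(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    pairs,
    horizon: int,
    anchors=None,
    discretization: float = 1.0,
    start_params=None,
):
    """One transform -> fit pass, g-computed over several intervention pairs.

    All pairs share the single fitted hazard model (and person-period
    expansion), so evaluating, say, the lead and the cadmium contrasts costs
    one fit.  Returns ``(effects, model, anchors)`` with one
    :class:`EffectEstimate` per pair.  ``start_params`` warm-starts the
    Newton iterations (used by the bootstrap).
    """
    weighting = "weighted" if spec.weighted else "unweighted"
    if anchors is None:
        cohort, anchors = transform_exposures(cohort, weighted=spec.weighted)
    else:
        # fixed-anchor mode: keep the supplied anchors for intervention
        # resolution AND for the quartile coding of the design matrix
        cohort, _ = transform_exposures(cohort, weighted=spec.weighted)
        for exposure, a in anchors.items():
            cuts = np.asarray(a.quartile_cuts)
            x = cohort[exposure_column(exposure)].to_numpy(dtype=float)
            cohort[quartile_column(exposure)] = 1 + np.searchsorted(
                cuts, x, side="right"
            )
    needed = ["id", "weight"]
    for exposure in spec.exposures:
        needed += [log2_column(exposure), quartile_column(exposure)]
    needed += list(spec.covariates)
    pp = expand_person_periods(
        cohort, cause=spec.cause, years_per_period=discretization, columns=needed
    )
    model = fit_pooled_logistic(pp, spec, anchors, start_params=start_params)
    effects = []
    for low, high in pairs:
        curves = {}
        for which, ispec in (("low", low), ("high", high)):
            cf = apply_intervention(cohort, ispec, anchors)
            curves[which] = marginal_risk(
                model, cf, horizon, weighting, intervention_label=ispec.label
            )
        effects.append(contrast(curves["low"], curves["high"]))
    return effects, model, anchors


def estimate_effect(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    low: InterventionSpec,
    high: InterventionSpec,
    horizon: int,
    anchors=None,
    discretization: float = 1.0,
    return_model: bool = False,
):
    """One full g-computation pass: transform, fit, intervene, standardize.

    When ``anchors`` is None the percentile/quartile anchors are computed
    from this cohort (the honest default inside bootstrap replicates);
    passing fixed anchors reuses the full-cohort values.  Returns the
    :class:`EffectEstimate` (and, optionally, the fitted model, anchors and
    risk curves).
    """
    effects, model, anchors = estimate_effects_multi(
        cohort, spec, [(low, high)], horizon,
        anchors=anchors, discretization=discretization,
    )
    if return_model:
        curves = {
            "low": RiskCurve(model.design.spec.cause, low.label, effects[0].low_risk,
                             weighted=spec.weighted),
            "high": RiskCurve(model.design.spec.cause, high.label, effects[0].high_risk,
                              weighted=spec.weighted),
        }
        return effects[0], model, anchors, curves
    return effects[0]
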