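"""Cohort ingestion, exposure transforms and person-period expansion.

The analysis operates on a person-level baseline cohort: one row per
participant carrying two exposure biomarkers (blood lead in µg/dL, urinary
cadmium in µg/L with urinary creatinine in g/L for dilution correction),
baseline covariates, a survey weight, follow-up time in years, vital status
and — for deaths — a cause label.  Discrete-time hazard modelling requires
the long *person-period* layout: one row per participant per year at risk,
with a binary event indicator that is 1 only in the final row of a
participant who died of the target cause.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

#: Canonical column roles.  ``column_map`` entries in a run config map
#: arbitrary input headers onto these names.
CANONICAL_COLUMNS = {
    "id": "participant identifier",
    "blood_lead": "blood lead, µg/dL",
    "urinary_cadmium": "urinary cadmium, µg/L",
    "urinary_creatinine": "urinary creatinine, g/L",
    "cadmium_std": "creatinine-standardized cadmium, µg/g (optional, precomputed)",
    "age": "age at baseline, years",
    "sex": "sex (male/female)",
    "race_ethnicity": "race-ethnicity category",
    "poverty_tertile": "poverty-income ratio tertile (1-3)",
    "education_years": "completed education, years",
    "residence": "area of residence (metro/non_metro)",
    "smoking": "smoking status (never/former/current)",
    "bmi": "body-mass index, kg/m²",
    "physical_activity": "physical activity category (none/low/high)",
    "diet_index": "diet-quality index (continuous)",
    "weight": "survey weight (> 0)",
    "followup_years": "follow-up time, years",
    "status": "vital status (alive/dead)",
    "cause": "cause of death (cvd/cancer/other/none)",
}

CAUSES = ("cvd", "cancer", "other")

DEFAULT_COVARIATES = [
    "age",
    "sex",
    "race_ethnicity",
    "poverty_tertile",
    "education_years",
    "residence",
    "smoking",
    "bmi",
    "physical_activity",
    "diet_index",
]


def impute_below_lod(value, lod: float, below_lod=None):
    """Substitute LOD/sqrt(2) for measurements below the limit of detection.

    Parameters
    ----------
    value : float or array-like
        Measured concentration(s).  Must be non-negative.
    lod : float
        Assay limit of detection (> 0), same units as ``value``.
    below_lod : bool or boolean array, optional
        Flag(s) marking which measurements are below the LOD.  When omitted,
        any value strictly below ``lod`` is treated as below-LOD.

    Returns
    -------
    Imputed value(s): ``lod / sqrt(2)`` where flagged, the measured value
    otherwise.
    """
    if lod <= 0:
        raise InputError("lod must be > 0")
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise InputError("measured concentrations must be non-negative")
    if below_lod is None:
        mask = arr < lod
    else:
        mask = np.asarray(below_lod, dtype=bool)
    out = np.where(mask, lod / math.sqrt(2.0), arr)
    if np.isscalar(value) or np.ndim(value) == 0:
        return float(out)
    return out


def standardize_cadmium(cadmium_ugL, creatinine_gL, ids=None):
    """Creatinine-standardize urinary cadmium: µg/L ÷ g/L → µg/g creatinine.

    Raises :class:`InputError` listing the offending subject ids when any
    creatinine value is non-positive.
    """
    cd = np.asarray(cadmium_ugL, dtype=float)
    cr = np.asarray(creatinine_gL, dtype=float)
    bad = ~(cr > 0)
    if np.any(bad):
        if ids is not None:
            offenders = list(np.asarray(ids)[np.atleast_1d(bad)][:10])
            raise InputError(
                f"urinary creatinine must be > 0; offending subject ids: {offenders}"
            )
        raise InputError("urinary creatinine must be > 0")
    out = cd / cr
    if np.isscalar(cadmium_ugL) or np.ndim(cadmium_ugL) == 0:
        return float(out)
    return out


def weighted_quantile(x, q, weights=None):
    """Weighted empirical quantile(s) of ``x`` at probabilities ``q`` (0-1).

    Linear interpolation on the weighted ECDF with plotting positions
    ``(C_i - w_i) / (W - w_i)`` (``C_i`` the inclusive cumulative weight,
    ``W`` the total), which reduces *exactly* to the ordinary linear
    (type-7) quantile when all weights are equal — so equal survey weights
    reproduce the unweighted analysis to machine precision.
    """
    x = np.asarray(x, dtype=float)
    scalar = np.ndim(q) == 0
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((qs < 0) | (qs > 1)):
        raise InputError("quantile probabilities must lie in [0, 1]")
    if weights is None:
        out = np.quantile(x, qs)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise InputError("weights must be non-negative with positive sum")
        order = np.argsort(x, kind="mergesort")
        xs, ws = x[order], w[order]
        cw = np.cumsum(ws)
        denom = cw[-1] - ws
        pos = np.where(denom > 0, (cw - ws) / np.where(denom > 0, denom, 1.0), 0.0)
        out = np.interp(qs, pos, xs)
    return float(out[0]) if scalar else out


@dataclass
class ExposureAnchors:
    """Percentile and quartile anchors of the observed exposure distributions.

    Stored on the natural (untransformed) concentration scale.  ``p5``/``p95``
    are the threshold-intervention anchors; ``quartile_cuts`` are the
    25th/50th/75th percentiles; ``quartile_medians`` the within-quartile
    medians used by value-style quartile interventions.
    """

    exposure: str
    p5: float
    p50: float
    p95: float
    quartile_cuts: tuple[float, float, float]
    quartile_medians: tuple[float, float, float, float]
    weighted: bool = True
    degenerate: bool = False

    def percentile(self, p: float) -> float:
        return {5.0: self.p5, 50.0: self.p50, 95.0: self.p95}[float(p)]


EXPOSURES = ("lead", "cadmium")
_EXPOSURE_COL = {"lead": "blood_lead", "cadmium": "cadmium_std"}
_LOG2_COL = {"lead": "log2_lead", "cadmium": "log2_cadmium"}
_QUARTILE_COL = {"lead": "lead_quartile", "cadmium": "cadmium_quartile"}


def exposure_column(exposure: str) -> str:
    return _EXPOSURE_COL[exposure]


def log2_column(exposure: str) -> str:
    return _LOG2_COL[exposure]


def quartile_column(exposure: str) -> str:
    return _QUARTILE_COL[exposure]


def _compute_anchors(x, w, exposure, weighted):
    probs = np.array([0.05, 0.25, 0.50, 0.75, 0.95])
    p5, q1, p50, q3, p95 = weighted_quantile(x, probs, w if weighted else None)
    cuts = (q1, p50, q3)
    degenerate = not (q1 < p50 < q3)
    if degenerate:
        warnings.warn(
            f"degenerate quartile anchors for {exposure}: ties at the quartile "
            "cut points; all subjects assigned to Q1",
            stacklevel=3,
        )
        labels = np.ones(len(x), dtype=int)
    else:
        # lower-closed intervals [q_k, q_{k+1})
        labels = 1 + np.searchsorted(np.asarray(cuts), x, side="right")
    meds = []
    for k in range(1, 5):
        mask = labels == k
        if mask.any():
            meds.append(
                weighted_quantile(x[mask], 0.5, w[mask] if weighted else None)
            )
        else:
            meds.append(float("nan"))
    return (
        ExposureAnchors(
            exposure=exposure,
            p5=float(p5),
            p50=float(p50),
            p95=float(p95),
            quartile_cuts=tuple(float(c) for c in cuts),
            quartile_medians=tuple(float(m) for m in meds),
            weighted=weighted,
            degenerate=degenerate,
        ),
        labels,
    )


def transform_exposures(cohort: pd.DataFrame, weighted: bool = True):
    """Add log2 exposures and quartile labels; record percentile anchors.

    Expects canonical columns ``blood_lead`` (µg/dL) and either
    ``cadmium_std`` (µg/g, precomputed) or ``urinary_cadmium`` +
    ``urinary_creatinine`` from which the standardized value is derived.

    Returns ``(cohort_out, anchors)`` where ``anchors`` maps
    ``"lead"``/``"cadmium"`` to :class:`ExposureAnchors`.  Quantiles are
    survey-weighted by default, unweighted under the unweighted sensitivity
    mode.
    """
    out = cohort.copy()
    if "cadmium_std" not in out.columns or out["cadmium_std"].isna().all():
        out["cadmium_std"] = standardize_cadmium(
            out["urinary_cadmium"].to_numpy(),
            out["urinary_creatinine"].to_numpy(),
            ids=out["id"].to_numpy() if "id" in out.columns else None,
        )
    w = out["weight"].to_numpy(dtype=float) if "weight" in out.columns else np.ones(len(out))
    anchors: dict[str, ExposureAnchors] = {}
    for exposure in EXPOSURES:
        col = _EXPOSURE_COL[exposure]
        x = out[col].to_numpy(dtype=float)
        if np.any(~(x > 0)):
            raise InputError(
                f"{col} must be strictly positive after below-LOD imputation"
            )
        out[_LOG2_COL[exposure]] = np.log2(x)
        anchors[exposure], labels = _compute_anchors(x, w, exposure, weighted)
        out[_QUARTILE_COL[exposure]] = labels
    return out, anchors


def complete_case_filter(cohort: pd.DataFrame, required: list[str] | None = None):
    """Drop rows with missing values in the analysis columns.

    Returns ``(filtered, report)`` where ``report`` records counts per column
    and the total excluded, mirroring a complete-case exclusion log.
    """
    if required is None:
        required = [
            c
            for c in cohort.columns
            if c in CANONICAL_COLUMNS and c not in ("cadmium_std", "cause")
        ]
    miss = cohort[required].isna()
    keep = ~miss.any(axis=1)
    report = {
        "n_input": int(len(cohort)),
        "n_complete": int(keep.sum()),
        "n_excluded": int((~keep).sum()),
        "missing_by_column": {c: int(miss[c].sum()) for c in required if miss[c].any()},
    }
    return cohort.loc[keep].reset_index(drop=True), report


def _n_periods(followup_years, years_per_period, partial="ceil"):
    f = np.asarray(followup_years, dtype=float)
    if np.any(f <= 0):
        raise InputError("followup_years must be > 0")
    ratio = f / years_per_period
    if partial == "ceil":
        n = np.ceil(ratio)
    elif partial == "floor":
        n = np.maximum(np.floor(ratio), 1.0)
    else:
        raise InputError(f"unknown partial-period rule: {partial!r}")
    return n.astype(int)


def expand_person_periods(
    cohort: pd.DataFrame,
    cause: str = "all",
    years_per_period: float = 1.0,
    partial: str = "ceil",
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Expand a baseline cohort into the person-period (long) layout.

    One row per subject per discrete period at risk, annual periods by
    default, numbered ``period = 1..T_i`` with ``T_i =
    ceil(followup_years_i / years_per_period)``.  The binary ``event`` column
    is 1 only in a subject's final row and only if the subject died of the
    target cause.  For cause-specific runs (``cause`` in ``cvd``, ``cancer``,
    ``other``) deaths from competing causes contribute person-time through
    their death period with ``event = 0`` — the censor-at-competing-death
    (net-risk) convention.  ``cause="all"`` counts any death as the event.

    Baseline covariates, transformed exposures and the survey weight are
    carried unchanged onto every row; ``columns`` restricts which baseline
    columns are carried (all by default).
    """
    if cause != "all" and cause not in CAUSES:
        raise InputError(f"unknown cause: {cause!r}")
    n_periods = _n_periods(cohort["followup_years"], years_per_period, partial)
    status = cohort["status"].to_numpy()
    dead = status == "dead"
    if cause == "all":
        is_event = dead
    else:
        is_event = dead & (cohort["cause"].to_numpy() == cause)

    idx = np.repeat(np.arange(len(cohort)), n_periods)
    total = int(n_periods.sum())
    starts = np.cumsum(n_periods) - n_periods
    period = np.arange(1, total + 1) - np.repeat(starts, n_periods)
    last = period == np.repeat(n_periods, n_periods)
    event = (last & np.repeat(is_event, n_periods)).astype(np.int8)

    if columns is not None:
        keep = [c for c in columns if c in cohort.columns]
        base = cohort[keep]
    else:
        base = cohort.drop(
            columns=[c for c in ("followup_years", "status", "cause") if c in cohort.columns]
        )
    pp = base.iloc[idx].reset_index(drop=True)
    pp.insert(1, "period", period)
    pp["event"] = event
    return pp
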