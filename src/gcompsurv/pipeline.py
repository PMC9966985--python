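"""Config-driven end-to-end runs: cohort in, effect tables out.

A single :class:`RunConfig` (usually a YAML file) drives the whole
analysis: input source (CSV with a column map, or a synthetic-generator
block), hazard-model specification, intervention pairs, causes, optional
strata, bootstrap settings and the output directory.  ``run_analysis``
writes tidy risk-curve and effect tables (CSV), a JSON summary at the
horizon, a heterogeneity report and a run manifest (seed, version, config
hash) — rerunning the same config reproduces the files byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .gformula import InterventionSpec, estimate_effect
from .hazard import ModelSpec
from .inference import BootstrapConfig, bootstrap_effects, stratified_heterogeneity
from .prep import complete_case_filter, exposure_column, quartile_column
from .synthetic import GeneratorConfig, generate_cohort


def _build_generator_config(block: dict) -> GeneratorConfig:
    from .synthetic import CensoringParams, CovariateParams, ExposureParams, WeightParams

    kwargs = dict(block)
    nested = {
        "exposure_params": ExposureParams,
        "covariate_params": CovariateParams,
        "censoring_params": CensoringParams,
        "weight_params": WeightParams,
    }
    for key, cls in nested.items():
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = cls(**kwargs[key])
    return GeneratorConfig(**kwargs)


@dataclass
class RunConfig:
    """Everything one analysis run needs; exactly one input source."""

    input_csv: str | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    generator: dict | None = None
    causes: list[str] = field(default_factory=lambda: ["all"])
    model: dict = field(default_factory=dict)
    interventions: list[dict] = field(default_factory=list)
    strata: list[str] = field(default_factory=list)
    strata_exposures: list[str] = field(default_factory=lambda: ["lead", "cadmium"])
    bootstrap: dict | None = None
    horizon: int = 27
    discretization: float = 1.0
    output_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.input_csv is None) == (self.generator is None):
            raise ConfigurationError(
                "exactly one input source required: input_csv or generator"
            )
        if not self.interventions:
            raise ConfigurationError("at least one intervention pair is required")
        for pair in self.interventions:
            if "low" not in pair or "high" not in pair:
                raise ConfigurationError(
                    "each interventions entry needs 'low' and 'high' blocks"
                )

    # -- (de)serialization ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(f"invalid run config: {exc}") from exc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def analysis_dict(self) -> dict:
        """Analysis-relevant fields only (hash changes iff these change)."""
        d = self.to_dict()
        d.pop("output_dir")
        d.pop("log_level")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # -- component builders --------------------------------------------------

    def model_spec(self, cause: str) -> ModelSpec:
        return ModelSpec(cause=cause, **self.model)

    def intervention_pair(self, pair: dict) -> tuple[InterventionSpec, InterventionSpec]:
        return InterventionSpec(**pair["low"]), InterventionSpec(**pair["high"])

    def bootstrap_config(self) -> BootstrapConfig | None:
        if self.bootstrap is None:
            return None
        return BootstrapConfig(**self.bootstrap)

    def load_cohort(self) -> pd.DataFrame:
        if self.generator is not None:
            return generate_cohort(_build_generator_config(self.generator))
        df = pd.read_csv(self.input_csv)
        if self.column_map:
            df = df.rename(columns={v: k for k, v in self.column_map.items()})
        return df


def _pre_intervention_counts(cohort, cause, low, high, anchors):
    """Observed events among the low/high exposure groups before intervening.

    For percentile/value interventions the low group is subjects at or below
    the low anchor and the high group those at or above it is the high
    anchor; quartile interventions use quartile membership.
    """
    dead = (cohort["status"] == "dead").to_numpy()
    if cause != "all":
        dead = dead & (cohort["cause"] == cause).to_numpy()
    out = {}
    for which, ispec in (("low", low), ("high", high)):
        exposure = ispec.targets()[0]
        if ispec.rule == "quartile":
            mask = (cohort[quartile_column(exposure)] == ispec.quartile).to_numpy()
        else:
            v = ispec.resolve_value(exposure, anchors)
            x = cohort[exposure_column(exposure)].to_numpy(dtype=float)
            mask = x <= v if which == "low" else x >= v
        n = int(mask.sum())
        out[f"n_{which}"] = n
        out[f"events_{which}"] = int((dead & mask).sum())
    return out


@dataclass
class ResultBundle:
    """In-memory results of one run; ``write`` persists them as text files."""

    config: RunConfig
    risk_curves: pd.DataFrame
    effects: pd.DataFrame
    summary: list[dict]
    heterogeneity: pd.DataFrame
    manifest: dict

    def write(self, output_dir) -> Path:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.risk_curves.to_csv(out / "risk_curves.csv", index=False)
        self.effects.to_csv(out / "effects.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2)
        self.heterogeneity.to_csv(out / "heterogeneity.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)
        return out

    @classmethod
    def read(cls, output_dir) -> "ResultBundle":
        out = Path(output_dir)
        missing = [
            f
            for f in ("effects.csv", "summary.json", "manifest.json")
            if not (out / f).exists()
        ]
        if missing:
            raise FileNotFoundError(f"incomplete result bundle, missing: {missing}")
        def _read(path):
            # round-trip float parsing so write -> read -> write is
            # byte-identical
            if not path.exists() or path.stat().st_size <= 1:
                return pd.DataFrame()
            return pd.read_csv(path, float_precision="round_trip")

        return cls(
            config=None,
            risk_curves=_read(out / "risk_curves.csv"),
            effects=_read(out / "effects.csv"),
            summary=json.load(open(out / "summary.json")),
            heterogeneity=_read(out / "heterogeneity.csv"),
            manifest=json.load(open(out / "manifest.json")),
        )


def run_analysis(config: RunConfig, output_dir=None) -> ResultBundle:
    """Execute the full pipeline described by ``config``.

    Per cause and intervention pair: fit the pooled logistic hazard model,
    g-compute marginal risk curves under both interventions and contrast
    them, with bootstrap CIs when a bootstrap block is configured.  Optional
    strata produce Wald heterogeneity rows per stratum variable and metal.
    """
    from . import __version__

    cohort = config.load_cohort()
    cohort, exclusions = complete_case_filter(cohort)
    bc = config.bootstrap_config()

    curves_rows, effect_frames, summary = [], [], []
    for cause in config.causes:
        spec = config.model_spec(cause)
        for pair in config.interventions:
            low, high = config.intervention_pair(pair)
            if bc is not None:
                res = bootstrap_effects(
                    cohort, spec, low, high, config.horizon, bc,
                    discretization=config.discretization,
                )
                effect = res.effect
                diag = {"bootstrap_failed": res.n_failed, "unstable": res.unstable}
            else:
                effect = estimate_effect(
                    cohort, spec, low, high, config.horizon,
                    discretization=config.discretization,
                )
                diag = {}
            from .prep import transform_exposures

            transformed, anchors = transform_exposures(cohort, weighted=spec.weighted)
            counts = _pre_intervention_counts(transformed, cause, low, high, anchors)
            effect_frames.append(effect.to_frame())
            for which, curve in (("low", effect.low_risk), ("high", effect.high_risk)):
                label = effect.low_label if which == "low" else effect.high_label
                curves_rows.append(
                    pd.DataFrame(
                        {
                            "cause": cause,
                            "intervention": label,
                            "t": np.arange(1, config.horizon + 1),
                            "risk": curve,
                        }
                    )
                )
            summary.append({**effect.summary(), **counts, **diag})

    het_rows = []
    for strata in config.strata:
        for exposure in config.strata_exposures:
            for cause in config.causes:
                spec = config.model_spec(cause)
                try:
                    h = stratified_heterogeneity(
                        cohort, spec, strata, exposure=exposure,
                        discretization=config.discretization,
                    )
                except Exception as exc:  # surfaced, not fatal to the run
                    het_rows.append(
                        {"strata": strata, "exposure": exposure, "cause": cause,
                         "error": str(exc)}
                    )
                    continue
                het_rows.append(
                    {
                        "strata": strata, "exposure": exposure, "cause": cause,
                        "stratum_a": h.label_a, "stratum_b": h.label_b,
                        "estimate_a": h.estimate_a, "estimate_b": h.estimate_b,
                        "se_a": h.se_a, "se_b": h.se_b,
                        "z": h.z, "p_value": h.p_value,
                        "significant_at_0.1": h.significant, "scale": h.scale,
                    }
                )

    manifest = {
        "package": "gcompsurv",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": (config.generator or {}).get("seed"),
        "bootstrap_seed": bc.seed if bc else None,
        "n_input": exclusions["n_input"],
        "n_complete": exclusions["n_complete"],
        "exclusions": exclusions,
    }
    bundle = ResultBundle(
        config=config,
        risk_curves=pd.concat(curves_rows, ignore_index=True),
        effects=pd.concat(effect_frames, ignore_index=True),
        summary=summary,
        heterogeneity=pd.DataFrame(het_rows),
        manifest=manifest,
    )
    target = output_dir or config.output_dir
    if target:
        bundle.write(target)
    return bundle


def _fmt_ci(value, lo, hi, pct=False):
    scale = 100.0 if pct else 1.0
    unit = "%" if pct else ""
    if np.isnan(value):
        return "NA"
    s = f"{value * scale:+.2f}{unit}" if pct else f"{value:.2f}"
    if np.isnan(lo) or np.isnan(hi):
        return s
    return f"{s} ({lo * scale:.2f} to {hi * scale:.2f})"


def summarize(bundle: ResultBundle) -> str:
    """Markdown report in the cause x intervention-pair layout."""
    lines = ["# G-computation effect estimates", ""]
    lines.append(f"Config hash: `{bundle.manifest['config_hash']}`; "
                 f"n = {bundle.manifest['n_complete']}")
    lines.append("")
    lines.append(
        "| Cause | Low | High | Events (low) | Events (high) "
        "| Risk ratio (95% CI) | Risk difference (95% CI) |"
    )
    lines.append("|---|---|---|---|---|---|---|")
    for row in bundle.summary:
        rr = _fmt_ci(row["rr"], row["rr_lo"], row["rr_hi"])
        rd = _fmt_ci(row["rd"], row["rd_lo"], row["rd_hi"], pct=True)
        lines.append(
            f"| {row['cause']} | {row['low']} | {row['high']} "
            f"| {row['events_low']}/{row['n_low']} | {row['events_high']}/{row['n_high']} "
            f"| {rr} | {rd} |"
        )
    if len(bundle.heterogeneity):
        lines += ["", "## Stratum heterogeneity (Wald, alpha = 0.1)", ""]
        lines.append("| Strata | Exposure | Cause | p | Significant |")
        lines.append("|---|---|---|---|---|")
        for _, r in bundle.heterogeneity.iterrows():
            if "error" in r and isinstance(r.get("error"), str) and r.get("error"):
                lines.append(f"| {r['strata']} | {r['exposure']} | {r['cause']} | error | — |")
            else:
                lines.append(
                    f"| {r['strata']} | {r['exposure']} | {r['cause']} "
                    f"| {r['p_value']:.3f} | {bool(r['significant_at_0.1'])} |"
                )
    lines.append("")
    return "\n".join(lines)
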