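"""Attach nonparametric bootstrap percentile confidence intervals to the
risk difference and risk ratio curves.

Participants are resampled with replacement; the whole transform-fit-
standardize pipeline is re-run per resample and the 2.5th/97.5th
percentiles of the replicate estimates bound the CI at every year.
"""

from gcompsurv import (
    BootstrapConfig,
    InterventionSpec,
    ModelSpec,
    bootstrap_effects,
    generate_cohort,
    study_config,
)

cohort = generate_cohort(study_config(n_subjects=4000, seed=8))
spec = ModelSpec(cause="all", weighted=True)
low = InterventionSpec(exposure="cadmium", rule="percentile", percentile=5)
high = InterventionSpec(exposure="cadmium", rule="percentile", percentile=95)

res = bootstrap_effects(
    cohort, spec, low, high, horizon=27,
    bc=BootstrapConfig(replicates=50, seed=0),
)
for t in (13, 27):
    s = res.effect.at(t)
    print(f"t={t:2d}y  RD = {100 * s['rd']:+.2f} pp "
          f"(95% CI {100 * s['rd_lo']:+.2f} to {100 * s['rd_hi']:+.2f})  "
          f"RR = {s['rr']:.2f} ({s['rr_lo']:.2f} to {s['rr_hi']:.2f})")
print(f"replicates used: {res.n_completed}/{res.n_requested}")
# The RD typically grows with follow-up time: absolute effects accumulate
# as baseline risk rises, which is why a single hazard ratio would hide
# the time profile.
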