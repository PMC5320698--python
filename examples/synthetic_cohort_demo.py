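"""Generate a calibrated synthetic mild-stroke cohort and recover its structure.

The generator is calibrated so baseline WMH volume has mean 22.0 / SD 24.8 ml,
Fazekas categories follow the observed marginals, mean 1-year progression is
1.27 ml with model R^2 0.90, and 28% of patients drop out informatively
(older, higher Fazekas).  Refitting the observational models on the
synthetic data recovers the generative parameters.
"""

from wmhtrial import (
    compare_dropout_groups,
    default_config,
    fit_progression_models,
    fit_volume_to_fazekas,
    generate_full_cohort,
)

config = default_config(n_patients=20_000, seed=0)
cohort = generate_full_cohort(config)
d = cohort.data

print(f"baseline volume  mean {d.wmh_baseline.mean():.1f} ml, SD {d.wmh_baseline.std():.1f} ml")
print(f"dropout fraction {d.dropout.mean():.3f}")

_, multi = fit_progression_models(cohort)
print(f"multivariable fit on completers: R2 {multi.r_squared:.3f}, "
      f"baseline-volume coefficient {multi.coef('wmh_baseline'):.3f}")

ordinal = fit_volume_to_fazekas(cohort)
print(f"OR per ml of baseline volume: {ordinal.odds_ratio:.3f} "
      f"(95% CI {ordinal.ci_low:.3f}-{ordinal.ci_high:.3f})")

age = next(c for c in compare_dropout_groups(cohort) if c.variable == "age")
print(f"age gap, completers minus non-completers: {age.difference:.1f} years")

print(
    "\nTargets were 22.0/24.8 ml, 0.28, 0.90, 0.73, 1.21 and -5.7 years;"
    "\nagreement is limited only by sampling noise at this cohort size."
)
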