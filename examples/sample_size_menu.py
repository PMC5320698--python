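"""Sample sizes for a volume-outcome trial, with covariate deflation and dropout.

A hypothetical two-arm trial assumes treatment halts WMH progression while the
control arm gains 1 ml/year, with a follow-up SD of 23.3 ml.  Adjusting the
analysis for baseline covariates deflates the requirement by (1 - R^2);
recruiting above the completer target compensates 20%/year attrition.
"""

from wmhtrial import ContinuousDesign, continuous_sample_size

for label, design in [
    ("unadjusted, 1-year", ContinuousDesign()),
    ("adjusted for all predictors (R2=0.90)", ContinuousDesign(r_squared=0.90)),
    ("adjusted + 2-year follow-up", ContinuousDesign(r_squared=0.90, years=2)),
]:
    res = continuous_sample_size(design)
    print(
        f"{label:42s} per group {res.n_per_group:>6d}   "
        f"total {res.n_total:>6d}   recruit {res.n_recruit_total:>6d}"
    )

print(
    "\nEach row: completers needed per arm, both arms, and the recruitment"
    "\ntarget once (1 - 0.20)^years retention is divided out.  Covariate"
    "\nadjustment alone cuts the requirement about tenfold."
)
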