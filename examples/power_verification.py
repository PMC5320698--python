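"""Verify closed-form sample sizes by Monte-Carlo simulation.

Every design formula here has a matching simulation: trials are generated at
the candidate size and analysed as planned, and the rejection fraction should
sit at the design power.  Heterogeneous per-category odds ratios deliberately
break the proportional-odds assumption to probe robustness.
"""

from wmhtrial import (
    ContinuousDesign,
    OrdinalDesign,
    SimulationPlan,
    fazekas_baseline_distribution,
    n_per_group_continuous,
    simulate_po_violation,
    simulate_power,
    whitehead_n_per_group,
)

n_cont = n_per_group_continuous(ContinuousDesign())
est = simulate_power(
    SimulationPlan(kind="continuous", n_per_group=n_cont, analysis="z",
                   reps=2000, seed=1, delta=1.0, sd=23.3)
)
print(f"continuous design, n={n_cont}/group: power {est.power:.3f} "
      f"(95% CI {est.ci_low:.3f}-{est.ci_high:.3f})")

dist = fazekas_baseline_distribution()
design = OrdinalDesign(odds_ratio=1.21, control_dist=dist)
n_ord = whitehead_n_per_group(design)
est = simulate_power(
    SimulationPlan(kind="ordinal", n_per_group=n_ord, analysis="po_score",
                   reps=2000, seed=2, control_dist=dist, odds_ratio=1.21)
)
print(f"ordinal design, n={n_ord}/group: power {est.power:.3f} "
      f"(95% CI {est.ci_low:.3f}-{est.ci_high:.3f})")

skew = simulate_po_violation(dist, (2.0, 1.0, 1.0, 1.0, 1.0, 1.0),
                             n_per_group=n_ord, reps=2000, seed=3)
print(f"same n, effect on the lowest split only: power {skew.power:.3f}")

print(
    "\nBoth designs hit ~0.80 when their assumptions hold; concentrating the"
    "\neffect on one category split leaves the rank/score analysis badly"
    "\nunderpowered - the robustness check the formula cannot provide."
)
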