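"""Classify a trait by comparing ordinal, proportional and null models.

Simulates a density-dependent study (fixed resource base: ordinal rank
drives the trait), runs the full inference pipeline, and shows the AIC
triplet and classification. Also reproduces the exact tests used to tally
classifications across traits by sex.
"""

from domrank import (
    RegimeSimConfig,
    analyze_study,
    binomial_two_tailed,
    fisher_two_sided,
    simulate_study,
)

cfg = RegimeSimConfig(n_groups=3, n_months=12, seed=7)
comparison = analyze_study(simulate_study(cfg))

print(f"AIC ordinal      {comparison.aic_ordinal:10.1f}")
print(f"AIC proportional {comparison.aic_proportional:10.1f}")
print(f"AIC null         {comparison.aic_null:10.1f}")
print(f"classification   {comparison.classification}")
print("(lower AIC by >= 2 wins; the generating regime was density-dependent,")
print(" so ordinal rank should and does carry the signal)\n")

# tallying classifications across many traits: 7/7 male traits ordinal,
# 3 of 7 female traits ordinal
print("male 7/7 ordinal vs chance, binomial p =", binomial_two_tailed(7, 7, 0.5))
print("female 3/7 ordinal vs chance, binomial p =", binomial_two_tailed(3, 7, 0.5))
print("male vs female contrast, Fisher p =", round(fisher_two_sided([[7, 0], [3, 4]]), 4))
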