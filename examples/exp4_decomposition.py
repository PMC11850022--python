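"""Decompose multidimensional response time into fixation and recall costs.

Five control-task conditions separate the time needed to *look at* five
features (letter counting: the answer is printed on the stimulus) from the
time needed to also *recall* each feature's learned category.  The per-trial
gap between the two odd/even conditions estimates five recall retrievals.
"""

import catstep as cs

dataset = cs.simulate_cohort(cs.default_cohort_config("EXP4", n_participants=54, seed=3))
results = cs.analyze_exp4(dataset)

print("Per-condition summary:")
print(results["condition_summary"].round(2).to_string())

anova = results["task_rt_anova"]
print(f"\nomnibus RT ANOVA: {anova['formatted']}")
oea_oet = next(
    p for p in anova["tukey"]
    if {p["group1"], p["group2"]} == {"ODD_EVEN_T", "ODD_EVEN_A"}
)
print(f"letter-counting vs category-counting gap: "
      f"{abs(oea_oet['mean_diff']):.2f} s (d = {abs(oea_oet['cohen_d']):.2f}, "
      f"adjusted p = {oea_oet['p_adj']:.2g})")
print(f"\nfeature-training last-block RT ANOVA (multidimensional conditions): "
      f"{results['feature_rt_anova']['formatted']}")
print(
    "\nBoth tasks require the same eye fixations over the same stimuli; the"
    "\ngap is the extra time to recall learned feature-category associations."
)
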