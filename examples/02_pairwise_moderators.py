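"""Per-variable moderator effect sizes over all cross-arm patient pairs.

Every CBASP patient is paired with every ESC/CM patient; for each pair the
outcome difference (ESC/CM minus CBASP percent change) and the average of
each baseline variable are recorded.  A variable's moderator effect size is
the Spearman correlation between the two: negative means higher values favor
ESC/CM, positive means they favor CBASP.  Variables with |rho| >= 0.20 (and
acceptable missingness) enter the composite moderator.
"""

from modstar import (
    GeneratorConfig,
    build_pairs,
    classify_outcomes,
    compute_all_effects,
    effects_table,
    generate_trial,
    preselect_variables,
)

trial = generate_trial(GeneratorConfig(seed=7, missing_rate=0.02))
outcomes = classify_outcomes(trial)

pairs = build_pairs(trial, outcomes)
print(f"{trial.arm_counts()['CBASP']} x {trial.arm_counts()['ESC_CM']} = "
      f"{len(pairs)} cross-arm pairs")

effects = compute_all_effects(trial, outcomes, n_reps=100, seed=1)
selected = preselect_variables(trial, effects)

table = effects_table(effects).sort_values("effect_size")
print(table[["variable", "effect_size", "ci_low", "ci_high", "n_missing",
             "selected"]].round(3).to_string(index=False))
print(f"\nselected for the composite moderator (|rho| >= 0.20): {selected}")
print("negative effect size: higher values favor ESC/CM; "
      "positive: favor CBASP")
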