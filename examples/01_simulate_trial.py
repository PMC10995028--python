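"""Generate a synthetic two-arm trial and look at its baseline profile.

The generator draws 27 CBASP and 26 ESC/CM completers with eleven baseline
variables whose marginals mimic a persistent-depressive-disorder outpatient
sample, then builds a percent-change MADRS outcome with a built-in
treatment-by-baseline interaction (the ground truth the analysis should
recover).
"""

from modstar import GeneratorConfig, classify_outcomes, generate_trial, write_trial_csv

config = GeneratorConfig(seed=7, missing_rate=0.02)
trial = generate_trial(config)
write_trial_csv(trial, "synthetic_trial.csv")

df = trial.data
print(f"patients: {trial.n_patients}  arms: {trial.arm_counts()}")
print(f"female: {df['female'].mean():.0%}   childhood trauma: "
      f"{df['childhood_trauma'].mean():.0%}   mean age: {df['age'].mean():.1f}")
print(f"baseline MADRS: {df['madrs_baseline'].mean():.1f} "
      f"(SD {df['madrs_baseline'].std():.1f})")

outcomes = classify_outcomes(trial)
print(f"mean percent change at week 8: {outcomes['percent_change'].mean():.1f}%  "
      f"(negative = improvement)")
print(f"responders: {outcomes['responder'].sum()}   "
      f"remitters: {outcomes['remitter'].sum()}   "
      f"non-improvers (<20% reduction): {(~outcomes['improver_20pct']).sum()}")
print("wrote synthetic_trial.csv")
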