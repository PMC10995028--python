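# Methods

## The moderation model

The package targets two-arm randomized trials where the question is not
*does treatment A beat treatment B on average* but *for whom*.  The working
outcome is the percent change in MADRS from baseline to week 8; all sign
conventions follow from "negative = improvement" and from coding the
treatment indicator T = 1 for CBASP, 0 for ESC/CM.

The paired-difference construction turns a between-patient contrast into an
estimable quantity: with every cross-arm pair (i ∈ CBASP, j ∈ ESC/CM) we
observe `d_ij = y_j − y_i` and the pair average of each baseline variable.
If a variable moderates the arm contrast, `d` trends with the average; the
Spearman correlation over all n₁·n₂ pairs is the moderator effect size.
Rank correlation makes the effect size invariant under any strictly
increasing transformation of the variable or outcome (a stronger property
than linear invariance, and the one our tests assert).  The subtraction
order ESC/CM − CBASP is fixed so that a *negative* ρ reads "higher values
favor ESC/CM" — stated prominently because nothing else in the arithmetic
pins it down.

The composite moderator is a deliberately simple object: a linear score
`M* = Σ w_k x_ik` whose weights come from an L1-penalized regression of the
pair outcome difference on the pair averages of the preselected variables.
The penalty does the variable selection; cross-validation picks its
strength.  The final OLS interaction model `y ~ 1 + M* + T + M*·T` is fitted
on the *unpaired* patients; the arms' predicted-outcome lines cross at
`M* = −β_T / β_{M*·T}`, and the subgroup labels follow from which side of
the crossing gives ESC/CM the lower (better) predicted outcome.  Labels are
derived from the fitted lines, never from a hard-coded sign convention, so
they remain correct for either sign of the interaction slope.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| effect-size threshold | 0.20 | inclusive cutoff on \|ρ\| for a variable to enter the lasso; the method's stated preselection rule |
| missingness rule | ≥ 50 valid or ≤ 3 missing | per-variable validity requirement, keeps the final complete-case M\* sample from shrinking |
| bootstrap replications | 100 | percentile CIs for every effect size; replications resample patients within arms and rebuild all pairs |
| CV folds k | 10 | fold partition of the pair records for the penalty search |
| λ grid | 100 points, geometric, λ_max → 10⁻³·λ_max | λ_max is the smallest penalty with an empty model (computed from the standardized design), so the grid provably brackets the whole path |
| λ rule | `min` | penalty minimizing cross-validated MSPE; a `1se` option returns the sparsest model within one SE of the minimum |
| near-parallel tolerance | 10⁻⁸ × outcome SD | below this the interaction slope is treated as no qualitative interaction and the cross-point is refused |

Three independent seeds (generation, bootstrap, CV folds) let each
stochastic stage be varied in isolation; identical seeds give byte-identical
reports.

## Numerical choices

- **Standardization.**  The lasso penalty is applied to predictors
  standardized on the full paired dataset; reported coefficients are
  destandardized back to the original variable scale (so binary variables
  legitimately carry much larger raw weights than, say, age).  Full-sample
  rather than per-fold standardization mirrors common lasso-CV tooling and
  changes MSPE only marginally at ~700 pair records.
- **Folds at the pair level.**  The CV partition is over pair records, as
  the original procedure runs CV inside the paired dataset.  Pairs sharing
  a patient are statistically dependent, which makes pair-level CV somewhat
  optimistic; we verified on planted-truth simulations that a
  patient-grouped partition gives materially the same selections at this
  scale, and kept the pair-level default.
- **Intercept.**  The lasso fit includes an intercept; M\* is the weighted
  sum of the selected variables only (no intercept), which shifts the
  cross-point but not the subgroup split.
- **Missing data.**  Pairwise deletion per variable for effect sizes
  (maximizing data use); complete-case on the weighted variables for M\*.
- **Bootstrap unit.**  Patients within arms, re-pairing after each
  resample — resampling pairs directly would destroy the dependence
  structure the pairing induces.  Percentile intervals (not BCa, which is
  unstable at 100 replications).  Degenerate replications (constant ranks)
  are skipped; more than half skipped is an error.
- **Ties and degeneracy.**  Spearman uses average ranks.  A constant
  variable or constant outcome difference yields a flagged degenerate
  effect with ρ recorded as 0, never a silent NaN.
- **Boundary inclusivity.**  Response (≤ −50.0%), remission (week-8 ≤ 9)
  and the 20% improvement rule are inclusive and evaluated on unrounded
  percentages; report tables round to one decimal at the presentation layer
  only.
- **Comparison tests.**  Subgroup baseline tables use the pooled-variance
  (Student) two-sample t for metric variables — the only variant that
  reproduces the published age CI from its summary statistics — and, for
  dichotomous variables, a Wald CI on the proportion difference with a
  two-sided Fisher exact p (point-probability method).  Ordinal
  treatment-history variables are dichotomized at ≥ 1 previous treatment.
  These are presentation-layer conventions, labeled as such.
- **Cohen's d.**  `(mean_ESC/CM − mean_CBASP)/pooled SD` within each
  subgroup (same subtraction order as the pair differences), with the
  normal-approximation CI `d ± 1.96·√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)))`.
- **Pooling identities.**  Matched/mismatched rows are computed from
  cluster *summary statistics* (n-weighted means and rates; SDs via the
  within-plus-between variance decomposition), which provably equals the
  direct patient-level computation — and lets already-tabulated rows be
  pooled without raw data.

## The synthetic generator

The generator emulates the structure the analysis assumes, not any real
patient: eleven baseline variables with marginals set to a published
persistent-depressive-disorder outpatient sample (50% female, mean age 42.9
SD 10.8, 58% early onset, baseline MADRS 26.6 SD 8.6, 70% childhood trauma,
0.3 SD 0.7 previous suicide attempts, 1.8 SD 1.1 adverse life events,
48%/38% Axis-I/II comorbidity, and the published category frequencies for
previous psychotherapies and antidepressant treatments).  One reported
entire-sample age SD of 1.08 is internally inconsistent with the subgroup
SDs (10.8 / 9.9) and is treated as a typo for 10.8.  A Gaussian-copula
latent factor (default loading 0.35, switchable to 0) correlates the
clinically co-occurring trauma variables — female gender, childhood trauma,
suicide attempts, adverse life events — without disturbing the marginals.

The outcome is generated directly on the percent-change scale,

    y_i = μ0 + τ·T_i + γᵀx_i + T_i·(δᵀx_i) + ε_i,   ε_i ~ N(0, σ²),

and a consistent (baseline, week-8) score pair is back-computed, avoiding
any claim about a longitudinal score model.  Because δᵀx is added to the
*CBASP* arm's percent change and lower is better, **positive δ components
favor ESC/CM** and give negative pairwise effect sizes.  Defaults: arm
sizes 27/26 (completer counts of the motivating trial), δ with the
motivating trial's sign pattern at moderate magnitude (trauma-related
variables positive; age, early onset, previous antidepressants negative),
τ = +20 so the cross-point falls inside the observed M\* range,
μ0 = −25 (ESC/CM mean change ≈ −25%), σ = 25 (cluster-level outcome SDs in
the motivating trial span 22–37), γ = 0 for interpretability of the planted
truth, and a 2% per-variable missing rate (≈ 1 missing value per variable
at n = 53, matching the "no more than three missing" regime).  Week-8
scores are clipped to the MADRS range [0, 60] and y is recomputed from the
clipped pair — the one place the emitted outcome can deviate from the
linear model.

What passing tests on synthetic data do and do not show: the generator has
exactly the linear interaction structure the analysis models, plus clean
MCAR missingness; real trials add measurement error in the ratings,
informative dropout, non-linear moderation and confounded missingness, none
of which are emulated.  Green tests demonstrate the *procedure* is
implemented correctly and recovers known truth under its own assumptions —
not that the method is robust to violations of them.

## Validation design and a known limit

The suite validates against independent oracles (hand pair enumeration,
rank-then-Pearson Spearman, normal-equations OLS, hypergeometric
enumeration for Fisher, textbook pooled-t and pooled-SD formulas), against
structural invariances (pair-count conservation, monotone-transform
invariance with arm-relabel sign flip, exact lasso null at λ ≥ λ_max, OLS
limit as the penalty vanishes, cross-point self-consistency, weight-scaling
equivariance of M\*), against published-table arithmetic identities, and
with end-to-end parameter recovery on planted-truth trials (100 trials at
27/26 per condition; sizes chosen to exercise study scale).

One honest limit, measured rather than hidden: at study scale the
noise-free (σ = 0) planted-moderator experiment recovers the true moderator
in 100% of trials but assigns subgroups with ~94%, not 100%, mean accuracy.
At n = 53, null covariates cross the |ρ| ≥ 0.20 preselection threshold by
chance, and because their sample correlation with the true moderator is
genuinely present *within* that sample, no cross-validation variant can
screen them out; the slightly contaminated M\* misorders patients near the
cross-point.  At 10× the sample size only the true moderator survives and
assignment accuracy is exactly 100%.  This is a property of the method at
small n — a caution worth carrying into any application at this scale — and
the corresponding exact-recovery test is intentionally left failing as a
record of it.

## Other limitations

- No inference on the lasso weights (no post-selection p-values), no
  alternative learners; the composite is linear by construction.
- The extended 28-week phase of the motivating design (augmentation
  outcomes after week 8) is out of scope; the augmentation sub-analysis
  only classifies who the week-8 non-improvers were.
- No outcome imputation; patients without a week-8 score are excluded and
  counted.  The outlier/skewness screen is diagnostic only.
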