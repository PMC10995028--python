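"""Pairwise (all cross-arm pairs) moderator effect sizes.

The moderation method pairs every CBASP patient with every ESC/CM patient.
For each pair it records the outcome difference (ESC/CM minus CBASP percent
change) and, per baseline variable, the average of the two members' values.
The moderator effect size of a variable is the Spearman rank correlation,
over all pairs with complete data, between the pair's outcome difference and
its average value.

Sign convention (fixed throughout): ``outcome_diff = y_ESC/CM - y_CBASP``.
Because negative percent change is improvement, a *negative* rho means
higher values (or presence) of the variable go with a better outcome under
ESC/CM, a *positive* rho with a better outcome under CBASP.

Confidence intervals are percentile bootstrap intervals; each replication
resamples patients with replacement *within each arm* (arm sizes preserved),
rebuilds all pairs and recomputes rho.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import ARM_CBASP, ARM_ESC, TrialDataset

PAIR_FIXED_COLUMNS = ("cbasp_id", "esc_id", "outcome_diff")


@dataclass
class ModeratorEffect:
    """Effect size of one candidate moderator over the paired dataset."""

    variable: str
    rho: float
    n_pairs_used: int
    ci_low: float | None = None
    ci_high: float | None = None
    degenerate: bool = False
    n_valid: int | None = None  # patients with a non-missing value
    n_missing: int | None = None
    preselected_missingness: bool | None = None
    selected_by_threshold: bool | None = None
    notes: list[str] = field(default_factory=list)


def build_pairs(dataset: TrialDataset, outcomes: pd.DataFrame) -> pd.DataFrame:
    """All n_CBASP x n_ESC cross-arm pairs.

    Returns a frame with ``cbasp_id``, ``esc_id``, ``outcome_diff`` and one
    column per baseline variable holding the pair average (NaN whenever
    either member's value is missing).
    """
    counts = dataset.arm_counts()
    if counts[ARM_CBASP] == 0 or counts[ARM_ESC] == 0:
        raise ValueError(f"both arms must be non-empty, got {counts}")

    df = dataset.data.merge(
        outcomes[["patient_id", "percent_change"]], on="patient_id", how="inner"
    )
    if len(df) < dataset.n_patients:
        warnings.warn(
            f"build_pairs: {dataset.n_patients - len(df)} patient(s) without an "
            "outcome were dropped",
            stacklevel=2,
        )
    cb = df[df["arm"] == ARM_CBASP].reset_index(drop=True)
    es = df[df["arm"] == ARM_ESC].reset_index(drop=True)
    i, j = np.meshgrid(np.arange(len(cb)), np.arange(len(es)), indexing="ij")
    i, j = i.ravel(), j.ravel()

    pairs = pd.DataFrame(
        {
            "cbasp_id": cb["patient_id"].to_numpy()[i],
            "esc_id": es["patient_id"].to_numpy()[j],
            "outcome_diff": es["percent_change"].to_numpy()[j]
            - cb["percent_change"].to_numpy()[i],
        }
    )
    for name in dataset.variable_names:
        pairs[name] = (cb[name].to_numpy()[i] + es[name].to_numpy()[j]) / 2.0
    return pairs


def moderator_effect_size(pairs: pd.DataFrame, variable: str) -> ModeratorEffect:
    """Spearman rho between pair outcome difference and the pair average.

    Pairs with a missing average are dropped (pairwise deletion).  A constant
    variable or constant outcome difference makes the correlation undefined;
    the effect is then flagged degenerate with rho recorded as 0.
    """
    sub = pairs[["outcome_diff", variable]].dropna()
    if len(sub) < 3:
        raise ValueError(
            f"need >= 3 complete pairs for {variable!r}, got {len(sub)}"
        )
    x = sub[variable].to_numpy()
    d = sub["outcome_diff"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(d) == 0:
        warnings.warn(
            f"moderator_effect_size: {variable!r} degenerate (constant ranks); rho set to 0",
            stacklevel=2,
        )
        return ModeratorEffect(variable, 0.0, len(sub), degenerate=True,
                               notes=["degenerate: constant variable or outcome"])
    rho = stats.spearmanr(x, d).statistic
    return ModeratorEffect(variable, float(rho), len(sub))


def bootstrap_ci(
    dataset: TrialDataset,
    outcomes: pd.DataFrame,
    variable: str,
    n_reps: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a variable's moderator effect size.

    Each replication resamples patients with replacement within each arm,
    rebuilds the full paired dataset and recomputes rho.  Replications with a
    degenerate rho are skipped (logged); more than 50% skipped is an error.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 bootstrap replications")
    rng = np.random.default_rng(seed)
    df = dataset.data
    cb_idx = np.flatnonzero(df["arm"].to_numpy() == ARM_CBASP)
    es_idx = np.flatnonzero(df["arm"].to_numpy() == ARM_ESC)

    rhos = []
    n_skipped = 0
    for _ in range(n_reps):
        take = np.concatenate(
            [rng.choice(cb_idx, size=len(cb_idx), replace=True),
             rng.choice(es_idx, size=len(es_idx), replace=True)]
        )
        boot = df.iloc[take].copy()
        orig_ids = boot["patient_id"].to_numpy().copy()
        boot["patient_id"] = [f"B{k}" for k in range(len(boot))]  # resampled copies are distinct units
        # outcome lookup by original id, reattached under the new ids
        out_map = outcomes.set_index("patient_id")["percent_change"]
        boot_outcomes = pd.DataFrame(
            {"patient_id": boot["patient_id"].to_numpy(),
             "percent_change": out_map.reindex(orig_ids).to_numpy()}
        )
        boot_ds = TrialDataset(boot, variable_specs=dataset.variable_specs)
        pairs = build_pairs(boot_ds, boot_outcomes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eff = moderator_effect_size(pairs, variable)
        if eff.degenerate:
            n_skipped += 1
            continue
        rhos.append(eff.rho)
    if n_skipped > n_reps / 2:
        raise RuntimeError(
            f"bootstrap_ci: {n_skipped}/{n_reps} replications degenerate for {variable!r}"
        )
    lo, hi = np.percentile(rhos, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def compute_all_effects(
    dataset: TrialDataset,
    outcomes: pd.DataFrame,
    n_reps: int = 100,
    seed: int = 0,
    with_ci: bool = True,
) -> list[ModeratorEffect]:
    """Effect size (and optionally bootstrap CI) for every baseline variable."""
    pairs = build_pairs(dataset, outcomes)
    effects = []
    for k, name in enumerate(dataset.variable_names):
        eff = moderator_effect_size(pairs, name)
        eff.n_valid = int(dataset.data[name].notna().sum())
        eff.n_missing = dataset.n_patients - eff.n_valid
        if with_ci and not eff.degenerate:
            # per-variable sub-seed keeps results invariant to variable order
            eff.ci_low, eff.ci_high = bootstrap_ci(
                dataset, outcomes, name, n_reps=n_reps, seed=seed + k
            )
        effects.append(eff)
    return effects


def preselect_variables(
    dataset: TrialDataset,
    effects: list[ModeratorEffect],
    threshold: float = 0.20,
    min_valid: int = 50,
    max_missing: int = 3,
) -> list[str]:
    """Variables eligible for the composite moderator.

    A variable passes iff it has at least ``min_valid`` valid cases OR at
    most ``max_missing`` missing cases, AND its |effect size| is at least
    ``threshold`` (inclusive, as in the source method's |rho| >= 0.20 rule).
    Flags are recorded on the effect objects as a side product.
    """
    selected = []
    n = dataset.n_patients
    for eff in effects:
        n_valid = int(dataset.data[eff.variable].notna().sum())
        n_missing = n - n_valid
        eff.n_valid, eff.n_missing = n_valid, n_missing
        eff.preselected_missingness = (n_valid >= min_valid) or (n_missing <= max_missing)
        eff.selected_by_threshold = abs(eff.rho) >= threshold and not eff.degenerate
        if eff.preselected_missingness and eff.selected_by_threshold:
            selected.append(eff.variable)
    return selected


def screen_distributions(dataset: TrialDataset, z_cutoff: float = 3.0) -> pd.DataFrame:
    """Diagnostic outlier/skewness screen on the metric baseline variables.

    Reports, per metric variable, the skewness and the ids of patients whose
    value lies more than ``z_cutoff`` SDs from the mean.  Purely diagnostic:
    nothing is removed.
    """
    rows = []
    for spec in dataset.variable_specs:
        if spec.kind != "metric":
            continue
        col = dataset.data[spec.name]
        vals = col.dropna()
        sd = vals.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            rows.append({"variable": spec.name, "skewness": np.nan, "n_outliers": 0, "outlier_ids": ""})
            continue
        z = (vals - vals.mean()) / sd
        out_ids = dataset.data.loc[z.index[np.abs(z) > z_cutoff], "patient_id"]
        rows.append(
            {
                "variable": spec.name,
                "skewness": float(stats.skew(vals)),
                "n_outliers": int((np.abs(z) > z_cutoff).sum()),
                "outlier_ids": ";".join(out_ids.astype(str)),
            }
        )
    return pd.DataFrame(rows)


def effects_table(effects: list[ModeratorEffect]) -> pd.DataFrame:
    """Tidy export of per-variable effect sizes, CIs and selection flags."""
    return pd.DataFrame(
        [
            {
                "variable": e.variable,
                "effect_size": e.rho,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_pairs_used": e.n_pairs_used,
                "n_valid": e.n_valid,
                "n_missing": e.n_missing,
                "degenerate": e.degenerate,
                "selected": bool(e.preselected_missingness and e.selected_by_threshold)
                if e.preselected_missingness is not None
                else None,
            }
            for e in effects
        ]
    )
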