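"""Composite moderator: lasso-CV weights, M*, interaction model, subgroups.

The composite moderator ``M*`` is a per-patient weighted sum of the
preselected baseline variables.  The weights come from a lasso regression on
the paired dataset (pair outcome difference regressed on the pair averages of
the preselected variables), with the penalty chosen by k-fold cross-validation
to minimize the mean-squared prediction error (MSPE).  An ordinary
least-squares interaction model on the *unpaired* patients,

    percent_change ~ 1 + M* + T + M* x T,       T = 1 for CBASP,

then yields the cross-point — the M* value where the two arms' predicted
outcomes intersect — which splits the sample into a subgroup likely to
benefit more from ESC/CM and one likely to benefit more from CBASP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .pairing import ModeratorEffect, bootstrap_ci, build_pairs, moderator_effect_size
from .trial_data import ARM_CBASP, ARM_ESC, BaselineVariableSpec, TrialDataset

BENEFIT_ESC = "benefit_ESC_CM"
BENEFIT_CBASP = "benefit_CBASP"


class NoModeratorError(RuntimeError):
    """The cross-validated lasso zeroed every coefficient: no moderator survives."""


class NoQualitativeInteractionError(RuntimeError):
    """Interaction slope indistinguishable from zero: arm lines near-parallel."""


@dataclass
class LassoCVFit:
    """Cross-validated lasso fit on the paired dataset.

    ``coefficients`` are on the original variable scale (the penalty is
    applied to internally standardized predictors); zero means deselected.
    """

    lambda_grid: np.ndarray
    cv_mspe: np.ndarray
    cv_mspe_se: np.ndarray
    lambda_opt: float
    coefficients: dict[str, float]
    intercept: float
    fold_seed: int
    n_pairs_used: int
    rule: str = "min"

    @property
    def nonzero_weights(self) -> dict[str, float]:
        return {k: v for k, v in self.coefficients.items() if v != 0.0}


@dataclass
class InteractionFit:
    """OLS fit of outcome on {1, M*, T, M* x T} over the unpaired patients."""

    beta_intercept: float
    beta_mstar: float
    beta_treatment: float
    beta_interaction: float
    se_interaction: float
    p_interaction: float
    r_squared: float
    outcome_sd: float
    n_patients: int


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    if (scale == 0).any():
        raise ValueError("a selected variable is constant over the complete pairs")
    return (X - mean) / scale, mean, scale


def fit_lasso_cv(
    pairs: pd.DataFrame,
    selected_variables: Sequence[str],
    k: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    rule: str = "min",
) -> LassoCVFit:
    """Lasso with k-fold cross-validation over a log-spaced penalty grid.

    Pair records with any missing selected average are dropped (complete-case,
    as the composite is only computable from complete data anyway).  The grid
    runs from ``lambda_max`` — the smallest penalty that zeroes every
    coefficient — down by ``lambda_min_ratio``.  Folds are a random
    near-equal partition of the pair records given ``seed``.  ``rule`` is
    ``"min"`` (penalty with the smallest MSPE) or ``"1se"`` (largest penalty
    within one standard error of that minimum).
    """
    if not selected_variables:
        raise ValueError("no selected variables to fit")
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    cols = list(selected_variables)
    sub = pairs[["outcome_diff", *cols]].dropna()
    if len(sub) < k:
        raise ValueError(f"{len(sub)} complete pair records < {k} folds")

    X_raw = sub[cols].to_numpy(dtype=float)
    y = sub["outcome_diff"].to_numpy(dtype=float)
    X, x_mean, x_scale = _standardize(X_raw)
    n = len(y)

    # smallest penalty at which every coefficient is zero (sklearn's scaling:
    # objective (1/2n)||y - Xb||^2 + lambda ||b||_1)
    lambda_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    grid = np.geomspace(lambda_max, lambda_max * lambda_min_ratio, n_lambdas)

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    sq_err = np.zeros((k, len(grid)))       # per-fold mean squared prediction error
    fold_sizes = np.zeros(k)
    for f, (tr, te) in enumerate(kf.split(X)):
        Xtr, ytr = X[tr], y[tr]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        # lasso_path fits without an intercept; center by the training means
        _, coefs, _ = lasso_path(Xtr - xm, ytr - ym, alphas=grid)
        pred = (X[te] - xm) @ coefs + ym    # (n_te, n_lambdas)
        sq_err[f] = ((y[te][:, None] - pred) ** 2).mean(axis=0)
        fold_sizes[f] = len(te)
    # MSPE pooled over all held-out points (folds weighted by size)
    cv_mspe = (sq_err * fold_sizes[:, None]).sum(axis=0) / n
    cv_mspe_se = sq_err.std(axis=0, ddof=1) / np.sqrt(k)

    i_min = int(np.argmin(cv_mspe))
    if rule == "min":
        i_opt = i_min
    else:
        within = np.flatnonzero(cv_mspe <= cv_mspe[i_min] + cv_mspe_se[i_min])
        i_opt = int(within.min())  # grid is ordered from largest penalty down
    lambda_opt = float(grid[i_opt])

    beta_std, intercept_std = _fit_at_lambda(X, y, lambda_opt)
    if np.all(beta_std == 0):
        raise NoModeratorError(
            "no moderator survives: lasso zeroed every coefficient at lambda_opt"
        )
    beta = beta_std / x_scale
    intercept = intercept_std - float(beta @ x_mean)
    return LassoCVFit(
        lambda_grid=grid,
        cv_mspe=cv_mspe,
        cv_mspe_se=cv_mspe_se,
        lambda_opt=lambda_opt,
        coefficients={c: float(b) for c, b in zip(cols, beta)},
        intercept=float(intercept),
        fold_seed=seed,
        n_pairs_used=n,
        rule=rule,
    )


def _fit_at_lambda(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    model = Lasso(alpha=lam, fit_intercept=True, max_iter=100_000, tol=1e-10)
    model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_)


def lasso_refit(
    pairs: pd.DataFrame, variables: Sequence[str], lam: float
) -> dict[str, float]:
    """Lasso coefficients (original scale) at a fixed penalty; no CV.

    Useful for inspecting the path; at ``lam`` -> 0 this approaches the OLS
    solution, at ``lam`` >= lambda_max every coefficient is exactly zero.
    """
    cols = list(variables)
    sub = pairs[["outcome_diff", *cols]].dropna()
    X, x_mean, x_scale = _standardize(sub[cols].to_numpy(dtype=float))
    beta_std, _ = _fit_at_lambda(X, sub["outcome_diff"].to_numpy(dtype=float), lam)
    return {c: float(b) for c, b in zip(cols, beta_std / x_scale)}


def compute_m_star(dataset: TrialDataset, weights: Mapping[str, float]) -> pd.Series:
    """Per-patient composite moderator M* = sum_k w_k x_ik (no intercept).

    Only patients with complete data on every weighted variable get a value;
    the rest are excluded (their count is len(dataset) - len(result)).
    """
    if not weights:
        raise ValueError("weights must be nonempty")
    cols = list(weights)
    df = dataset.data
    complete = df[cols].notna().all(axis=1)
    if not complete.any():
        raise ValueError("no patient has complete data on all weighted variables")
    w = np.array([weights[c] for c in cols])
    vals = df.loc[complete, cols].to_numpy(dtype=float) @ w
    return pd.Series(vals, index=df.loc[complete, "patient_id"], name="m_star")


def fit_interaction_model(
    dataset: TrialDataset, outcomes: pd.DataFrame, m_star: pd.Series
) -> InteractionFit:
    """OLS of percent change on {1, M*, T, M* x T} over patients with M*."""
    df = dataset.data.merge(outcomes[["patient_id", "percent_change"]], on="patient_id")
    df = df[df["patient_id"].isin(m_star.index)].copy()
    df["m_star"] = m_star.reindex(df["patient_id"]).to_numpy()
    if len(df) < 4:
        raise ValueError("need >= 4 patients with M* to fit the interaction model")
    t = (df["arm"] == ARM_CBASP).to_numpy(dtype=float)
    if t.min() == t.max():
        raise ValueError("patients with M* must span both arms")
    X = np.column_stack([df["m_star"].to_numpy(), t, df["m_star"].to_numpy() * t])
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    res = sm.OLS(df["percent_change"].to_numpy(), X).fit()
    return InteractionFit(
        beta_intercept=float(res.params[0]),
        beta_mstar=float(res.params[1]),
        beta_treatment=float(res.params[2]),
        beta_interaction=float(res.params[3]),
        se_interaction=float(res.bse[3]),
        p_interaction=float(res.pvalues[3]),
        r_squared=float(res.rsquared),
        outcome_sd=float(np.std(df["percent_change"].to_numpy(), ddof=1)),
        n_patients=len(df),
    )


def composite_effect_size(
    dataset: TrialDataset,
    outcomes: pd.DataFrame,
    m_star: pd.Series,
    n_reps: int = 100,
    seed: int = 0,
) -> ModeratorEffect:
    """Moderator effect size of M* itself, with a percentile bootstrap CI.

    Same contract as the single-variable effect size: M* is attached to the
    patients that have it, all cross-arm pairs are rebuilt, and Spearman rho
    between the pair outcome difference and the pair M* average is computed;
    the bootstrap resamples patients within arms.
    """
    df = dataset.data[dataset.data["patient_id"].isin(m_star.index)].copy()
    df["m_star"] = m_star.reindex(df["patient_id"]).to_numpy()
    specs = dataset.variable_specs + (
        BaselineVariableSpec("m_star", "metric", "composite moderator"),
    )
    ds = TrialDataset(df, variable_specs=specs)
    pairs = build_pairs(ds, outcomes)
    eff = moderator_effect_size(pairs, "m_star")
    if not eff.degenerate:
        eff.ci_low, eff.ci_high = bootstrap_ci(
            ds, outcomes, "m_star", n_reps=n_reps, seed=seed
        )
    eff.n_valid = len(df)
    eff.n_missing = dataset.n_patients - len(df)
    return eff


def find_cross_point(fit: InteractionFit, rel_tol: float = 1e-8) -> float:
    """M* value where the two arms' predicted outcomes intersect.

    The CBASP-minus-ESC/CM predicted contrast is
    ``beta_treatment + beta_interaction * M*``, so the lines cross at
    ``-beta_treatment / beta_interaction``.  An interaction slope smaller
    than ``rel_tol`` times the outcome SD means the lines are near-parallel
    and no qualitative interaction exists.
    """
    if abs(fit.beta_interaction) < rel_tol * fit.outcome_sd:
        raise NoQualitativeInteractionError(
            "no qualitative interaction: predicted arm lines are near-parallel"
        )
    return -fit.beta_treatment / fit.beta_interaction


def assign_subgroups(
    m_star: pd.Series, cross_point: float, beta_interaction: float
) -> pd.Series:
    """Label each patient by the arm their M* side favors.

    The side where the predicted ESC/CM outcome is below (more negative
    percent change than) the predicted CBASP outcome is ``benefit_ESC_CM``;
    the other side is ``benefit_CBASP``.  With the CBASP-minus-ESC/CM
    contrast ``beta_interaction * (M* - cross_point)``, a positive
    interaction slope puts ``benefit_ESC_CM`` above the cross-point and a
    negative slope below it.  Patients exactly at the cross-point go to
    ``benefit_ESC_CM`` by convention.
    """
    contrast = beta_interaction * (m_star.to_numpy() - cross_point)
    # contrast > 0: CBASP predicted outcome higher (worse) => ESC/CM benefits
    labels = np.where(contrast >= 0, BENEFIT_ESC, BENEFIT_CBASP)
    out = pd.Series(labels, index=m_star.index, name="subgroup")
    if out.nunique() == 1:
        import warnings

        warnings.warn(
            f"assign_subgroups: every patient on one side ({out.iloc[0]}); "
            "the other subgroup is empty",
            stacklevel=2,
        )
    return out


@dataclass
class CohensD:
    subgroup: str
    d: float
    ci_low: float
    ci_high: float
    n_esc: int
    n_cbasp: int


def subgroup_cohens_d(
    dataset: TrialDataset, outcomes: pd.DataFrame, subgroup: pd.Series
) -> dict[str, CohensD]:
    """Within-subgroup standardized arm contrast on the percent-change outcome.

    ``d = (mean_ESC/CM - mean_CBASP) / pooled SD`` (same subtraction order as
    the pair outcome difference, so d < 0 means ESC/CM patients improved
    more).  95% CI by the normal approximation
    ``d +/- 1.96 * sqrt((n1+n2)/(n1*n2) + d^2 / (2*(n1+n2)))``.
    """
    df = dataset.data.merge(outcomes[["patient_id", "percent_change"]], on="patient_id")
    df = df[df["patient_id"].isin(subgroup.index)].copy()
    df["subgroup"] = subgroup.reindex(df["patient_id"]).to_numpy()
    results: dict[str, CohensD] = {}
    for name, grp in df.groupby("subgroup"):
        esc = grp.loc[grp["arm"] == ARM_ESC, "percent_change"].to_numpy()
        cb = grp.loc[grp["arm"] == ARM_CBASP, "percent_change"].to_numpy()
        if len(esc) < 2 or len(cb) < 2:
            import warnings

            warnings.warn(
                f"subgroup_cohens_d: {name} lacks >= 2 patients in each arm; d undefined",
                stacklevel=2,
            )
            continue
        n1, n2 = len(esc), len(cb)
        pooled_var = ((n1 - 1) * esc.var(ddof=1) + (n2 - 1) * cb.var(ddof=1)) / (n1 + n2 - 2)
        d = (esc.mean() - cb.mean()) / np.sqrt(pooled_var)
        se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
        results[str(name)] = CohensD(
            subgroup=str(name),
            d=float(d),
            ci_low=float(d - 1.96 * se),
            ci_high=float(d + 1.96 * se),
            n_esc=n1,
            n_cbasp=n2,
        )
    return results
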