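"""Lasso-CV, M*, interaction model, cross-point and subgroup machinery."""

import numpy as np
import pandas as pd
import pytest

from modstar import (
    GeneratorConfig,
    NoQualitativeInteractionError,
    assign_subgroups,
    build_pairs,
    classify_outcomes,
    composite_effect_size,
    compute_m_star,
    find_cross_point,
    fit_interaction_model,
    fit_lasso_cv,
    generate_trial,
    lasso_refit,
    moderator_effect_size,
    subgroup_cohens_d,
)
from modstar.composite import BENEFIT_CBASP, BENEFIT_ESC, InteractionFit

from conftest import make_trial


@pytest.fixture(scope="module")
def trial_pairs(default_trial, default_outcomes):
    return build_pairs(default_trial, default_outcomes)


SELECTED = ["age", "childhood_trauma", "adverse_life_events", "female", "early_onset"]


def test_large_penalty_zeroes_everything(trial_pairs):
    coefs = lasso_refit(trial_pairs, SELECTED, lam=1e6)
    assert all(v == 0.0 for v in coefs.values())


def test_grid_top_is_exact_null_model(trial_pairs):
    """The first grid point is lambda_max: the smallest penalty at which the
    lasso model is empty."""
    fit = fit_lasso_cv(trial_pairs, SELECTED, k=10, seed=0)
    at_max = lasso_refit(trial_pairs, SELECTED, lam=float(fit.lambda_grid[0]))
    assert all(abs(v) < 1e-10 for v in at_max.values())
    just_below = lasso_refit(trial_pairs, SELECTED, lam=float(fit.lambda_grid[0]) * 0.99)
    assert any(v != 0.0 for v in just_below.values())


def test_vanishing_penalty_recovers_ols(trial_pairs):
    """As the penalty goes to zero the lasso solution converges to ordinary
    least squares on the same pair records."""
    sub = trial_pairs[["outcome_diff", *SELECTED]].dropna()
    X = np.column_stack([np.ones(len(sub)), sub[SELECTED].to_numpy(float)])
    beta_ols = np.linalg.lstsq(X, sub["outcome_diff"].to_numpy(float), rcond=None)[0]
    near_zero = lasso_refit(trial_pairs, SELECTED, lam=1e-10)
    np.testing.assert_allclose(
        [near_zero[v] for v in SELECTED], beta_ols[1:], rtol=1e-5, atol=1e-6
    )


def test_cv_fit_structure(trial_pairs):
    fit = fit_lasso_cv(trial_pairs, SELECTED, k=10, seed=0)
    assert fit.cv_mspe[np.argmin(fit.cv_mspe)] == fit.cv_mspe.min()
    assert fit.lambda_opt == fit.lambda_grid[np.argmin(fit.cv_mspe)]
    assert set(fit.coefficients) == set(SELECTED)
    assert fit.n_pairs_used == len(trial_pairs[["outcome_diff", *SELECTED]].dropna())
    # determinism in the fold seed
    again = fit_lasso_cv(trial_pairs, SELECTED, k=10, seed=0)
    np.testing.assert_array_equal(fit.cv_mspe, again.cv_mspe)
    assert fit.coefficients == again.coefficients


def test_one_se_rule_picks_larger_penalty(trial_pairs):
    f_min = fit_lasso_cv(trial_pairs, SELECTED, k=10, seed=0, rule="min")
    f_1se = fit_lasso_cv(trial_pairs, SELECTED, k=10, seed=0, rule="1se")
    assert f_1se.lambda_opt >= f_min.lambda_opt


def test_cv_errors(trial_pairs):
    with pytest.raises(ValueError, match="folds"):
        fit_lasso_cv(trial_pairs.head(5), SELECTED, k=10, seed=0)
    with pytest.raises(ValueError):
        fit_lasso_cv(trial_pairs, [], k=10, seed=0)


def test_true_moderators_selected_over_noise():
    """Two planted moderators among eleven variables: the CV lasso puts
    nonzero weight on both planted variables and zero on most noise."""
    cfg = GeneratorConfig(seed=4, delta={"age": 1.5, "childhood_trauma": 30.0},
                          gamma={}, tau=-80.0, noise_sd=5.0, missing_rate=0.0)
    ds = generate_trial(cfg)
    out = classify_outcomes(ds)
    pairs = build_pairs(ds, out)
    fit = fit_lasso_cv(pairs, list(ds.variable_names), k=10, seed=4)
    w = fit.nonzero_weights
    assert "age" in w and "childhood_trauma" in w
    # planted weights carry the right sign: positive delta favors ESC/CM,
    # so the pair-difference regression sees a negative slope
    assert w["age"] < 0 and w["childhood_trauma"] < 0


def test_m_star_identity_and_exclusions(default_trial):
    m = compute_m_star(default_trial, {"age": 1.0})
    expect = default_trial.data.set_index("patient_id")["age"]
    pd.testing.assert_series_equal(m, expect.rename("m_star"), check_names=True)

    df = default_trial.data.copy()
    df.loc[df.index[:3], "age"] = np.nan
    ds = type(default_trial)(df, variable_specs=default_trial.variable_specs)
    m2 = compute_m_star(ds, {"age": 2.0, "female": -5.0})
    assert len(m2) == 50  # 53 completers, 3 missing a weighted variable

    with pytest.raises(ValueError):
        compute_m_star(default_trial, {})


def test_m_star_hand_dot_product():
    """Published weights applied to one constructed patient reproduce the
    hand-computed weighted sum."""
    weights = {
        "age": 2.817, "female": -31.344, "childhood_trauma": -65.803,
        "suicide_attempts": -8.806, "adverse_life_events": -9.782,
        "early_onset": 56.434, "prev_antidepressants": 12.629,
    }
    ds = make_trial([
        {"arm": "CBASP", "base": 25, "week8": 18, "age": 40, "female": 1,
         "childhood_trauma": 1, "suicide_attempts": 1, "adverse_life_events": 2,
         "early_onset": 0, "prev_antidepressants": 1},
    ])
    m = compute_m_star(ds, weights)
    # 2.817*40 - 31.344 - 65.803 - 8.806 - 9.782*2 + 0 + 12.629 = -0.208
    assert m.iloc[0] == pytest.approx(-0.208, abs=1e-9)


def test_interaction_exact_recovery(default_trial, default_outcomes):
    """Outcome constructed exactly as a + b*M* + c*T + d*M**T is recovered
    to numerical precision with R^2 = 1."""
    m = compute_m_star(default_trial, {"age": 1.0, "adverse_life_events": 3.0})
    df = default_trial.data.set_index("patient_id")
    t = (df["arm"] == "CBASP").astype(float)
    y = 5.0 + 0.4 * m - 30.0 * t + 0.9 * m * t
    outcomes = pd.DataFrame({"patient_id": m.index, "percent_change": y.to_numpy()})
    fit = fit_interaction_model(default_trial, outcomes, m)
    assert fit.beta_intercept == pytest.approx(5.0, abs=1e-8)
    assert fit.beta_mstar == pytest.approx(0.4, abs=1e-9)
    assert fit.beta_treatment == pytest.approx(-30.0, abs=1e-8)
    assert fit.beta_interaction == pytest.approx(0.9, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_interaction_null_case():
    """With no generated interaction the fitted interaction stays small."""
    tstats = []
    for seed in range(5):
        ds = generate_trial(GeneratorConfig(seed=seed, delta={}, gamma={},
                                            tau=-10.0, noise_sd=20.0,
                                            missing_rate=0.0))
        out = classify_outcomes(ds)
        m = compute_m_star(ds, {"age": 1.0})
        fit = fit_interaction_model(ds, out, m)
        tstats.append(abs(fit.beta_interaction) / fit.se_interaction)
    assert np.mean(tstats) < 2.0


def test_interaction_matches_normal_equations(default_trial, default_outcomes):
    """Six-patient toy agrees with a direct normal-equations solve."""
    ds = make_trial(
        [
            {"arm": "CBASP", "base": 30, "week8": 10, "age": 25},
            {"arm": "CBASP", "base": 30, "week8": 20, "age": 35},
            {"arm": "CBASP", "base": 30, "week8": 30, "age": 45},
            {"arm": "ESC_CM", "base": 30, "week8": 12, "age": 28},
            {"arm": "ESC_CM", "base": 30, "week8": 18, "age": 38},
            {"arm": "ESC_CM", "base": 30, "week8": 33, "age": 48},
        ]
    )
    out = classify_outcomes(ds)
    m = compute_m_star(ds, {"age": 1.0})
    fit = fit_interaction_model(ds, out, m)

    df = ds.data.merge(out[["patient_id", "percent_change"]], on="patient_id")
    t = (df["arm"] == "CBASP").to_numpy(float)
    X = np.column_stack([np.ones(6), df["age"], t, df["age"] * t])
    y = df["percent_change"].to_numpy()
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert fit.beta_intercept == pytest.approx(beta[0], abs=1e-9)
    assert fit.beta_mstar == pytest.approx(beta[1], abs=1e-9)
    assert fit.beta_treatment == pytest.approx(beta[2], abs=1e-9)
    assert fit.beta_interaction == pytest.approx(beta[3], abs=1e-9)


def test_interaction_preconditions(default_trial, default_outcomes):
    m = compute_m_star(default_trial, {"age": 1.0})
    with pytest.raises(ValueError, match=">= 4"):
        fit_interaction_model(default_trial, default_outcomes, m.head(3))
    one_arm = m[default_trial.data.set_index("patient_id")["arm"] == "CBASP"]
    with pytest.raises(ValueError, match="both arms"):
        fit_interaction_model(default_trial, default_outcomes, one_arm)


def test_composite_effect_reduces_to_single_variable(default_trial, default_outcomes):
    """M* proportional to one variable has that variable's rho (rank
    invariance under positive scaling)."""
    pairs = build_pairs(default_trial, default_outcomes)
    rho_age = moderator_effect_size(pairs, "age").rho
    m = compute_m_star(default_trial, {"age": 2.5})
    eff = composite_effect_size(default_trial, default_outcomes, m, n_reps=20, seed=0)
    assert eff.rho == pytest.approx(rho_age, abs=1e-12)
    assert eff.ci_low is not None and eff.ci_low <= eff.ci_high


@pytest.mark.parametrize(
    "beta_t, beta_i, expected",
    [(0.0, 2.0, 0.0), (-10.0, 0.5, 20.0)],
)
def test_cross_point_arithmetic(beta_t, beta_i, expected):
    fit = InteractionFit(
        beta_intercept=1.0, beta_mstar=0.2, beta_treatment=beta_t,
        beta_interaction=beta_i, se_interaction=0.1, p_interaction=0.01,
        r_squared=0.5, outcome_sd=30.0, n_patients=50,
    )
    assert find_cross_point(fit) == pytest.approx(expected)


def test_cross_point_self_consistency():
    """At the returned M* the two arms' predicted outcomes coincide."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        b0, b1, bt, bi = rng.normal(0, 10, 4)
        if abs(bi) < 1e-3:
            continue
        fit = InteractionFit(b0, b1, bt, bi, 0.1, 0.01, 0.5, 30.0, 50)
        c = find_cross_point(fit)
        pred_esc = b0 + b1 * c
        pred_cbasp = b0 + b1 * c + bt + bi * c
        assert abs(pred_esc - pred_cbasp) < 1e-9 * max(1.0, abs(pred_esc))


def test_near_parallel_lines_rejected():
    fit = InteractionFit(0.0, 1.0, -10.0, 1e-12, 0.1, 0.9, 0.5, 30.0, 50)
    with pytest.raises(NoQualitativeInteractionError):
        find_cross_point(fit)


def test_subgroup_assignment_consistent_with_lines():
    """Every patient's label equals the arm with the lower (better)
    predicted percent change at their M*, for both interaction signs."""
    m = pd.Series([0.0, 10.0, 20.0, 30.0], index=list("abcd"))
    for bi in (1.5, -1.5):
        cross = 15.0
        sg = assign_subgroups(m, cross, bi)
        for pid, mv in m.items():
            contrast = bi * (mv - cross)  # CBASP minus ESC/CM prediction
            better_esc = contrast >= 0
            assert (sg[pid] == BENEFIT_ESC) == better_esc


def test_subgroup_boundary_and_single_side():
    m = pd.Series([5.0, 10.0], index=["a", "b"])
    sg = assign_subgroups(m, 5.0, 2.0)
    assert sg["a"] == BENEFIT_ESC  # exactly at the cross-point, by convention
    with pytest.warns(UserWarning, match="one side"):
        assign_subgroups(pd.Series([1.0, 2.0], index=["a", "b"]), 0.0, 2.0)


def test_weight_scaling_equivariance(default_trial, default_outcomes):
    """Scaling all weights by c > 0 scales M* and the cross-point by c and
    leaves the subgroup assignment unchanged."""
    w = {"age": 1.2, "childhood_trauma": -20.0}
    c = 3.7
    m1 = compute_m_star(default_trial, w)
    m2 = compute_m_star(default_trial, {k: c * v for k, v in w.items()})
    np.testing.assert_allclose(m2.to_numpy(), c * m1.to_numpy(), rtol=1e-12)
    f1 = fit_interaction_model(default_trial, default_outcomes, m1)
    f2 = fit_interaction_model(default_trial, default_outcomes, m2)
    c1, c2 = find_cross_point(f1), find_cross_point(f2)
    assert c2 == pytest.approx(c * c1, rel=1e-9)
    s1 = assign_subgroups(m1, c1, f1.beta_interaction)
    s2 = assign_subgroups(m2, c2, f2.beta_interaction)
    assert (s1 == s2).all()


def test_cohens_d_examples(default_trial):
    """d = 0 for identical arm distributions; a constructed -50 vs 0 contrast
    with common SD 25 gives exactly d = -2; a 4+4 toy matches the hand
    pooled-SD formula."""
    base = np.array([-1.2, -0.6, 0.3, 1.5])
    z = (base - base.mean()) / base.std(ddof=1)  # exact mean 0, sd 1

    def trial_from(esc_vals, cb_vals):
        recs = []
        for i, v in enumerate(esc_vals):
            recs.append({"id": f"E{i}", "arm": "ESC_CM", "base": 100,
                         "week8": 100 + v})
        for i, v in enumerate(cb_vals):
            recs.append({"id": f"C{i}", "arm": "CBASP", "base": 100,
                         "week8": 100 + v})
        ds = make_trial(recs)
        out = classify_outcomes(ds)
        sg = pd.Series(["g"] * len(recs), index=out["patient_id"])
        return subgroup_cohens_d(ds, out, sg)["g"]

    same = trial_from(base, base)
    assert same.d == pytest.approx(0.0, abs=1e-12)

    v = np.arange(10, dtype=float)
    z10 = (v - v.mean()) / v.std(ddof=1)  # exact sample mean 0, sample SD 1
    res = trial_from(-50 + 25 * z10, 0 + 25 * z10)
    # both arms have sample SD exactly 25 and means -50 / 0
    assert res.d == pytest.approx(-2.0, abs=1e-9)

    esc = np.array([-40.0, -20.0, -10.0, -30.0])
    cb = np.array([5.0, -5.0, 15.0, 25.0])
    got = trial_from(esc, cb)
    sp = np.sqrt((3 * esc.var(ddof=1) + 3 * cb.var(ddof=1)) / 6)
    d_hand = (esc.mean() - cb.mean()) / sp
    se_hand = np.sqrt(8 / 16 + d_hand**2 / 16)
    assert got.d == pytest.approx(d_hand, abs=1e-12)
    assert got.ci_low == pytest.approx(d_hand - 1.96 * se_hand, abs=1e-12)
    assert got.ci_high == pytest.approx(d_hand + 1.96 * se_hand, abs=1e-12)
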