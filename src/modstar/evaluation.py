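"""Cluster stratification, matched/mismatched pooling, subgroup comparisons.

Crossing the two composite-moderator subgroups with the two randomized arms
gives four clusters; patients treated with the arm their subgroup favors are
*matched*, the rest *mismatched*.  Cluster summaries are plain summary
statistics (n, means, SDs, response/remission rates) and pooling works on
those summaries alone, so pooled rows can be recomputed either from patient
level data or from an already-printed per-cluster table — the two routes
agree exactly by the usual within-plus-between variance decomposition.

Subgroup baseline comparisons follow the convention: metric variables get a
pooled-variance (Student) two-sample t test and CI; dichotomous variables get
a Wald CI on the difference in proportions and a two-sided Fisher exact p;
ordinal treatment-history variables are dichotomized at >= 1 first.
Differences are reported as (ESC/CM-benefit subgroup) minus (CBASP-benefit
subgroup).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .composite import BENEFIT_CBASP, BENEFIT_ESC
from .trial_data import ARM_CBASP, ARM_ESC, TrialDataset

# cluster labels: Be<benefit arm>|Tr<treatment arm>
CL_ESC_ESC = "BeESC_TrESC"
CL_CBASP_CBASP = "BeCBASP_TrCBASP"
CL_CBASP_ESC = "BeCBASP_TrESC"
CL_ESC_CBASP = "BeESC_TrCBASP"
MATCHED_CLUSTERS = (CL_ESC_ESC, CL_CBASP_CBASP)
MISMATCHED_CLUSTERS = (CL_CBASP_ESC, CL_ESC_CBASP)
ALL_CLUSTERS = (CL_ESC_ESC, CL_CBASP_CBASP, CL_CBASP_ESC, CL_ESC_CBASP)


@dataclass
class ClusterSummary:
    """Outcome summary for one subgroup x treatment cluster (or a pool)."""

    cluster: str
    n: int
    madrs_baseline_mean: float | None = None
    madrs_baseline_sd: float | None = None
    madrs_week8_mean: float | None = None
    madrs_week8_sd: float | None = None
    pct_change_mean: float | None = None
    pct_change_sd: float | None = None
    response_rate: float | None = None  # percent
    remission_rate: float | None = None  # percent


@dataclass
class SubgroupComparison:
    variable: str
    summary_esc_benefit: str
    summary_cbasp_benefit: str
    difference: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    test: str


def stratify_clusters(dataset: TrialDataset, subgroup: pd.Series) -> pd.Series:
    """Per-patient cluster label from (benefit subgroup, randomized arm)."""
    df = dataset.data[dataset.data["patient_id"].isin(subgroup.index)]
    sg = subgroup.reindex(df["patient_id"]).to_numpy()
    arm = df["arm"].to_numpy()
    labels = np.empty(len(df), dtype=object)
    labels[(sg == BENEFIT_ESC) & (arm == ARM_ESC)] = CL_ESC_ESC
    labels[(sg == BENEFIT_CBASP) & (arm == ARM_CBASP)] = CL_CBASP_CBASP
    labels[(sg == BENEFIT_CBASP) & (arm == ARM_ESC)] = CL_CBASP_ESC
    labels[(sg == BENEFIT_ESC) & (arm == ARM_CBASP)] = CL_ESC_CBASP
    return pd.Series(labels, index=df["patient_id"], name="cluster")


def is_matched(clusters: pd.Series) -> pd.Series:
    """True where the patient received the arm their subgroup favors."""
    return clusters.isin(MATCHED_CLUSTERS).rename("matched")


def _mean_sd(vals: np.ndarray) -> tuple[float, float | None]:
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    return mean, sd


def cluster_outcomes(
    dataset: TrialDataset, outcomes: pd.DataFrame, clusters: pd.Series
) -> list[ClusterSummary]:
    """Per-cluster summary of baseline/week-8 MADRS, percent change and rates."""
    df = dataset.data.merge(outcomes, on="patient_id")
    df = df[df["patient_id"].isin(clusters.index)].copy()
    df["cluster"] = clusters.reindex(df["patient_id"]).to_numpy()
    summaries = []
    for name in ALL_CLUSTERS:
        grp = df[df["cluster"] == name]
        if len(grp) == 0:
            summaries.append(ClusterSummary(cluster=name, n=0))
            continue
        b_mean, b_sd = _mean_sd(grp["madrs_baseline"].to_numpy())
        w_mean, w_sd = _mean_sd(grp["madrs_week8"].to_numpy())
        c_mean, c_sd = _mean_sd(grp["percent_change"].to_numpy())
        summaries.append(
            ClusterSummary(
                cluster=name,
                n=len(grp),
                madrs_baseline_mean=b_mean,
                madrs_baseline_sd=b_sd,
                madrs_week8_mean=w_mean,
                madrs_week8_sd=w_sd,
                pct_change_mean=c_mean,
                pct_change_sd=c_sd,
                response_rate=100.0 * grp["responder"].mean(),
                remission_rate=100.0 * grp["remitter"].mean(),
            )
        )
    return summaries


def pool_summaries(summaries: list[ClusterSummary], name: str) -> ClusterSummary:
    """Pool cluster summaries from their summary statistics alone.

    Means and rates pool n-weighted; SDs combine within- and between-cluster
    variance: ``s^2 = [sum (n_i-1) s_i^2 + sum n_i (m_i - m)^2] / (N - 1)``.
    This reproduces the direct patient-level computation exactly, so it can
    equally be fed already-tabulated per-cluster rows.
    """
    parts = [s for s in summaries if s.n > 0]
    n_total = sum(s.n for s in parts)
    if n_total == 0:
        return ClusterSummary(cluster=name, n=0)

    def pool_stat(attr_mean: str, attr_sd: str) -> tuple[float | None, float | None]:
        vals = [(s.n, getattr(s, attr_mean), getattr(s, attr_sd)) for s in parts]
        if any(m is None for _, m, _ in vals):
            return None, None
        mean = sum(n * m for n, m, _ in vals) / n_total
        if n_total < 2:
            return mean, None
        ss = sum((n - 1) * (sd**2 if sd is not None else 0.0) for n, _, sd in vals)
        ss += sum(n * (m - mean) ** 2 for n, m, _ in vals)
        return mean, math.sqrt(ss / (n_total - 1))

    def pool_rate(attr: str) -> float | None:
        vals = [(s.n, getattr(s, attr)) for s in parts]
        if any(r is None for _, r in vals):
            return None
        return sum(n * r for n, r in vals) / n_total

    b_mean, b_sd = pool_stat("madrs_baseline_mean", "madrs_baseline_sd")
    w_mean, w_sd = pool_stat("madrs_week8_mean", "madrs_week8_sd")
    c_mean, c_sd = pool_stat("pct_change_mean", "pct_change_sd")
    return ClusterSummary(
        cluster=name,
        n=n_total,
        madrs_baseline_mean=b_mean,
        madrs_baseline_sd=b_sd,
        madrs_week8_mean=w_mean,
        madrs_week8_sd=w_sd,
        pct_change_mean=c_mean,
        pct_change_sd=c_sd,
        response_rate=pool_rate("response_rate"),
        remission_rate=pool_rate("remission_rate"),
    )


def matched_mismatched_summaries(
    summaries: list[ClusterSummary],
) -> tuple[ClusterSummary, ClusterSummary]:
    """Pooled rows for the matched and mismatched treatment pools."""
    by_name = {s.cluster: s for s in summaries}
    matched = pool_summaries([by_name[c] for c in MATCHED_CLUSTERS if c in by_name], "matched")
    mismatched = pool_summaries(
        [by_name[c] for c in MISMATCHED_CLUSTERS if c in by_name], "mismatched"
    )
    return matched, mismatched


# -- subgroup baseline comparisons ----------------------------------------

def pooled_t_comparison(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, alpha: float = 0.05
) -> tuple[float, float, float, float]:
    """Two-sample pooled-variance (Student) t comparison from summary stats.

    Returns (difference m1-m2, ci_low, ci_high, two-sided p).
    """
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = m1 - m2
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    tstat = diff / se if se > 0 else math.inf
    p = 2 * stats.t.sf(abs(tstat), df)
    return diff, diff - tcrit * se, diff + tcrit * se, p


def proportion_comparison(
    k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05
) -> tuple[float, float, float, float]:
    """Difference in proportions (percent points) with Wald CI and Fisher p.

    Returns (difference, ci_low, ci_high, p) where difference = 100*(k1/n1 -
    k2/n2).  The CI is the Wald normal-approximation interval; the p-value is
    the two-sided Fisher exact test (point-probability method).
    """
    p1, p2 = k1 / n1, k2 / n2
    diff = 100.0 * (p1 - p2)
    z = stats.norm.ppf(1 - alpha / 2)
    se = 100.0 * math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
    return diff, diff - z * se, diff + z * se, float(p)


def compare_subgroup_baselines(
    dataset: TrialDataset, subgroup: pd.Series
) -> list[SubgroupComparison]:
    """Baseline comparison table between the two benefit subgroups.

    Metric variables: pooled-variance t test on the non-missing values.
    Nominal variables: proportion difference with Fisher exact p.  Ordinal
    treatment-history variables: dichotomized at >= 1 previous treatment.
    """
    df = dataset.data[dataset.data["patient_id"].isin(subgroup.index)].copy()
    df["subgroup"] = subgroup.reindex(df["patient_id"]).to_numpy()
    g_esc = df[df["subgroup"] == BENEFIT_ESC]
    g_cb = df[df["subgroup"] == BENEFIT_CBASP]
    if len(g_esc) == 0 or len(g_cb) == 0:
        raise ValueError("both benefit subgroups must be non-empty")

    out: list[SubgroupComparison] = []
    for spec in dataset.variable_specs:
        a = g_esc[spec.name].dropna().to_numpy(dtype=float)
        b = g_cb[spec.name].dropna().to_numpy(dtype=float)
        if spec.kind == "metric":
            if len(a) > 1 and len(b) > 1 and (np.std(a) > 0 or np.std(b) > 0):
                diff, lo, hi, p = pooled_t_comparison(
                    a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
                )
                out.append(
                    SubgroupComparison(
                        variable=spec.name,
                        summary_esc_benefit=f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                        summary_cbasp_benefit=f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                        difference=diff, ci_low=lo, ci_high=hi, p_value=p,
                        test="two-sample-t",
                    )
                )
            else:
                out.append(
                    SubgroupComparison(
                        variable=spec.name,
                        summary_esc_benefit=f"{a.mean():.1f}" if len(a) else "-",
                        summary_cbasp_benefit=f"{b.mean():.1f}" if len(b) else "-",
                        difference=float(a.mean() - b.mean()) if len(a) and len(b) else float("nan"),
                        ci_low=None, ci_high=None, p_value=None,
                        test="none (zero variance or too few values)",
                    )
                )
        else:
            # nominal as-is; ordinal dichotomized at >= 1 previous treatment
            ka = int((a >= 1).sum()) if spec.kind == "ordinal" else int(a.sum())
            kb = int((b >= 1).sum()) if spec.kind == "ordinal" else int(b.sum())
            diff, lo, hi, p = proportion_comparison(ka, len(a), kb, len(b))
            out.append(
                SubgroupComparison(
                    variable=spec.name if spec.kind == "nominal" else f"{spec.name}>=1",
                    summary_esc_benefit=f"{100 * ka / len(a):.1f}%",
                    summary_cbasp_benefit=f"{100 * kb / len(b):.1f}%",
                    difference=diff, ci_low=lo, ci_high=hi, p_value=p,
                    test="Fisher-exact",
                )
            )
    return out


# -- augmentation sub-analysis --------------------------------------------

@dataclass
class AugmentationSummary:
    """Who the augmentation candidates (non-improvers at week 8) were."""

    n_candidates: int
    n_mismatched: int
    n_matched: int
    share_mismatched: float | None  # percent

    @property
    def empty(self) -> bool:
        return self.n_candidates == 0


def augmentation_analysis(
    outcomes: pd.DataFrame, clusters: pd.Series
) -> AugmentationSummary:
    """Among non-improvers (< 20.0% reduction), how many were mismatched.

    In the source trial these patients had the other treatment added after
    week 8; the question is whether their non-improvement reflects having
    started on their likely less beneficial arm.
    """
    df = outcomes[outcomes["patient_id"].isin(clusters.index)].copy()
    df["matched"] = is_matched(clusters).reindex(df["patient_id"]).to_numpy()
    cand = df[~df["improver_20pct"]]
    n = len(cand)
    if n == 0:
        return AugmentationSummary(0, 0, 0, None)
    n_mis = int((~cand["matched"]).sum())
    return AugmentationSummary(
        n_candidates=n,
        n_mismatched=n_mis,
        n_matched=n - n_mis,
        share_mismatched=100.0 * n_mis / n,
    )


# -- exports ---------------------------------------------------------------

def summaries_frame(summaries: list[ClusterSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def comparisons_frame(comparisons: list[SubgroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in comparisons])
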