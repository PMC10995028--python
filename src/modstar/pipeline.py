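"""End-to-end pipeline: data in, moderation analysis out, reports written.

`run_pipeline` chains every stage — completer filtering, outcome
classification, distribution screening, pairwise effect sizes with bootstrap
CIs, preselection, lasso-CV, M*, interaction model, cross-point, subgroups,
cluster summaries, baseline comparisons and the augmentation sub-analysis —
and writes the report bundle (effect-size table, subgroup comparison table,
cluster outcome table, model report JSON, log).  Three independent seeds
control the three stochastic stages: trial generation, the bootstrap, and
the cross-validation fold partition.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import composite, evaluation, pairing, trial_data
from .synthetic import GeneratorConfig, generate_trial
from .trial_data import TrialDataset

logger = logging.getLogger("modstar")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; defaults are the method's stated settings."""

    input_csv: str | Path | None = None
    column_map: dict[str, str] | None = None
    arm_labels: dict[str, str] | None = None
    generator: GeneratorConfig | None = None

    threshold: float = 0.20        # |rho| preselection cutoff (inclusive)
    min_valid: int = 50            # preselection: minimum valid cases, OR
    max_missing: int = 3           # ... at most this many missing cases
    n_bootstrap: int = 100         # bootstrap replications for every CI
    k_folds: int = 10              # cross-validation folds
    lambda_rule: str = "min"       # "min" = smallest MSPE; "1se" optional

    bootstrap_seed: int = 0
    fold_seed: int = 0

    output_dir: str | Path | None = None
    make_plot: bool = False

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError("provide exactly one of input_csv or generator")


@dataclass
class PipelineResult:
    """Everything a run produced, stage by stage."""

    dataset: TrialDataset
    outcomes: pd.DataFrame
    screen: pd.DataFrame
    effects: list[pairing.ModeratorEffect]
    selected: list[str]
    lasso_fit: composite.LassoCVFit
    m_star: pd.Series
    interaction: composite.InteractionFit
    composite_effect: pairing.ModeratorEffect
    cross_point: float
    subgroup: pd.Series
    cohens_d: dict[str, composite.CohensD]
    clusters: pd.Series
    cluster_summaries: list[evaluation.ClusterSummary]
    matched_summary: evaluation.ClusterSummary
    mismatched_summary: evaluation.ClusterSummary
    comparisons: list[evaluation.SubgroupComparison]
    augmentation: evaluation.AugmentationSummary
    counts: dict[str, int] = field(default_factory=dict)

    def model_report(self) -> dict[str, Any]:
        """JSON-ready summary of the fitted composite moderator model."""
        return {
            "lasso": {
                "lambda_opt": self.lasso_fit.lambda_opt,
                "rule": self.lasso_fit.rule,
                "n_pairs_used": self.lasso_fit.n_pairs_used,
                "weights": self.lasso_fit.nonzero_weights,
                "intercept": self.lasso_fit.intercept,
                "mspe_curve": {
                    "lambda": self.lasso_fit.lambda_grid.tolist(),
                    "mspe": self.lasso_fit.cv_mspe.tolist(),
                },
            },
            "composite_effect_size": {
                "rho": self.composite_effect.rho,
                "ci_low": self.composite_effect.ci_low,
                "ci_high": self.composite_effect.ci_high,
            },
            "interaction": dataclasses.asdict(self.interaction),
            "cross_point": self.cross_point,
            "subgroup_sizes": self.subgroup.value_counts().to_dict(),
            "cohens_d": {k: dataclasses.asdict(v) for k, v in self.cohens_d.items()},
            "augmentation": dataclasses.asdict(self.augmentation),
            "counts": self.counts,
        }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full moderation analysis; see the module docstring.

    Raises the underlying stage error (e.g. ``NoModeratorError`` when the
    cross-validated lasso deselects everything) with the stage logged.
    """
    counts: dict[str, int] = {}

    if config.generator is not None:
        logger.info("generating synthetic trial (seed=%d)", config.generator.seed)
        dataset = generate_trial(config.generator)
    else:
        logger.info("reading trial table from %s", config.input_csv)
        dataset = trial_data.read_trial_csv(
            config.input_csv, column_map=config.column_map, arm_labels=config.arm_labels
        )
    counts["input_patients"] = dataset.n_patients

    dataset = trial_data.filter_completers(dataset)
    counts["completers"] = dataset.n_patients
    counts["non_completers_excluded"] = counts["input_patients"] - counts["completers"]
    logger.info(
        "completers: %d (%s); excluded without week-8 score: %d",
        counts["completers"], dataset.arm_counts(), counts["non_completers_excluded"],
    )

    outcomes = trial_data.classify_outcomes(dataset)
    screen = pairing.screen_distributions(dataset)
    for row in screen.itertuples():
        if row.n_outliers:
            logger.warning(
                "outlier screen: %s has %d value(s) with |z| > 3 (%s) — diagnostic only",
                row.variable, row.n_outliers, row.outlier_ids,
            )

    logger.info("computing pairwise moderator effect sizes (bootstrap reps=%d)",
                config.n_bootstrap)
    effects = pairing.compute_all_effects(
        dataset, outcomes, n_reps=config.n_bootstrap, seed=config.bootstrap_seed
    )
    selected = pairing.preselect_variables(
        dataset, effects,
        threshold=config.threshold,
        min_valid=config.min_valid,
        max_missing=config.max_missing,
    )
    logger.info("preselected %d/%d variables: %s", len(selected), len(effects), selected)
    if not selected:
        raise composite.NoModeratorError(
            "stage preselection: no variable reaches the effect-size threshold"
        )

    pairs = pairing.build_pairs(dataset, outcomes)
    counts["pairs"] = len(pairs)
    lasso_fit = composite.fit_lasso_cv(
        pairs, selected, k=config.k_folds, seed=config.fold_seed, rule=config.lambda_rule
    )
    logger.info("lasso-CV: lambda_opt=%.4g, nonzero weights=%s",
                lasso_fit.lambda_opt, lasso_fit.nonzero_weights)

    m_star = composite.compute_m_star(dataset, lasso_fit.nonzero_weights)
    counts["with_m_star"] = len(m_star)
    counts["excluded_missing_m_star"] = dataset.n_patients - len(m_star)
    logger.info("M* calculable for %d patients (%d excluded for missing values)",
                counts["with_m_star"], counts["excluded_missing_m_star"])

    interaction = composite.fit_interaction_model(dataset, outcomes, m_star)
    composite_effect = composite.composite_effect_size(
        dataset, outcomes, m_star, n_reps=config.n_bootstrap, seed=config.bootstrap_seed
    )
    cross_point = composite.find_cross_point(interaction)
    subgroup = composite.assign_subgroups(m_star, cross_point, interaction.beta_interaction)
    logger.info("cross-point %.3f; subgroups: %s", cross_point,
                subgroup.value_counts().to_dict())

    cohens = composite.subgroup_cohens_d(dataset, outcomes, subgroup)
    clusters = evaluation.stratify_clusters(dataset, subgroup)
    cluster_summaries = evaluation.cluster_outcomes(dataset, outcomes, clusters)
    matched, mismatched = evaluation.matched_mismatched_summaries(cluster_summaries)
    comparisons = evaluation.compare_subgroup_baselines(dataset, subgroup)
    augmentation = evaluation.augmentation_analysis(outcomes, clusters)

    result = PipelineResult(
        dataset=dataset, outcomes=outcomes, screen=screen, effects=effects,
        selected=selected, lasso_fit=lasso_fit, m_star=m_star,
        interaction=interaction, composite_effect=composite_effect,
        cross_point=cross_point, subgroup=subgroup, cohens_d=cohens,
        clusters=clusters, cluster_summaries=cluster_summaries,
        matched_summary=matched, mismatched_summary=mismatched,
        comparisons=comparisons, augmentation=augmentation, counts=counts,
    )
    if config.output_dir is not None:
        write_reports(result, config)
    return result


def _round_frame(df: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    return out


def write_reports(result: PipelineResult, config: PipelineConfig) -> dict[str, Path]:
    """Write the report bundle; returns the paths written.

    Tables are rounded to one decimal for display; the JSON model report
    keeps full precision.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    effects_df = pairing.effects_table(result.effects)
    paths["effects"] = outdir / "moderator_effects.csv"
    _round_frame(effects_df, 3).to_csv(paths["effects"], index=False)

    comp_df = evaluation.comparisons_frame(result.comparisons)
    paths["comparisons"] = outdir / "subgroup_comparison.csv"
    _round_frame(comp_df).to_csv(paths["comparisons"], index=False)

    rows = result.cluster_summaries + [result.matched_summary, result.mismatched_summary]
    paths["clusters"] = outdir / "cluster_outcomes.csv"
    _round_frame(evaluation.summaries_frame(rows)).to_csv(paths["clusters"], index=False)

    paths["outcomes"] = outdir / "outcomes.csv"
    result.outcomes.to_csv(paths["outcomes"], index=False)

    paths["model"] = outdir / "model_report.json"
    with open(paths["model"], "w") as fh:
        json.dump(result.model_report(), fh, indent=2, default=_json_default)

    paths["log"] = outdir / "run_log.json"
    with open(paths["log"], "w") as fh:
        json.dump(
            {
                "counts": result.counts,
                "seeds": {
                    "generator": config.generator.seed if config.generator else None,
                    "bootstrap": config.bootstrap_seed,
                    "folds": config.fold_seed,
                },
                "settings": {
                    "threshold": config.threshold,
                    "min_valid": config.min_valid,
                    "max_missing": config.max_missing,
                    "n_bootstrap": config.n_bootstrap,
                    "k_folds": config.k_folds,
                    "lambda_rule": config.lambda_rule,
                },
            },
            fh, indent=2,
        )

    if config.make_plot:
        from .plotting import plot_predicted_outcomes

        paths["plot"] = outdir / "predicted_outcomes.png"
        plot_predicted_outcomes(result, paths["plot"])
    return paths


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
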