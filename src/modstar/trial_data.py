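"""Data model for a two-arm trial: patients, baseline variables, derived outcomes.

The container is a thin dataclass around a :class:`pandas.DataFrame` with one
row per patient.  Fixed columns are ``patient_id``, ``arm`` (``"CBASP"`` or
``"ESC_CM"``), ``madrs_baseline`` and ``madrs_week8`` (NaN for non-completers);
the remaining columns are the baseline moderator candidates.  The clinician
rated MADRS baseline score doubles as both the outcome baseline and one of the
candidate moderators.

Sign conventions used throughout the package:

* outcome = percent change in MADRS from baseline to week 8; negative values
  are improvement,
* treatment indicator ``T`` = 1 for CBASP, 0 for ESC/CM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ARM_CBASP = "CBASP"
ARM_ESC = "ESC_CM"
ARMS = (ARM_CBASP, ARM_ESC)

#: Inclusive outcome thresholds, on the percent-change scale.
RESPONSE_THRESHOLD = -50.0
IMPROVER_THRESHOLD = -20.0
REMISSION_WEEK8_MAX = 9.0


@dataclass(frozen=True)
class BaselineVariableSpec:
    """One baseline moderator candidate: its name, measurement level, meaning."""

    name: str
    kind: str  # "nominal" (0/1), "ordinal" (integer 0-5) or "metric" (real)
    description: str

    def __post_init__(self) -> None:
        if self.kind not in ("nominal", "ordinal", "metric"):
            raise ValueError(f"unknown variable kind {self.kind!r}")


#: The eleven canonical baseline variables considered as moderator candidates.
CANONICAL_VARIABLES: tuple[BaselineVariableSpec, ...] = (
    BaselineVariableSpec("female", "nominal", "female gender (yes/no)"),
    BaselineVariableSpec("age", "metric", "age in years"),
    BaselineVariableSpec("early_onset", "nominal", "illness onset before age 21 (yes/no)"),
    BaselineVariableSpec("madrs_baseline", "metric", "clinician-rated MADRS total score at baseline"),
    BaselineVariableSpec("suicide_attempts", "metric", "number of previous suicide attempts"),
    BaselineVariableSpec("axis1_comorbidity", "nominal", "at least one comorbid Axis-I disorder (yes/no)"),
    BaselineVariableSpec("axis2_comorbidity", "nominal", "at least one comorbid Axis-II disorder (yes/no)"),
    BaselineVariableSpec("childhood_trauma", "nominal", "moderate-to-severe childhood trauma on any CTQ dimension (yes/no)"),
    BaselineVariableSpec("adverse_life_events", "metric", "number of major psychosocial stressors over the lifetime"),
    BaselineVariableSpec("prev_psychotherapies", "ordinal", "previous psychotherapies, categories 0-5 (5 = more than 5)"),
    BaselineVariableSpec("prev_antidepressants", "ordinal", "previous antidepressant treatments, categories 0-5 (5 = more than 5)"),
)

VARIABLE_NAMES: tuple[str, ...] = tuple(v.name for v in CANONICAL_VARIABLES)

_FIXED_COLUMNS = ("patient_id", "arm", "madrs_baseline", "madrs_week8")


class TrialDataError(ValueError):
    """Raised when a trial table violates the data model's invariants."""


@dataclass
class TrialDataset:
    """A two-arm trial table plus the specs of its baseline variables."""

    data: pd.DataFrame
    variable_specs: tuple[BaselineVariableSpec, ...] = field(default=CANONICAL_VARIABLES)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variable_specs)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def arm_counts(self) -> dict[str, int]:
        counts = self.data["arm"].value_counts()
        return {arm: int(counts.get(arm, 0)) for arm in ARMS}

    def arm_mask(self, arm: str) -> np.ndarray:
        return (self.data["arm"] == arm).to_numpy()

    def treatment_indicator(self) -> np.ndarray:
        """T = 1 for CBASP, 0 for ESC/CM."""
        return (self.data["arm"] == ARM_CBASP).to_numpy(dtype=float)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        missing_cols = [c for c in _FIXED_COLUMNS if c not in df.columns]
        if missing_cols:
            raise TrialDataError(f"missing required columns: {missing_cols}")
        for spec in self.variable_specs:
            if spec.name not in df.columns:
                raise TrialDataError(f"missing baseline variable column {spec.name!r}")
        if df["patient_id"].duplicated().any():
            raise TrialDataError("patient_id values must be unique")
        bad_arm = set(df["arm"].unique()) - set(ARMS)
        if bad_arm:
            raise TrialDataError(f"unknown arm labels {sorted(bad_arm)}; expected {ARMS}")
        if (df["madrs_baseline"] <= 0).any():
            raise TrialDataError("madrs_baseline must be > 0 (percent change undefined otherwise)")
        for spec in self.variable_specs:
            col = df[spec.name].dropna()
            if spec.kind == "nominal" and not col.isin([0, 1]).all():
                raise TrialDataError(f"nominal variable {spec.name!r} has values outside {{0, 1}}")
            if spec.kind == "ordinal" and not col.isin(range(6)).all():
                raise TrialDataError(f"ordinal variable {spec.name!r} has values outside 0..5")

    # -- derived datasets ------------------------------------------------
    def completers(self) -> "TrialDataset":
        """Patients with a week-8 score; see :func:`filter_completers`."""
        return filter_completers(self)


def percent_change(madrs_baseline, madrs_week8):
    """Percent change in MADRS from baseline to week 8.

    ``(week8 - baseline) / baseline * 100``; negative = improvement, zero = no
    change, positive = worsening.  Accepts scalars or arrays; a zero or
    negative baseline raises, since the ratio is then meaningless.
    """
    baseline = np.asarray(madrs_baseline, dtype=float)
    week8 = np.asarray(madrs_week8, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("percent change undefined for baseline MADRS <= 0")
    out = (week8 - baseline) / baseline * 100.0
    return float(out) if out.ndim == 0 else out


def classify_outcomes(dataset: TrialDataset) -> pd.DataFrame:
    """Per-patient outcome classification.

    Returns a frame with columns ``patient_id``, ``percent_change``,
    ``responder`` (>= 50.0% reduction, boundary inclusive), ``remitter``
    (week-8 MADRS <= 9) and ``improver_20pct`` (>= 20.0% reduction).
    Augmentation candidates in the source trial are exactly the
    non-improvers.  Patients without a week-8 score are excluded with a
    warning.  All comparisons are made on unrounded percent changes.
    """
    df = dataset.data
    has_week8 = df["madrs_week8"].notna()
    n_dropped = int((~has_week8).sum())
    if n_dropped:
        warnings.warn(
            f"classify_outcomes: excluding {n_dropped} patient(s) without a week-8 score",
            stacklevel=2,
        )
    sub = df.loc[has_week8]
    pct = percent_change(sub["madrs_baseline"].to_numpy(), sub["madrs_week8"].to_numpy())
    pct = np.atleast_1d(pct)
    return pd.DataFrame(
        {
            "patient_id": sub["patient_id"].to_numpy(),
            "percent_change": pct,
            "responder": pct <= RESPONSE_THRESHOLD,
            "remitter": sub["madrs_week8"].to_numpy() <= REMISSION_WEEK8_MAX,
            "improver_20pct": pct <= IMPROVER_THRESHOLD,
        }
    )


def filter_completers(dataset: TrialDataset) -> TrialDataset:
    """Keep only patients with a week-8 MADRS score (treatment completers)."""
    keep = dataset.data["madrs_week8"].notna()
    if not keep.any():
        raise TrialDataError("no completers: every patient lacks a week-8 score")
    out = replace(dataset, data=dataset.data.loc[keep].reset_index(drop=True))
    return out


# -- I/O ------------------------------------------------------------------

def read_trial_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    na_values: Iterable[str] = ("", "NA", "NaN"),
    arm_labels: Mapping[str, str] | None = None,
    variable_specs: tuple[BaselineVariableSpec, ...] = CANONICAL_VARIABLES,
) -> TrialDataset:
    """Read a trial table from delimited text.

    Parameters
    ----------
    column_map
        Optional mapping from the file's column names to the canonical ones.
    arm_labels
        Optional mapping from the file's arm labels to ``"CBASP"``/``"ESC_CM"``.
    """
    df = pd.read_csv(path, na_values=list(na_values), keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if arm_labels:
        df["arm"] = df["arm"].map(dict(arm_labels)).fillna(df["arm"])
    return TrialDataset(df, variable_specs=variable_specs)


def write_trial_csv(dataset: TrialDataset, path: str | Path) -> None:
    dataset.data.to_csv(path, index=False)


def write_outcomes_csv(outcomes: pd.DataFrame, path: str | Path) -> None:
    outcomes.to_csv(path, index=False)
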