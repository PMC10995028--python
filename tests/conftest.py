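"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from modstar import GeneratorConfig, TrialDataset, classify_outcomes, generate_trial
from modstar.trial_data import VARIABLE_NAMES


def make_trial(records: list[dict]) -> TrialDataset:
    """Build a TrialDataset from minimal per-patient dicts.

    Each dict needs ``arm``, ``base``, ``week8`` (None = non-completer) and
    may set any baseline variable by name; unset variables default to 0
    (age defaults to 40 so the metric column is not degenerate by accident).
    """
    rows = []
    for i, rec in enumerate(records):
        row = {
            "patient_id": rec.get("id", f"P{i:03d}"),
            "arm": rec["arm"],
            "madrs_baseline": rec["base"],
            "madrs_week8": rec.get("week8"),
        }
        for name in VARIABLE_NAMES:
            if name == "madrs_baseline":
                continue
            row[name] = rec.get(name, 40.0 if name == "age" else 0.0)
        rows.append(row)
    return TrialDataset(pd.DataFrame(rows))


def brute_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Independent Spearman rho: average ranks + Pearson correlation."""
    return float(np.corrcoef(rankdata(x), rankdata(y))[0, 1])


def brute_pairs(dataset: TrialDataset, outcomes: pd.DataFrame) -> list[dict]:
    """O(n1*n2) loop enumeration of cross-arm pairs (oracle for build_pairs)."""
    df = dataset.data.merge(outcomes[["patient_id", "percent_change"]], on="patient_id")
    cb = df[df["arm"] == "CBASP"].to_dict("records")
    es = df[df["arm"] == "ESC_CM"].to_dict("records")
    out = []
    for c in cb:
        for e in es:
            rec = {
                "cbasp_id": c["patient_id"],
                "esc_id": e["patient_id"],
                "outcome_diff": e["percent_change"] - c["percent_change"],
            }
            for name in dataset.variable_names:
                rec[name] = (c[name] + e[name]) / 2.0
            out.append(rec)
    return out


@pytest.fixture(scope="session")
def default_trial() -> TrialDataset:
    """One study-scale synthetic trial with the default generating model."""
    return generate_trial(GeneratorConfig(seed=3, missing_rate=0.0))


@pytest.fixture(scope="session")
def default_outcomes(default_trial) -> pd.DataFrame:
    return classify_outcomes(default_trial)
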