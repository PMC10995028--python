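"""Predicted-outcome plot: the two arms' fitted lines across the M* range."""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_predicted_outcomes(result, path: str | Path) -> None:
    """Predicted percent change vs. M* for both arms, cross-point marked.

    Pointwise 95% bands use the OLS normal approximation from the refitted
    interaction model.
    """
    import statsmodels.api as sm

    fit = result.interaction
    m = result.m_star.to_numpy()
    grid = np.linspace(m.min(), m.max(), 200)

    df = result.dataset.data.merge(
        result.outcomes[["patient_id", "percent_change"]], on="patient_id"
    )
    df = df[df["patient_id"].isin(result.m_star.index)].copy()
    df["m_star"] = result.m_star.reindex(df["patient_id"]).to_numpy()
    t = (df["arm"] == "CBASP").to_numpy(dtype=float)
    X = sm.add_constant(
        np.column_stack([df["m_star"], t, df["m_star"] * t])
    )
    res = sm.OLS(df["percent_change"].to_numpy(), X).fit()

    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    for t_val, label, color in ((0.0, "ESC/CM", "tab:blue"), (1.0, "CBASP", "tab:orange")):
        Xg = np.column_stack(
            [np.ones_like(grid), grid, np.full_like(grid, t_val), grid * t_val]
        )
        pred = res.get_prediction(Xg)
        mean = pred.predicted_mean
        lo, hi = pred.conf_int().T
        ax.plot(grid, mean, color=color, label=label)
        ax.fill_between(grid, lo, hi, color=color, alpha=0.2, lw=0)
    ax.axvline(result.cross_point, color="grey", ls="--", lw=1,
               label=f"cross-point {result.cross_point:.2f}")
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel("composite moderator M*")
    ax.set_ylabel("predicted % change in MADRS (baseline to week 8)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
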