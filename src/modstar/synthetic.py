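"""Synthetic two-arm trial generator.

Generates trials with the statistical structure the moderation analysis
assumes: eleven baseline variables with realistic marginals (defaults follow
the source trial's entire-sample descriptives), an optional shared latent
factor correlating the trauma-related variables, and a percent-change outcome

    y_i = mu0 + tau * T_i + gamma' x_i + T_i * (delta' x_i) + eps_i,
    eps_i ~ Normal(0, sigma^2),  T_i = 1 for CBASP, 0 for ESC/CM,

from which a consistent (baseline, week-8) MADRS pair is back-computed.  The
``delta`` weights are the ground-truth moderation: a variable with nonzero
delta changes the CBASP-vs-ESC/CM contrast and should be recovered by the
downstream pipeline.

The week-8 score is clipped to the MADRS range [0, 60] and the outcome is
then recomputed from the clipped pair; clipping is the single place where the
emitted outcome can deviate from the linear generating model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .trial_data import ARM_CBASP, ARM_ESC, CANONICAL_VARIABLES, TrialDataset

# -- marginal distributions ----------------------------------------------


@dataclass(frozen=True)
class Bernoulli:
    """0/1 variable with success probability ``p``."""

    p: float

    def ppf(self, q: np.ndarray) -> np.ndarray:
        return (q >= 1.0 - self.p).astype(float)


@dataclass(frozen=True)
class TruncNormal:
    """Normal(mu, sd) truncated to [lo, hi]; optionally rounded to integers."""

    mu: float
    sd: float
    lo: float
    hi: float
    integer: bool = False

    def ppf(self, q: np.ndarray) -> np.ndarray:
        a = (self.lo - self.mu) / self.sd
        b = (self.hi - self.mu) / self.sd
        x = stats.truncnorm.ppf(q, a, b, loc=self.mu, scale=self.sd)
        return np.round(x) if self.integer else x


@dataclass(frozen=True)
class Ordinal:
    """Integer codes 0..len(probs)-1 with the given probabilities."""

    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("ordinal probabilities must sum to 1")

    def ppf(self, q: np.ndarray) -> np.ndarray:
        cum = np.cumsum(self.probs)
        return np.searchsorted(cum, q, side="left").astype(float)


Marginal = Bernoulli | TruncNormal | Ordinal

#: Default marginals, matching the source sample's descriptives: 50% female,
#: mean age 42.9 (SD 10.8), 58% early onset, baseline MADRS 26.6 (8.6),
#: 0.3 (0.7) previous suicide attempts, 48%/38% Axis-I/II comorbidity, 70%
#: childhood trauma, 1.8 (1.1) adverse life events, and the printed category
#: frequencies for previous psychotherapies / antidepressant treatments.
DEFAULT_MARGINALS: dict[str, Marginal] = {
    "female": Bernoulli(0.50),
    "age": TruncNormal(42.9, 10.8, 18.0, 75.0),
    "early_onset": Bernoulli(0.58),
    "madrs_baseline": TruncNormal(26.6, 8.6, 10.0, 50.0),
    "suicide_attempts": Ordinal((0.78, 0.14, 0.06, 0.02, 0.0, 0.0)),
    "axis1_comorbidity": Bernoulli(0.48),
    "axis2_comorbidity": Bernoulli(0.38),
    "childhood_trauma": Bernoulli(0.70),
    "adverse_life_events": TruncNormal(1.8, 1.1, 0.0, 8.0, integer=True),
    "prev_psychotherapies": Ordinal((0.30, 0.24, 0.20, 0.10, 0.06, 0.10)),
    "prev_antidepressants": Ordinal((0.44, 0.20, 0.08, 0.18, 0.04, 0.06)),
}

#: Variables tied to the shared latent factor (they co-occur clinically:
#: female gender, childhood trauma, suicide attempts, adverse life events).
LATENT_FACTOR_VARIABLES = ("female", "childhood_trauma", "suicide_attempts", "adverse_life_events")

#: Default ground-truth interaction weights.  ``delta' x`` is *added to the
#: CBASP arm's percent change* and negative percent change is improvement, so
#: a positive delta makes CBASP relatively worse for high values of the
#: variable, i.e. favors ESC/CM there (and gives that variable a negative
#: pairwise effect size downstream).  The default pattern mirrors the source
#: trial: trauma-related variables favor ESC/CM; age, early onset and
#: previous antidepressant history favor CBASP.
DEFAULT_DELTA: dict[str, float] = {
    "suicide_attempts": 12.0,
    "adverse_life_events": 8.0,
    "childhood_trauma": 25.0,
    "female": 15.0,
    "age": -1.0,
    "early_onset": -20.0,
    "prev_antidepressants": -6.0,
}


@dataclass
class GeneratorConfig:
    """All knobs of the generating model; defaults emulate the source trial.

    ``mu0`` is the mean percent change under ESC/CM at x = 0, ``tau`` the
    CBASP main effect, ``gamma`` prognostic (arm-independent) weights,
    ``delta`` the moderation weights, ``noise_sd`` the residual SD of the
    percent-change outcome.  ``latent_corr`` is the loading of the shared
    factor on the trauma-related variables (0 switches correlation off).
    """

    n_cbasp: int = 27
    n_esc: int = 26
    variable_model: dict[str, Marginal] = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    gamma: dict[str, float] = field(default_factory=dict)
    delta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DELTA))
    tau: float = 20.0
    mu0: float = -25.0
    noise_sd: float = 25.0
    missing_rate: float | dict[str, float] = 0.0
    latent_corr: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cbasp < 2 or self.n_esc < 2:
            raise ValueError("need at least 2 patients per arm")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.latent_corr < 1.0:
            raise ValueError("latent_corr must be in [0, 1)")
        unknown = (set(self.gamma) | set(self.delta)) - set(self.variable_model)
        if unknown:
            raise ValueError(f"gamma/delta refer to unknown variables: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "variable_model" in d:
            vm = {}
            for name, spec in d["variable_model"].items():
                spec = dict(spec)
                kind = spec.pop("kind")
                ctor = {"bernoulli": Bernoulli, "truncnormal": TruncNormal, "ordinal": Ordinal}[kind]
                if kind == "ordinal":
                    spec["probs"] = tuple(spec["probs"])
                vm[name] = ctor(**spec)
            d["variable_model"] = vm
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def generate_trial(config: GeneratorConfig) -> TrialDataset:
    """Draw one synthetic trial; bit-identical for a fixed config and seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cbasp + config.n_esc
    arms = np.array([ARM_CBASP] * config.n_cbasp + [ARM_ESC] * config.n_esc)
    t = (arms == ARM_CBASP).astype(float)

    # Gaussian copula: latent z = rho * u + sqrt(1-rho^2) * e for factor-linked
    # variables, independent standard normal otherwise; q = Phi(z) feeds each
    # marginal's quantile function.
    u = rng.standard_normal(n)
    rho = config.latent_corr
    x = {}
    for name, marginal in config.variable_model.items():
        e = rng.standard_normal(n)
        z = rho * u + np.sqrt(1.0 - rho**2) * e if name in LATENT_FACTOR_VARIABLES else e
        q = stats.norm.cdf(z)
        x[name] = marginal.ppf(q)

    # Baseline MADRS must be positive for percent change to exist; redraw any
    # nonpositive values (cannot occur with the default truncation bounds).
    baseline = np.asarray(x["madrs_baseline"], dtype=float)
    for _ in range(100):
        bad = baseline <= 0
        if not bad.any():
            break
        q = stats.norm.cdf(rng.standard_normal(int(bad.sum())))
        baseline[bad] = config.variable_model["madrs_baseline"].ppf(q)
    else:
        raise RuntimeError("could not draw positive baseline MADRS; check variable_model")
    x["madrs_baseline"] = baseline

    lin = np.full(n, config.mu0)
    lin += config.tau * t
    for name, g in config.gamma.items():
        lin += g * x[name]
    for name, d in config.delta.items():
        lin += t * d * x[name]
    y = lin + rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else lin

    week8 = np.clip(baseline * (1.0 + y / 100.0), 0.0, 60.0)

    df = pd.DataFrame({"patient_id": [f"P{i:03d}" for i in range(n)], "arm": arms})
    df["madrs_baseline"] = baseline
    df["madrs_week8"] = week8
    for spec in CANONICAL_VARIABLES:
        if spec.name != "madrs_baseline":
            df[spec.name] = x[spec.name]

    dataset = TrialDataset(df)
    if isinstance(config.missing_rate, Mapping) or float(config.missing_rate) > 0:
        dataset = inject_missingness(
            dataset, config.missing_rate, seed=rng.integers(0, 2**31 - 1)
        )
    return dataset


def inject_missingness(
    dataset: TrialDataset,
    missing_rate: float | Mapping[str, float],
    seed: int,
) -> TrialDataset:
    """Remove baseline values completely at random, per variable.

    ``missing_rate`` is either one probability applied to every baseline
    variable except ``madrs_baseline`` (which the outcome needs), or a
    mapping variable name -> probability.  Raises if a variable would lose
    all its values.
    """
    rng = np.random.default_rng(seed)
    if isinstance(missing_rate, Mapping):
        rates = dict(missing_rate)
    else:
        rates = {
            name: float(missing_rate)
            for name in dataset.variable_names
            if name != "madrs_baseline"
        }
    bad = {k: v for k, v in rates.items() if not 0.0 <= v < 1.0}
    if bad:
        raise ValueError(f"missing rates must be in [0, 1): {bad}")

    df = dataset.data.copy()
    n_removed = {}
    for name, rate in rates.items():
        mask = rng.random(len(df)) < rate
        if mask.all():
            raise ValueError(f"missing rate {rate} removed every value of {name!r}")
        df.loc[mask, name] = np.nan
        if df[name].notna().sum() == 0:
            raise ValueError(f"variable {name!r} lost all values")
        n_removed[name] = int(mask.sum())
    out = replace(dataset, data=df)
    out.n_removed = n_removed  # type: ignore[attr-defined]
    return out
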