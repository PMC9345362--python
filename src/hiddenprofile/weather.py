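"""The weather-forecasting environment: stimuli, indicators, outcomes, scoring.

Each round a latent draw ``x`` in [0, 1] per indicator category is mapped
through a category-specific transfer function (linear increasing for humidity,
linear decreasing for temperature, clamped quadratic for wind), z-scored over
the whole game, summed across categories and squashed through a sigmoid to a
rain probability.  Forecasts are scored with the Brier rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CATEGORIES, GameConfig
from .errors import ConfigurationError, DegenerateInputError

#: Column order of the serialised stimulus table.
STIMULUS_COLUMNS = [
    "round",
    "x_hum", "x_temp", "x_wind",
    "v_hum", "v_temp", "v_wind",
    "z_hum", "z_temp", "z_wind",
    "Z", "p_rain", "outcome",
]


def predictor_value(category: str, x, eps=0.0, scale: float = 0.01):
    """Transform a raw stimulus draw into an indicator value.

    humidity: ``1 + x + scale*eps`` (increasing linear);
    temperature: ``1 - x + scale*eps`` (decreasing linear);
    wind: ``50x^2 - 50x + 10 + scale*eps`` with the *value* clamped to
    [-2, 2], so both low and high wind predict rain while mid-range wind
    predicts its absence.

    ``eps`` is a standard-normal noise draw; pass 0 for deterministic use.
    """
    x = np.asarray(x, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if category == "hum":
        v = 1.0 + x + scale * eps
    elif category == "temp":
        v = 1.0 - x + scale * eps
    elif category == "wind":
        v = np.clip(50.0 * x**2 - 50.0 * x + 10.0 + scale * eps, -2.0, 2.0)
    else:
        raise ConfigurationError(f"unknown predictor category {category!r}")
    return float(v) if v.ndim == 0 else v


def zscore_normalize(values) -> np.ndarray:
    """Z-score a sample: subtract its mean, divide by its sample (ddof=1) sd."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateInputError("need at least 2 values to z-score")
    sd = v.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateInputError("cannot z-score a constant (zero-variance) sample")
    return (v - v.mean()) / sd


def rain_probability(Z, slope: float = 5.0):
    """Sigmoid link from the summed indicator z-scores to P(rain): 1/(1+e^{-slope*Z})."""
    Z = np.asarray(Z, dtype=float)
    p = 1.0 / (1.0 + np.exp(-slope * Z))
    return float(p) if p.ndim == 0 else p


def brier_score(forecast, outcome, variant: str = "original_two_class"):
    """Brier score of a probabilistic forecast of a binary outcome.

    ``original_two_class`` follows Brier's two-category formulation and equals
    ``2*(f - o)^2`` (range [0, 2]); ``squared_error`` is the modern one-term
    convention ``(f - o)^2`` (range [0, 1]).  Both are strictly proper.
    """
    f = np.asarray(forecast, dtype=float)
    o = np.asarray(outcome, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ConfigurationError("forecast must lie in [0, 1]")
    if variant == "original_two_class":
        s = 2.0 * (f - o) ** 2
    elif variant == "squared_error":
        s = (f - o) ** 2
    else:
        raise ConfigurationError(f"unknown brier variant {variant!r}")
    return float(s) if s.ndim == 0 else s


def draw_stimuli(config: GameConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the raw uniform stimuli ``x`` for every round and category."""
    config.validate()
    n = config.n_rounds
    if n < 2:
        raise ConfigurationError("need at least 2 rounds")
    table = pd.DataFrame({"round": np.arange(1, n + 1)})
    for c in CATEGORIES:
        table[f"x_{c}"] = rng.uniform(0.0, 1.0, size=n)
    return table


def realize_outcomes(
    table: pd.DataFrame, rule: str = "bernoulli", rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Fill the binary rain outcome from ``p_rain``.

    ``bernoulli`` draws each round independently with its rain probability;
    ``threshold`` sets rain deterministically when ``p_rain >= 0.5``.
    """
    table = table.copy()
    p = table["p_rain"].to_numpy()
    if rule == "bernoulli":
        if rng is None:
            raise ConfigurationError("bernoulli outcome rule needs an rng")
        table["outcome"] = (rng.uniform(size=p.size) < p).astype(int)
    elif rule == "threshold":
        table["outcome"] = (p >= 0.5).astype(int)
    else:
        raise ConfigurationError(f"unknown outcome rule {rule!r}")
    return table


def generate_stimulus_table(config: GameConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Generate the complete pre-drawn environment for one game.

    All rounds are generated before play starts, z-scores are taken over the
    full game (so each indicator contributes mean 0, sd 1 to the summed
    signal), and outcomes are realised per ``config.outcome_rule``.
    """
    table = draw_stimuli(config, rng)
    for c in CATEGORIES:
        eps = rng.standard_normal(config.n_rounds)
        table[f"v_{c}"] = predictor_value(c, table[f"x_{c}"].to_numpy(), eps,
                                          scale=config.noise_scale)
    for c in CATEGORIES:
        table[f"z_{c}"] = zscore_normalize(table[f"v_{c}"].to_numpy())
    table["Z"] = sum(table[f"z_{c}"] for c in CATEGORIES)
    table["p_rain"] = rain_probability(table["Z"].to_numpy(), slope=config.sigmoid_slope)
    table = realize_outcomes(table, config.outcome_rule, rng)
    return table[STIMULUS_COLUMNS]
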