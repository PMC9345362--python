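"""Game, agent and model configuration.

A full run is a pure function of (:class:`GameConfig`, seed).  Every behavioural
knob of the simulator lives here so that experiment manifests can round-trip
through plain dictionaries (and therefore YAML/JSON).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import yaml

from .errors import ConfigurationError

#: Predictor categories, in canonical column order.
CATEGORIES: tuple[str, ...] = ("hum", "temp", "wind")

BRIER_VARIANTS = ("original_two_class", "squared_error")
OUTCOME_RULES = ("bernoulli", "threshold")
BOT_MODES = ("replace", "append")


@dataclass(frozen=True)
class AgentParams:
    """Behavioural parameters of a synthetic human forecaster.

    The agents are deliberately simple; they exist to reproduce the three
    statistical regularities the bot-training pipeline relies on: forecasts of
    players sharing an indicator are correlated, forecast noise shrinks with
    practice, and social yielding depends on opinion distance (latitude of
    acceptance).

    Parameters
    ----------
    skill_noise_sd
        Residual standard deviation (on the indicator z-score scale) of the
        perception noise after learning has plateaued.
    learning_halflife
        Rounds for the excess early-game noise to halve.  Noise starts at
        ``3 * skill_noise_sd`` and decays geometrically to ``skill_noise_sd``.
    susceptibility
        Weight in [0, 1] placed on the peer median when revising a forecast.
    ally_sensitivity
        Fraction in [0, 1] by which susceptibility is reduced when some peer
        forecast lies within ``ally_threshold`` of the agent's own initial
        forecast (a nearby "ally" entrenches the agent).
    ally_threshold
        Opinion distance within which a peer counts as an ally.
    latitude_width
        Latitude of acceptance: peers further than this from the agent's own
        forecast fall in the latitude of rejection and are ignored at
        revision (the classic Goldilocks region of social influence --
        opinions must be neither trivially close nor unacceptably far to
        persuade).  ``inf`` disables rejection.
    miss_prob
        Probability of omitting the initial forecast on an interaction-phase
        round (attrition).  Training-phase forecasts are never missing.  The
        default reflects the high attrition characteristic of this paradigm:
        most players skip the unrewarded initial forecast most rounds.
    """

    skill_noise_sd: float = 0.05
    learning_halflife: float = 20.0
    susceptibility: float = 0.5
    ally_sensitivity: float = 1.0
    ally_threshold: float = 0.1
    latitude_width: float = 0.3
    miss_prob: float = 0.8

    def validate(self) -> None:
        if self.skill_noise_sd < 0:
            raise ConfigurationError("skill_noise_sd must be >= 0")
        for name in ("susceptibility", "ally_sensitivity", "miss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        if self.ally_threshold < 0:
            raise ConfigurationError("ally_threshold must be >= 0")
        if self.latitude_width <= 0:
            raise ConfigurationError("latitude_width must be > 0")


@dataclass(frozen=True)
class VAEParams:
    """Hyper-parameters of the variational autoencoder and of the clustering step."""

    hidden_width: int = 8
    latent_dim: int = 3
    epochs: int = 5000
    learning_rate: float = 1e-3
    kl_weight: float = 0.1
    n_clusters: int = 3
    kmeans_restarts: int = 25
    include_bias_in_clustering: bool = False
    latent_mode: str = "mean"  # "mean" (deterministic bot) or "sample"

    def validate(self) -> None:
        if self.hidden_width < 1 or self.latent_dim < 1:
            raise ConfigurationError("hidden_width and latent_dim must be >= 1")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ConfigurationError("epochs must be >= 1 and learning_rate > 0")
        if self.kl_weight < 0:
            raise ConfigurationError("kl_weight must be >= 0")
        if self.n_clusters < 1 or self.kmeans_restarts < 1:
            raise ConfigurationError("n_clusters and kmeans_restarts must be >= 1")
        if self.latent_mode not in ("mean", "sample"):
            raise ConfigurationError(f"unknown latent_mode {self.latent_mode!r}")


@dataclass(frozen=True)
class GameConfig:
    """Full configuration of one hidden-profile forecasting game.

    Defaults reproduce the study design: teams of 10 split 5/3/2 across three
    weather indicators, 110 training rounds followed by 50 interaction rounds,
    a 10-round burn-in excluded from bot training, sigmoid slope 5 linking the
    summed indicator z-scores to rain probability, and minority-weighting
    exponent ``gamma = 2``.
    """

    n_players: int = 10
    group_sizes: tuple[int, ...] = (5, 3, 2)
    category_assignment: Mapping[int, str] | None = None
    n_training: int = 110
    n_interaction: int = 50
    burn_in: int = 10
    sigmoid_slope: float = 5.0
    noise_scale: float = 0.01
    gamma: float = 2.0
    brier_variant: str = "original_two_class"
    outcome_rule: str = "bernoulli"
    bot_mode: str = "replace"
    seed: int | None = None
    agent: AgentParams = field(default_factory=AgentParams)
    vae: VAEParams = field(default_factory=VAEParams)

    @property
    def n_rounds(self) -> int:
        return self.n_training + self.n_interaction

    def validate(self) -> None:
        if sum(self.group_sizes) != self.n_players:
            raise ConfigurationError(
                f"group sizes {self.group_sizes} do not sum to n_players={self.n_players}"
            )
        if len(self.group_sizes) != len(CATEGORIES):
            raise ConfigurationError(
                f"expected {len(CATEGORIES)} groups, got {len(self.group_sizes)}"
            )
        if self.n_training < 1 or self.n_interaction < 0 or self.n_rounds < 2:
            raise ConfigurationError("round counts must give at least 2 total rounds")
        if not 0 <= self.burn_in < self.n_training:
            raise ConfigurationError("burn_in must satisfy 0 <= burn_in < n_training")
        if self.brier_variant not in BRIER_VARIANTS:
            raise ConfigurationError(f"unknown brier_variant {self.brier_variant!r}")
        if self.outcome_rule not in OUTCOME_RULES:
            raise ConfigurationError(f"unknown outcome_rule {self.outcome_rule!r}")
        if self.bot_mode not in BOT_MODES:
            raise ConfigurationError(f"unknown bot_mode {self.bot_mode!r}")
        if self.category_assignment is not None:
            sizes = sorted(self.category_assignment)
            cats = sorted(self.category_assignment.values())
            if sizes != sorted(self.group_sizes) or cats != sorted(CATEGORIES):
                raise ConfigurationError(
                    "category_assignment must map each group size to a distinct category"
                )
        self.agent.validate()
        self.vae.validate()

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_sizes"] = list(self.group_sizes)
        if self.category_assignment is not None:
            d["category_assignment"] = {int(k): v for k, v in self.category_assignment.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GameConfig":
        d = dict(d)
        if "agent" in d and isinstance(d["agent"], Mapping):
            d["agent"] = AgentParams(**d["agent"])
        if "vae" in d and isinstance(d["vae"], Mapping):
            d["vae"] = VAEParams(**d["vae"])
        if "group_sizes" in d:
            d["group_sizes"] = tuple(d["group_sizes"])
        if d.get("category_assignment") is not None:
            d["category_assignment"] = {int(k): v for k, v in d["category_assignment"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "GameConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_updates(self, **kwargs) -> "GameConfig":
        cfg = replace(self, **kwargs)
        cfg.validate()
        return cfg
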