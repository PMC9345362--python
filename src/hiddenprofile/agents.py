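"""Synthetic human forecasters.

The agents stand in for the human participants.  They are not a cognitive
model; they are the minimal generative process with the three properties the
bot-training pipeline exploits:

1. agents sharing an indicator produce correlated forecasts (they see the
   same z-score each round);
2. forecast noise shrinks with practice (geometric decay toward a floor);
3. social revision follows a latitude-of-acceptance rule — an agent yields
   toward the peer median unless a nearby "ally" forecast entrenches it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CATEGORIES, AgentParams, GameConfig
from .errors import ConfigurationError


@dataclass(frozen=True)
class AgentProfile:
    """One synthetic player: identity, information condition and behaviour."""

    agent_id: str
    condition: str
    group_size: int
    skill_noise_sd: float = 0.05
    learning_halflife: float = 20.0
    susceptibility: float = 0.5
    ally_sensitivity: float = 1.0
    ally_threshold: float = 0.1
    latitude_width: float = 0.3
    miss_prob: float = 0.0

    @classmethod
    def from_params(cls, agent_id: str, condition: str, group_size: int,
                    params: AgentParams) -> "AgentProfile":
        return cls(agent_id=agent_id, condition=condition, group_size=group_size,
                   skill_noise_sd=params.skill_noise_sd,
                   learning_halflife=params.learning_halflife,
                   susceptibility=params.susceptibility,
                   ally_sensitivity=params.ally_sensitivity,
                   ally_threshold=params.ally_threshold,
                   latitude_width=params.latitude_width,
                   miss_prob=params.miss_prob)


def assign_conditions(config: GameConfig, rng: np.random.Generator) -> list[AgentProfile]:
    """Build the team roster, randomising which indicator each size-group sees.

    With the default 5/3/2 split, the mapping from group size to predictor
    category is a uniformly random permutation of (hum, temp, wind) unless
    ``config.category_assignment`` pins it.
    """
    config.validate()
    if sum(config.group_sizes) != config.n_players:
        raise ConfigurationError("group sizes must sum to n_players")
    if config.category_assignment is not None:
        cat_for_size = dict(config.category_assignment)
        categories = [cat_for_size[s] for s in config.group_sizes]
    else:
        categories = list(rng.permutation(CATEGORIES))
    roster: list[AgentProfile] = []
    i = 0
    for size, cat in zip(config.group_sizes, categories):
        for _ in range(size):
            i += 1
            roster.append(AgentProfile.from_params(
                f"p{i:02d}", cat, size, config.agent))
    return roster


def noise_sd(agent: AgentProfile, round_index: int) -> float:
    """Forecast-noise sd on round ``round_index`` (1-based).

    Starts at three times the skill floor and halves its excess every
    ``learning_halflife`` rounds; a non-positive half-life means the agent is
    already at floor.
    """
    s = agent.skill_noise_sd
    if agent.learning_halflife <= 0:
        return s
    return s * (1.0 + 2.0 * 0.5 ** ((round_index - 1) / agent.learning_halflife))


def form_forecast(agent: AgentProfile, z_own: float, round_index: int,
                  rng: np.random.Generator, slope: float = 5.0) -> tuple[float, bool]:
    """The agent's private judgment and whether it is published.

    Every round the agent perceives its z-score with (decaying) noise and
    forms an internal forecast through the same sigmoid link the environment
    uses.  With probability ``miss_prob`` the agent skips *entering* that
    forecast (attrition): the judgment exists and still anchors the agent's
    later revision, but peers never see it and the log records it missing.

    The rng is advanced identically whether or not the forecast is
    published, so attrition does not perturb the noise stream.
    """
    publish = rng.uniform() >= agent.miss_prob
    sd = noise_sd(agent, round_index)
    eta = rng.normal(0.0, sd) if sd > 0 else 0.0
    f = 1.0 / (1.0 + np.exp(-slope * (z_own + eta)))
    return float(min(1.0, max(0.0, f))), publish


def initial_forecast(
    agent: AgentProfile,
    z_own: float,
    round_index: int,
    rng: np.random.Generator,
    slope: float = 5.0,
    phase: str = "training",
) -> float | None:
    """Published initial forecast; ``None`` under interaction-phase attrition.

    Training-phase forecasts are always published (feedback rounds with no
    social stage).  See :func:`form_forecast` for the generative model.
    """
    f, publish = form_forecast(agent, z_own, round_index, rng, slope=slope)
    if phase == "interaction" and not publish:
        return None
    return f


def accepted_peers(agent: AgentProfile, own_initial: float, peer_forecasts) -> list[float]:
    """Peers within the agent's latitude of acceptance.

    Opinions further than ``latitude_width`` from the agent's own forecast
    fall in the latitude of rejection and are discounted entirely; only the
    remainder enter the revision.  ``latitude_width = inf`` accepts everyone.
    """
    return [p for p in peer_forecasts
            if p is not None and np.isfinite(p)
            and abs(p - own_initial) <= agent.latitude_width]


def revise_forecast(agent: AgentProfile, own_initial: float, peer_forecasts) -> float:
    """Social revision toward the peer median, moderated by nearby allies.

    Effective susceptibility is ``susceptibility * (1 - ally_sensitivity)``
    when any peer forecast lies within ``ally_threshold`` of the agent's own
    initial forecast, otherwise plain ``susceptibility``.  An empty peer set
    leaves the forecast unchanged.
    """
    peers = np.asarray([p for p in peer_forecasts if p is not None and np.isfinite(p)],
                       dtype=float)
    if peers.size == 0:
        return float(own_initial)
    has_ally = bool(np.any(np.abs(peers - own_initial) <= agent.ally_threshold))
    s = agent.susceptibility * (1.0 - agent.ally_sensitivity * has_ally)
    final = (1.0 - s) * own_initial + s * float(np.median(peers))
    return float(min(1.0, max(0.0, final)))
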