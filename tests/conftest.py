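import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hiddenprofile import AgentParams, GameConfig, VAEParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_config():
    return GameConfig()


@pytest.fixture
def small_config():
    """Scaled-down game for fast structural tests."""
    return GameConfig(
        n_training=30, n_interaction=10, burn_in=5,
        vae=VAEParams(epochs=600),
    )


@pytest.fixture
def full_roster_config(small_config):
    """Small game with no attrition: every log cell populated."""
    return small_config.with_updates(agent=AgentParams(miss_prob=0.0))


def make_toy_log(seed=0, n_rounds=5, miss_rate=0.15, team_id="toy"):
    """Randomized 10-player interaction-phase log with attrition and a bot."""
    rng = np.random.default_rng(seed)
    sizes = [5] * 5 + [3] * 3 + [2] * 2
    conds = ["wind"] * 5 + ["hum"] * 3 + ["temp"] * 2
    z = {c: rng.normal(size=n_rounds) for c in ("hum", "temp", "wind")}
    rows = []
    for k in range(1, n_rounds + 1):
        outcome = int(rng.uniform() < 0.5)
        for i in range(10):
            init = rng.uniform() if rng.uniform() > miss_rate else np.nan
            final = rng.uniform()
            rows.append(dict(team_id=team_id, round=k, phase="interaction",
                             player_id=f"p{i + 1:02d}", is_bot=False,
                             condition=conds[i], group_size=sizes[i],
                             stimulus_x=rng.uniform(), z_own=z[conds[i]][k - 1],
                             initial_forecast=init, final_forecast=final,
                             outcome=outcome, brier=2 * (final - outcome) ** 2))
        b = rng.uniform()
        rows.append(dict(team_id=team_id, round=k, phase="interaction",
                         player_id="bot", is_bot=True, condition="",
                         group_size=0, stimulus_x=np.nan, z_own=np.nan,
                         initial_forecast=b, final_forecast=b,
                         outcome=outcome, brier=2 * (b - outcome) ** 2))
    return pd.DataFrame.from_records(rows)


def make_training_log(forecast=0.5, n_training=110, n_players=10, team_id="t"):
    """Training-phase log with a constant forecast everywhere."""
    rng = np.random.default_rng(7)
    rows = []
    for k in range(1, n_training + 1):
        outcome = int(rng.uniform() < 0.5)
        for i in range(n_players):
            rows.append(dict(team_id=team_id, round=k, phase="training",
                             player_id=f"p{i + 1:02d}", is_bot=False,
                             condition="hum", group_size=5, stimulus_x=0.5,
                             z_own=0.0, initial_forecast=forecast,
                             final_forecast=forecast, outcome=outcome,
                             brier=2 * (forecast - outcome) ** 2))
    return pd.DataFrame.from_records(rows)


@pytest.fixture
def toy_log():
    return make_toy_log(seed=42)
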