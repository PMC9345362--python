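"""Orchestration: full games and multi-team experiments.

A game is 110 training rounds of independent forecasting with feedback,
followed (in the ``vae`` arm) by training the team's own VAE on rounds
11-110 and 50 interaction rounds in which every player sees peers' initial
forecasts — including the algorithmic player's — before revising.  The
``random`` arm swaps the VAE bot for a seeded uniform forecaster.

Everything downstream is a pure function of (config, seed): the seed is
split into independent sub-streams for stimuli, condition assignment, agent
noise, VAE initialisation, K-means, bot-slot choice and the bot's own
randomness, all recorded in the manifest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agents import (accepted_peers, assign_conditions, form_forecast,
                     initial_forecast, revise_forecast)
from .bot import (BotProfile, bot_forecast, build_bot_profile,
                  build_response_matrix, install_bot, random_bot_forecast)
from .config import GameConfig
from .errors import ConfigurationError
from .metrics import player_round_metrics, team_round_metrics, team_summary
from .vae import VAEModel, train_vae
from .weather import brier_score, generate_stimulus_table

BOT_ID = "bot"

#: Stable public schema of the forecast log (missing values = empty fields).
FORECAST_LOG_COLUMNS = [
    "team_id", "round", "phase", "player_id", "is_bot", "condition",
    "group_size", "stimulus_x", "z_own", "initial_forecast",
    "final_forecast", "outcome", "brier",
]

TREATMENTS = ("vae", "random")


@dataclass
class GameLog:
    """Complete record of one simulated game."""

    frame: pd.DataFrame
    manifest: dict
    stimuli: pd.DataFrame
    model: VAEModel | None = None
    profile: BotProfile | None = None

    @property
    def team_id(self) -> str:
        return self.manifest["team_id"]


def _derive_seed(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31))


def run_game(config: GameConfig | None = None, treatment: str = "vae",
             seed: int | None = None, team_id: str = "team_01") -> GameLog:
    """Simulate one full game and return its log.

    ``treatment`` selects the algorithmic player: ``"vae"`` trains the
    minority-supporting bot on this team's own training-phase responses;
    ``"random"`` uses uniform guesses.
    """
    config = config or GameConfig()
    config.validate()
    if treatment not in TREATMENTS:
        raise ConfigurationError(f"unknown treatment {treatment!r}")
    if seed is None:
        seed = config.seed if config.seed is not None else 0

    ss = np.random.SeedSequence(seed)
    s_stim, s_assign, s_agent, s_vae, s_cluster, s_bot = ss.spawn(6)
    rng_stim = np.random.default_rng(s_stim)
    rng_assign = np.random.default_rng(s_assign)
    rng_agent = np.random.default_rng(s_agent)
    rng_slot = np.random.default_rng(s_cluster)
    rng_bot = np.random.default_rng(s_bot)
    vae_seed = _derive_seed(s_vae)
    kmeans_seed = _derive_seed(s_cluster)

    stimuli = generate_stimulus_table(config, rng_stim)
    roster = assign_conditions(config, rng_assign)
    z = {c: stimuli[f"z_{c}"].to_numpy() for c in ("hum", "temp", "wind")}
    x = {c: stimuli[f"x_{c}"].to_numpy() for c in ("hum", "temp", "wind")}
    outcomes = stimuli["outcome"].to_numpy()
    slope = config.sigmoid_slope

    rows: list[dict] = []

    def add_row(rnd, phase, player_id, is_bot, condition, group_size,
                stim_x, z_own, initial, final):
        rows.append({
            "team_id": team_id, "round": rnd, "phase": phase,
            "player_id": player_id, "is_bot": is_bot, "condition": condition,
            "group_size": group_size, "stimulus_x": stim_x, "z_own": z_own,
            "initial_forecast": np.nan if initial is None else initial,
            "final_forecast": final, "outcome": int(outcomes[rnd - 1]),
            "brier": brier_score(final, outcomes[rnd - 1], config.brier_variant),
        })

    # ---- training phase: independent forecasts with outcome feedback ----
    for rnd in range(1, config.n_training + 1):
        for agent in roster:
            f = initial_forecast(agent, z[agent.condition][rnd - 1], rnd,
                                 rng_agent, slope=slope, phase="training")
            add_row(rnd, "training", agent.agent_id, False, agent.condition,
                    agent.group_size, x[agent.condition][rnd - 1],
                    z[agent.condition][rnd - 1], f, f)

    train_frame = pd.DataFrame.from_records(rows)

    # ---- build the algorithmic player ----
    # Both arms deploy the bot identically (in replace mode a uniformly
    # chosen player's displayed review-stage forecast becomes the bot's);
    # only the forecast source differs between treatments.
    model = profile = None
    slot = None
    replaced_player = None
    player_order = sorted(a.agent_id for a in roster)
    if treatment == "vae":
        rm = build_response_matrix(train_frame, burn_in=config.burn_in,
                                   n_training=config.n_training)
        model = train_vae(rm, config.vae, seed=vae_seed)
        profile = build_bot_profile(
            model, k=config.vae.n_clusters, gamma=config.gamma,
            seed=kmeans_seed, n_init=config.vae.kmeans_restarts,
            include_bias=config.vae.include_bias_in_clustering)
        model, slot = install_bot(model, profile, mode=config.bot_mode, rng=rng_slot)
        player_order = model.player_ids
        if config.bot_mode == "replace":
            replaced_player = model.player_ids[slot]
    elif config.bot_mode == "replace":
        slot = int(rng_slot.integers(config.n_players))
        replaced_player = player_order[slot]

    # ---- interaction phase: initial -> peer exposure -> revision ----
    for rnd in range(config.n_training + 1, config.n_rounds + 1):
        # every agent forms a private judgment; attrition only hides it
        private: dict[str, float] = {}
        initials: dict[str, float | None] = {}
        for agent in roster:
            f, publish = form_forecast(agent, z[agent.condition][rnd - 1],
                                       rnd, rng_agent, slope=slope)
            private[agent.agent_id] = f
            initials[agent.agent_id] = f if publish else None

        if treatment == "vae":
            bot_f = bot_forecast(
                model, [initials[p] for p in player_order],
                latent_mode=config.vae.latent_mode,
                rng=rng_bot if config.vae.latent_mode == "sample" else None)
        else:
            bot_f = random_bot_forecast(rng_bot)

        # what the review stage displays: in replace mode the bot's forecast
        # stands in for the replaced human's; in append mode it is an 11th voice
        displayed = {pid: f for pid, f in initials.items()
                     if f is not None and pid != replaced_player}
        displayed[BOT_ID] = bot_f

        for agent in roster:
            shown = [f for pid, f in displayed.items() if pid != agent.agent_id]
            own = initials[agent.agent_id]
            # revision anchors on the private judgment: an agent who skipped
            # publishing still saw their indicator and formed an opinion;
            # displayed opinions outside the latitude of acceptance are ignored
            anchor = private[agent.agent_id]
            final = revise_forecast(agent, anchor,
                                    accepted_peers(agent, anchor, shown))
            add_row(rnd, "interaction", agent.agent_id, False, agent.condition,
                    agent.group_size, x[agent.condition][rnd - 1],
                    z[agent.condition][rnd - 1], own, final)
        add_row(rnd, "interaction", BOT_ID, True, "", 0, np.nan, np.nan,
                bot_f, bot_f)

    frame = pd.DataFrame.from_records(rows, columns=FORECAST_LOG_COLUMNS)
    manifest = {
        "software_version": __version__,
        "team_id": team_id,
        "treatment": treatment,
        "seed": int(seed),
        "vae_seed": vae_seed,
        "kmeans_seed": kmeans_seed,
        "config": config.to_dict(),
        "roster": [agent.__dict__ for agent in roster],
        "bot_mode": config.bot_mode,
        "bot_slot": slot,
        "replaced_player": replaced_player,
        "bot_profile": profile.to_dict() if profile is not None else None,
    }
    return GameLog(frame=frame, manifest=manifest, stimuli=stimuli,
                   model=model, profile=profile)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_forecast_log(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_forecast_log(path) -> pd.DataFrame:
    frame = pd.read_csv(path, keep_default_na=True)
    frame["is_bot"] = frame["is_bot"].astype(bool)
    frame["condition"] = frame["condition"].fillna("")
    return frame


def save_game(log: GameLog, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_forecast_log(log.frame, out / "forecasts.csv")
    log.stimuli.to_csv(out / "stimuli.csv", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(log.manifest, fh, indent=1, default=float)
    if log.model is not None:
        log.model.to_json(out / "vae_model.json")
    return out


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Pooled outputs of a control-vs-treatment experiment."""

    logs: list[GameLog]
    team_rounds: pd.DataFrame
    players: pd.DataFrame
    summary_table: pd.DataFrame
    summary: dict
    failures: list[tuple[str, str]] = field(default_factory=list)


def run_experiment(n_control: int = 15, n_treatment: int = 15,
                   config: GameConfig | None = None, master_seed: int = 0,
                   out_dir=None) -> ExperimentResult:
    """Run ``n_treatment`` VAE-bot teams and ``n_control`` random-bot teams.

    Each team gets an independent seed derived from ``master_seed``.  Teams
    that fail are skipped with a warning; the run fails only if every team
    fails.  When ``out_dir`` is given, all per-team logs, pooled tables and a
    JSON summary are written there.
    """
    if n_control < 0 or n_treatment < 0 or n_control + n_treatment < 1:
        raise ConfigurationError("need at least one team")
    config = config or GameConfig()
    plan = ([("vae", f"vae_{i + 1:02d}") for i in range(n_treatment)]
            + [("random", f"rnd_{i + 1:02d}") for i in range(n_control)])
    seeds = np.random.SeedSequence(master_seed).spawn(len(plan))

    logs: list[GameLog] = []
    failures: list[tuple[str, str]] = []
    for (treatment, team_id), seq in zip(plan, seeds):
        try:
            log = run_game(config, treatment=treatment,
                           seed=_derive_seed(seq), team_id=team_id)
            logs.append(log)
        except Exception as exc:  # pragma: no cover - defensive path
            warnings.warn(f"team {team_id} failed: {exc}")
            failures.append((team_id, str(exc)))
    if not logs:
        raise RuntimeError("all teams failed")

    pooled = pd.concat([log.frame for log in logs], ignore_index=True)
    arm = {log.team_id: log.manifest["treatment"] for log in logs}
    team_rounds = team_round_metrics(pooled)
    team_rounds.insert(1, "treatment", team_rounds["team_id"].map(arm))
    players = player_round_metrics(pooled)
    players.insert(1, "treatment", players["team_id"].map(arm))
    summary_table = team_summary(pooled)
    summary_table.insert(1, "treatment", summary_table["team_id"].map(arm))

    by_arm = team_rounds.groupby("treatment")
    summary = {
        "n_teams": {"vae": int(n_treatment - sum(t.startswith("vae") for t, _ in failures)),
                    "random": int(n_control - sum(t.startswith("rnd") for t, _ in failures))},
        "master_seed": int(master_seed),
        "mean_deltaSD": by_arm["deltaSD"].mean().to_dict(),
        "mean_postSD": by_arm["postSD"].mean().to_dict(),
        "mean_median_error": by_arm["median_error"].mean().to_dict(),
        "mean_delta_median_error": by_arm["delta_median_error"].mean().to_dict(),
        "mean_improvement": players.groupby("treatment")["improvement"].mean().to_dict(),
        "mean_training_error": summary_table.groupby("treatment")["training_error"]
                                            .mean().to_dict(),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for log in logs:
            save_game(log, out / "teams" / log.team_id)
        team_rounds.to_csv(out / "team_round_metrics.csv", index=False)
        players.to_csv(out / "player_round_metrics.csv", index=False)
        summary_table.to_csv(out / "team_summary.csv", index=False)
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, default=float)

    return ExperimentResult(logs=logs, team_rounds=team_rounds, players=players,
                            summary_table=summary_table, summary=summary,
                            failures=failures)
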