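"""Team-dynamics and accuracy metrics computed from a forecast log.

All derived variables of the analysis: per-round indicator spread (Z-Range),
polarization before/after peer exposure (preSD, postSD, deltaSD), cross-group
influence between the 2-, 3- and 5-person indicator groups, individual
prediction error and improvement, team median errors with and without the
bot, per-team training error, round difficulty, and leave-one-out collective
error.

Missing forecasts (attrition) never raise: undefined metrics are emitted as
NaN, the package-wide missing code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CATEGORIES
from .errors import ConfigurationError, DegenerateInputError


def _clean(values) -> np.ndarray:
    v = np.asarray([np.nan if x is None else float(x) for x in np.ravel(values)])
    return v[np.isfinite(v)]


def z_range(z_temp: float, z_hum: float, z_wind: float) -> float:
    """Spread between the largest and smallest indicator z-score of a round."""
    z = np.array([z_temp, z_hum, z_wind], dtype=float)
    return float(z.max() - z.min())


def polarization(initials, finals, ddof: int = 1):
    """(preSD, postSD, deltaSD) of a team's forecasts around one round.

    deltaSD = postSD - preSD: positive values mean opinions spread apart
    after seeing peers.  Fewer than two usable values in either set gives NaN.
    """
    pre_v, post_v = _clean(initials), _clean(finals)
    pre = float(np.std(pre_v, ddof=ddof)) if pre_v.size >= 2 else np.nan
    post = float(np.std(post_v, ddof=ddof)) if post_v.size >= 2 else np.nan
    return pre, post, post - pre


def group_influence(source_initials, target_finals) -> float:
    """Influence of one indicator group on another for a single round.

    ``1 - |median(source initials) - median(target finals)|``: 1 when the
    target ends exactly on the source's initial position, 0 at maximal
    disagreement.
    """
    s, t = _clean(source_initials), _clean(target_finals)
    if s.size == 0 or t.size == 0:
        return np.nan
    return float(1.0 - abs(np.median(s) - np.median(t)))


def prediction_error_and_improvement(initial, final, outcome):
    """(initial error, final error, improvement) for one forecast pair.

    Errors are absolute distances to the binary outcome; improvement is the
    drop in error from initial to final (positive = accuracy gain).  A
    missing initial forecast gives NaN initial error and NaN improvement.
    """
    err_f = abs(float(final) - float(outcome))
    if initial is None or not np.isfinite(initial):
        return np.nan, err_f, np.nan
    err_i = abs(float(initial) - float(outcome))
    return err_i, err_f, err_i - err_f


def team_median_errors(initials, finals, outcome):
    """(median error, delta median error) of a team for one round.

    median error = |median(finals) - outcome|; delta = error of the median
    initial minus error of the median final (positive = the team improved).
    Pass forecast sets with or without the bot to get the two reported
    variants.
    """
    i, f = _clean(initials), _clean(finals)
    o = float(outcome)
    med_err = abs(float(np.median(f)) - o) if f.size else np.nan
    if i.size == 0 or f.size == 0:
        return med_err, np.nan
    return med_err, abs(float(np.median(i)) - o) - med_err


def training_error(log: pd.DataFrame, team_id=None, first_round: int = 56,
                   last_round: int = 110, rescale: bool = False) -> float:
    """Per-team mean prediction error over the late training rounds.

    Sums each human's |forecast - outcome| over rounds
    ``first_round..last_round`` and divides by rounds x players (550 for the
    default design).  Missing forecasts drop out of the numerator while the
    denominator stays fixed, unless ``rescale`` divides by the observed count.
    """
    rows = log[~log["is_bot"].astype(bool)]
    if team_id is not None:
        rows = rows[rows["team_id"] == team_id]
        if rows.empty:
            raise ConfigurationError(f"team {team_id!r} not present in log")
    elif rows.empty:
        raise ConfigurationError("empty log")
    rows = rows[(rows["phase"] == "training")
                & (rows["round"] >= first_round) & (rows["round"] <= last_round)]
    n_players = rows["player_id"].nunique()
    errs = (rows["final_forecast"] - rows["outcome"]).abs()
    denom = errs.notna().sum() if rescale else (last_round - first_round + 1) * n_players
    if denom == 0:
        return np.nan
    return float(errs.sum(skipna=True) / denom)


def standardize(values, ddof: int = 1) -> np.ndarray:
    """Center to mean 0 and scale to unit sample sd (NaNs pass through)."""
    v = np.asarray(values, dtype=float)
    obs = v[np.isfinite(v)]
    if obs.size < 2:
        raise DegenerateInputError("need at least 2 observed values to standardize")
    sd = obs.std(ddof=ddof)
    if sd == 0:
        raise DegenerateInputError("cannot standardize a constant column")
    return (v - obs.mean()) / sd


def round_difficulty(z_by_category: pd.DataFrame, assignment: dict,
                     measure: str = "abs_z",
                     p_rain=None) -> pd.DataFrame:
    """Per-round difficulty, per category and size-weighted for the team.

    ``abs_z`` (default): a round is hard for a group when its indicator's
    z-score is near zero (uninformative), so per-category difficulty is
    ``-|z|`` standardized across rounds; the team value weights categories by
    their group sizes (e.g. (5*wind + 3*hum + 2*temp)/10).  ``prob_extremity``
    scores the round as a whole by how close the rain probability is to 0.5
    (team-level only).

    ``assignment`` maps category name -> group size.
    """
    out = pd.DataFrame(index=z_by_category.index.copy())
    if measure == "abs_z":
        total = float(sum(assignment.values()))
        weighted = np.zeros(len(out))
        for c in CATEGORIES:
            d = standardize(-np.abs(z_by_category[f"z_{c}"].to_numpy(dtype=float)))
            out[f"difficulty_{c}"] = d
            weighted += assignment[c] * d
        out["team_difficulty"] = weighted / total
    elif measure == "prob_extremity":
        if p_rain is None:
            raise ConfigurationError("prob_extremity measure needs p_rain")
        out["team_difficulty"] = standardize(-np.abs(2.0 * np.asarray(p_rain, float) - 1.0))
    else:
        raise ConfigurationError(f"unknown difficulty measure {measure!r}")
    return out


def collective_error(initials, outcome, focal_index: int) -> float:
    """Mean absolute initial-forecast error of the focal player's teammates.

    Leave-one-out over human teammates with an observed initial forecast;
    NaN when every peer is missing.
    """
    v = np.asarray([np.nan if x is None else float(x) for x in np.ravel(initials)])
    peers = np.delete(v, focal_index)
    peers = peers[np.isfinite(peers)]
    if peers.size == 0:
        return np.nan
    return float(np.mean(np.abs(peers - float(outcome))))


# ---------------------------------------------------------------------------
# table builders
# ---------------------------------------------------------------------------

def _role_sizes(sizes) -> dict[str, int]:
    s = sorted(set(int(x) for x in sizes), reverse=True)
    if len(s) != 3:
        raise ConfigurationError(f"expected 3 distinct group sizes, got {s}")
    return {"majority": s[0], "midsize": s[1], "minority": s[2]}


def _team_z_table(team: pd.DataFrame) -> pd.DataFrame:
    """Per-round z-score of each category, recovered from human rows."""
    humans = team[~team["is_bot"].astype(bool)]
    z = humans.groupby(["round", "condition"])["z_own"].first().unstack("condition")
    z.columns = [f"z_{c}" for c in z.columns]
    return z


def team_round_metrics(log: pd.DataFrame, difficulty_measure: str = "abs_z") -> pd.DataFrame:
    """One row per team x interaction round with every round-level metric.

    Bot forecasts are excluded from polarization and influence; team median
    errors are reported both without (``median_error``) and with
    (``median_error_bot``) the bot.
    """
    records = []
    for team_id, team in log.groupby("team_id", sort=True):
        humans = team[~team["is_bot"].astype(bool)]
        roles = _role_sizes(humans["group_size"].unique())
        assignment = (humans.groupby("condition")["group_size"].first().to_dict())
        if difficulty_measure != "abs_z":
            raise ConfigurationError(
                "team_round_metrics supports the abs_z difficulty measure; "
                "use round_difficulty directly for prob_extremity")
        z_table = _team_z_table(team)
        diff = round_difficulty(z_table, assignment, measure=difficulty_measure)
        inter = team[team["phase"] == "interaction"]
        for rnd, rows in inter.groupby("round", sort=True):
            h = rows[~rows["is_bot"].astype(bool)]
            b = rows[rows["is_bot"].astype(bool)]
            zr = z_table.loc[rnd]
            outcome = rows["outcome"].iloc[0]
            pre, post, dsd = polarization(h["initial_forecast"], h["final_forecast"])
            by_size = {sz: grp for sz, grp in h.groupby("group_size")}

            def _grp(role, col):
                grp = by_size.get(roles[role])
                return grp[col] if grp is not None else []

            me, dme = team_median_errors(h["initial_forecast"], h["final_forecast"], outcome)
            me_b, dme_b = team_median_errors(
                pd.concat([h["initial_forecast"], b["initial_forecast"]]),
                pd.concat([h["final_forecast"], b["final_forecast"]]), outcome)
            rec = {
                "team_id": team_id,
                "round": rnd,
                "outcome": outcome,
                "ZRange": z_range(zr["z_temp"], zr["z_hum"], zr["z_wind"]),
                "preSD": pre, "postSD": post, "deltaSD": dsd,
                "minority_influence_majority": group_influence(
                    _grp("minority", "initial_forecast"), _grp("majority", "final_forecast")),
                "minority_influence_midsize": group_influence(
                    _grp("minority", "initial_forecast"), _grp("midsize", "final_forecast")),
                "majority_influence_minority": group_influence(
                    _grp("majority", "initial_forecast"), _grp("minority", "final_forecast")),
                "majority_influence_midsize": group_influence(
                    _grp("majority", "initial_forecast"), _grp("midsize", "final_forecast")),
                "median_error": me, "delta_median_error": dme,
                "median_error_bot": me_b, "delta_median_error_bot": dme_b,
            }
            for role in ("majority", "midsize", "minority"):
                cat = next(c for c, s in assignment.items() if s == roles[role])
                rec[f"difficulty_{role}"] = diff.loc[rnd, f"difficulty_{cat}"] \
                    if f"difficulty_{cat}" in diff.columns else np.nan
            rec["team_difficulty"] = diff.loc[rnd, "team_difficulty"]
            records.append(rec)
    return pd.DataFrame.from_records(records)


def player_round_metrics(log: pd.DataFrame) -> pd.DataFrame:
    """One row per human player x interaction round: errors, improvement,
    leave-one-out collective error, and the player's own-category difficulty."""
    records = []
    for team_id, team in log.groupby("team_id", sort=True):
        humans_all = team[~team["is_bot"].astype(bool)]
        assignment = humans_all.groupby("condition")["group_size"].first().to_dict()
        z_table = _team_z_table(team)
        diff = round_difficulty(z_table, assignment)
        inter = team[team["phase"] == "interaction"]
        for rnd, rows in inter.groupby("round", sort=True):
            h = rows[~rows["is_bot"].astype(bool)].reset_index(drop=True)
            outcome = rows["outcome"].iloc[0]
            initials = h["initial_forecast"].to_numpy(dtype=float)
            for idx, row in h.iterrows():
                err_i, err_f, imp = prediction_error_and_improvement(
                    row["initial_forecast"], row["final_forecast"], outcome)
                records.append({
                    "team_id": team_id, "round": rnd, "player_id": row["player_id"],
                    "condition": row["condition"], "group_size": row["group_size"],
                    "initial_forecast": row["initial_forecast"],
                    "final_forecast": row["final_forecast"], "outcome": outcome,
                    "prediction_error_initial": err_i,
                    "prediction_error_final": err_f,
                    "improvement": imp,
                    "collective_error": collective_error(initials, outcome, idx),
                    "difficulty_own": diff.loc[rnd, f"difficulty_{row['condition']}"],
                })
    return pd.DataFrame.from_records(records)


def team_summary(log: pd.DataFrame) -> pd.DataFrame:
    """Per-team scalars: training error and interaction-phase metric means."""
    tr = team_round_metrics(log)
    pr = player_round_metrics(log)
    rows = []
    for team_id, t in tr.groupby("team_id", sort=True):
        p = pr[pr["team_id"] == team_id]
        row = {
            "team_id": team_id,
            "training_error": training_error(log, team_id),
            "mean_deltaSD": t["deltaSD"].mean(),
            "mean_preSD": t["preSD"].mean(),
            "mean_postSD": t["postSD"].mean(),
            "mean_median_error": t["median_error"].mean(),
            "mean_delta_median_error": t["delta_median_error"].mean(),
            "mean_median_error_bot": t["median_error_bot"].mean(),
            "mean_delta_median_error_bot": t["delta_median_error_bot"].mean(),
            "mean_improvement": p["improvement"].mean(),
        }
        for cond, grp in p.groupby("condition"):
            row[f"mean_improvement_{cond}"] = grp["improvement"].mean()
        rows.append(row)
    return pd.DataFrame.from_records(rows)
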