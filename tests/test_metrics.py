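"""Derived team-dynamics variables, each checked against a brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest

import hiddenprofile as hp
from hiddenprofile.errors import ConfigurationError, DegenerateInputError

from _bruteforce import (bf_collective_error, bf_errors, bf_group_influence,
                         bf_polarization, bf_round_difficulty, bf_sd,
                         bf_team_median_errors, bf_training_error, bf_z_range)
from conftest import make_toy_log, make_training_log


class TestElementaryMetrics:
    def test_z_range_examples(self):
        assert hp.z_range(0.5, -0.5, 0.0) == pytest.approx(1.0)
        assert hp.z_range(0.3, 0.3, 0.3) == 0.0

    def test_z_range_permutation_invariant(self, rng):
        for _ in range(20):
            a, b, c = rng.normal(size=3)
            vals = {hp.z_range(*p) for p in
                    [(a, b, c), (c, a, b), (b, c, a), (a, c, b)]}
            assert len(vals) == 1

    def test_polarization_cases(self):
        pre, post, dsd = hp.polarization([0.2, 0.8], [0.5, 0.5])
        assert dsd == pytest.approx(-bf_sd([0.2, 0.8]))
        assert post == pytest.approx(0.0)
        _, _, dsd2 = hp.polarization([0.5, 0.5], [0.2, 0.8])
        assert dsd2 > 0
        same = [0.1, 0.4, 0.9]
        assert hp.polarization(same, same)[2] == 0.0

    def test_polarization_insufficient_values_flagged(self):
        pre, post, dsd = hp.polarization([0.4], [0.2, 0.6])
        assert math.isnan(pre) and math.isnan(dsd)

    def test_group_influence_examples(self):
        assert hp.group_influence([0.8], [0.6]) == pytest.approx(0.8)
        assert hp.group_influence([0.4, 0.4], [0.4]) == pytest.approx(1.0)
        assert hp.group_influence([0.0], [1.0]) == pytest.approx(0.0)
        assert math.isnan(hp.group_influence([], [0.5]))

    def test_prediction_error_and_improvement(self):
        err_i, err_f, imp = hp.prediction_error_and_improvement(0.6, 0.9, 1)
        assert (err_i, err_f) == pytest.approx((0.4, 0.1))
        assert imp == pytest.approx(0.3)
        assert hp.prediction_error_and_improvement(0.7, 0.7, 0)[2] == 0.0
        assert hp.prediction_error_and_improvement(0.0, 1.0, 1)[2] == pytest.approx(1.0)
        assert math.isnan(hp.prediction_error_and_improvement(np.nan, 0.5, 1)[2])

    def test_team_median_errors_examples(self):
        me, dme = hp.team_median_errors([0.2, 0.4, 0.6], [0.6, 0.8, 1.0], 1)
        assert me == pytest.approx(0.2)
        assert dme == pytest.approx(0.4)
        me2, _ = hp.team_median_errors([0.5], [1.0], 1)
        assert me2 == 0.0

    def test_team_median_errors_bot_equal_to_median_is_noop(self):
        humans_i, humans_f = [0.2, 0.4, 0.6], [0.3, 0.5, 0.7]
        with_bot = hp.team_median_errors(humans_i + [0.4], humans_f + [0.5], 1)
        without = hp.team_median_errors(humans_i, humans_f, 1)
        assert with_bot == pytest.approx(without)

    def test_order_invariance(self, rng):
        i = rng.uniform(size=6).tolist()
        f = rng.uniform(size=6).tolist()
        perm = rng.permutation(6)
        assert hp.team_median_errors(i, f, 1) == \
               pytest.approx(hp.team_median_errors([i[k] for k in perm],
                                                   [f[k] for k in perm], 1))
        assert hp.group_influence(i, f) == \
               pytest.approx(hp.group_influence([i[k] for k in perm], f))

    def test_standardize(self):
        assert np.allclose(hp.standardize([1, 2, 3]), [-1, 0, 1])
        assert abs(np.mean(hp.standardize([4.0, 9.0, 1.0, 7.0]))) < 1e-12
        with pytest.raises(DegenerateInputError):
            hp.standardize([2, 2, 2])

    def test_collective_error(self):
        # peers' initial errors 0.2 and 0.4 -> mean 0.3; focal excluded
        initials = [0.9, 0.8, 0.6]
        assert hp.collective_error(initials, 1, 2) == pytest.approx(0.15)
        assert hp.collective_error([0.2, 0.4, 0.99], 0, 2) == pytest.approx(0.3)
        changed = [0.2, 0.4, 0.01]
        assert hp.collective_error(changed, 0, 2) == \
               pytest.approx(hp.collective_error([0.2, 0.4, 0.99], 0, 2))
        assert math.isnan(hp.collective_error([np.nan, np.nan, 0.5], 1, 2))


class TestTrainingError:
    def test_all_half_forecasts_give_half(self):
        log = make_training_log(forecast=0.5)
        assert hp.training_error(log) == pytest.approx(0.5)

    def test_all_correct_give_zero(self):
        log = make_training_log(forecast=0.5)
        log["final_forecast"] = log["outcome"].astype(float)
        assert hp.training_error(log) == 0.0

    def test_only_late_rounds_contribute(self):
        log = make_training_log(forecast=0.5)
        base = hp.training_error(log)
        log.loc[log["round"] == 55, "final_forecast"] = 1.0
        assert hp.training_error(log) == pytest.approx(base)
        log.loc[log["round"] == 56, "final_forecast"] = log["outcome"]
        assert hp.training_error(log) != pytest.approx(base)

    def test_missing_kept_denominator(self):
        log = make_training_log(forecast=0.5)
        idx = (log["round"] == 60) & (log["player_id"] == "p01")
        log.loc[idx, "final_forecast"] = np.nan
        assert hp.training_error(log) == pytest.approx(0.5 - 0.5 / 550)
        assert hp.training_error(log, rescale=True) == pytest.approx(0.5)

    def test_absent_team_raises(self):
        log = make_training_log()
        with pytest.raises(ConfigurationError):
            hp.training_error(log, team_id="nope")


class TestRoundDifficulty:
    def test_team_weighting_matches_printed_formula(self, rng):
        z = pd.DataFrame({f"z_{c}": rng.normal(size=30) for c in hp.CATEGORIES})
        assignment = {"wind": 5, "hum": 3, "temp": 2}
        got = hp.round_difficulty(z, assignment)
        manual = (5 * got["difficulty_wind"] + 3 * got["difficulty_hum"]
                  + 2 * got["difficulty_temp"]) / 10
        assert np.allclose(got["team_difficulty"], manual)

    def test_less_extreme_z_is_harder(self, rng):
        z = pd.DataFrame({f"z_{c}": rng.normal(size=50) for c in hp.CATEGORIES})
        got = hp.round_difficulty(z, {"wind": 5, "hum": 3, "temp": 2})
        hardest = got["difficulty_wind"].idxmax()
        assert abs(z.loc[hardest, "z_wind"]) == pytest.approx(
            np.abs(z["z_wind"]).min())

    def test_prob_extremity_variant(self, rng):
        z = pd.DataFrame({f"z_{c}": rng.normal(size=20) for c in hp.CATEGORIES})
        p = rng.uniform(size=20)
        got = hp.round_difficulty(z, {"wind": 5, "hum": 3, "temp": 2},
                                  measure="prob_extremity", p_rain=p)
        assert np.allclose(got["team_difficulty"],
                           hp.standardize(-np.abs(2 * p - 1)))

    def test_unknown_measure_raises(self, rng):
        z = pd.DataFrame({f"z_{c}": rng.normal(size=5) for c in hp.CATEGORIES})
        with pytest.raises(ConfigurationError):
            hp.round_difficulty(z, {"wind": 5, "hum": 3, "temp": 2}, measure="???")


@pytest.fixture(scope="module")
def log():
    return make_toy_log(seed=2024)


class TestOracleEquivalence:
    """Every table entry equals an independently coded recomputation."""

    def check_team_rounds(self, log, tol=1e-12):
        table = hp.team_round_metrics(log).set_index("round")
        humans = log[~log["is_bot"]]
        z_by_round = {}
        for rnd, rows in humans.groupby("round"):
            z_by_round[rnd] = rows.groupby("condition")["z_own"].first().to_dict()
        assignment = humans.groupby("condition")["group_size"].first().to_dict()
        _, team_diff = bf_round_difficulty(z_by_round, assignment)
        for rnd, rows in log.groupby("round"):
            h = rows[~rows["is_bot"]]
            b = rows[rows["is_bot"]]
            got = table.loc[rnd]
            z = z_by_round[rnd]
            outcome = rows["outcome"].iloc[0]
            assert got["ZRange"] == pytest.approx(
                bf_z_range(z["temp"], z["hum"], z["wind"]), abs=tol)
            pre, post, dsd = bf_polarization(h["initial_forecast"],
                                             h["final_forecast"])
            assert got["preSD"] == pytest.approx(pre, abs=tol, nan_ok=True)
            assert got["postSD"] == pytest.approx(post, abs=tol, nan_ok=True)
            assert got["deltaSD"] == pytest.approx(dsd, abs=tol, nan_ok=True)
            by = {s: h[h["group_size"] == s] for s in (2, 3, 5)}
            assert got["minority_influence_majority"] == pytest.approx(
                bf_group_influence(by[2]["initial_forecast"],
                                   by[5]["final_forecast"]), abs=tol, nan_ok=True)
            assert got["minority_influence_midsize"] == pytest.approx(
                bf_group_influence(by[2]["initial_forecast"],
                                   by[3]["final_forecast"]), abs=tol, nan_ok=True)
            assert got["majority_influence_minority"] == pytest.approx(
                bf_group_influence(by[5]["initial_forecast"],
                                   by[2]["final_forecast"]), abs=tol, nan_ok=True)
            assert got["majority_influence_midsize"] == pytest.approx(
                bf_group_influence(by[5]["initial_forecast"],
                                   by[3]["final_forecast"]), abs=tol, nan_ok=True)
            me, dme = bf_team_median_errors(h["initial_forecast"],
                                            h["final_forecast"], outcome)
            assert got["median_error"] == pytest.approx(me, abs=tol, nan_ok=True)
            assert got["delta_median_error"] == pytest.approx(dme, abs=tol, nan_ok=True)
            me_b, dme_b = bf_team_median_errors(
                list(h["initial_forecast"]) + list(b["initial_forecast"]),
                list(h["final_forecast"]) + list(b["final_forecast"]), outcome)
            assert got["median_error_bot"] == pytest.approx(me_b, abs=tol, nan_ok=True)
            assert got["delta_median_error_bot"] == pytest.approx(dme_b, abs=tol,
                                                                  nan_ok=True)
            assert got["team_difficulty"] == pytest.approx(team_diff[rnd], abs=tol)

    def check_players(self, log, tol=1e-12):
        table = hp.player_round_metrics(log).set_index(["round", "player_id"])
        humans = log[~log["is_bot"]]
        for rnd, rows in humans.groupby("round"):
            rows = rows.reset_index(drop=True)
            outcome = rows["outcome"].iloc[0]
            initials = rows["initial_forecast"].tolist()
            for idx, r in rows.iterrows():
                got = table.loc[(rnd, r["player_id"])]
                err_i, err_f, imp = bf_errors(r["initial_forecast"],
                                              r["final_forecast"], outcome)
                assert got["prediction_error_initial"] == pytest.approx(
                    err_i, abs=tol, nan_ok=True)
                assert got["prediction_error_final"] == pytest.approx(err_f, abs=tol)
                assert got["improvement"] == pytest.approx(imp, abs=tol, nan_ok=True)
                assert got["collective_error"] == pytest.approx(
                    bf_collective_error(initials, outcome, idx), abs=tol,
                    nan_ok=True)

    def test_team_round_table_matches_bruteforce(self, log):
        self.check_team_rounds(log)

    def test_player_table_matches_bruteforce(self, log):
        self.check_players(log)

    def test_training_error_matches_bruteforce(self):
        rng = np.random.default_rng(55)
        log = make_training_log(forecast=0.5)
        log["final_forecast"] = rng.uniform(size=len(log))
        by_round = {r: g["final_forecast"].tolist()
                    for r, g in log.groupby("round")}
        outcomes = {r: g["outcome"].iloc[0] for r, g in log.groupby("round")}
        expected = bf_training_error(by_round, outcomes, 56, 110, 10)
        assert hp.training_error(log) == pytest.approx(expected, abs=1e-12)

    def test_no_revision_fixed_point(self):
        log = make_toy_log(seed=77)
        log["final_forecast"] = log["initial_forecast"].fillna(log["final_forecast"])
        log.loc[log["initial_forecast"].notna(), "final_forecast"] = \
            log.loc[log["initial_forecast"].notna(), "initial_forecast"]
        full = log[log["initial_forecast"].notna()]
        # on rows where finals == initials, deltaSD and improvement vanish
        for rnd, rows in full[~full["is_bot"]].groupby("round"):
            same = rows["initial_forecast"]
            assert hp.polarization(same, same)[2] == 0.0

    def test_missing_data_never_raises(self):
        log = make_toy_log(seed=3, miss_rate=0.95)
        tr = hp.team_round_metrics(log)
        pr = hp.player_round_metrics(log)
        assert len(tr) == 5
        assert len(pr) == 50
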