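"""Independent brute-force re-implementations of every derived metric.

Deliberately written with plain Python loops and the ``statistics`` module,
sharing no code with the package, so they can serve as oracles.
"""

import math
import statistics


def _obs(values):
    return [float(v) for v in values
            if v is not None and not (isinstance(v, float) and math.isnan(v))]


def bf_z_range(zt, zh, zw):
    vals = [zt, zh, zw]
    return max(vals) - min(vals)


def bf_sd(values):
    vals = _obs(values)
    if len(vals) < 2:
        return float("nan")
    return statistics.stdev(vals)


def bf_polarization(initials, finals):
    pre, post = bf_sd(initials), bf_sd(finals)
    return pre, post, post - pre


def bf_group_influence(source_initials, target_finals):
    s, t = _obs(source_initials), _obs(target_finals)
    if not s or not t:
        return float("nan")
    return 1.0 - abs(statistics.median(s) - statistics.median(t))


def bf_errors(initial, final, outcome):
    err_f = abs(final - outcome)
    if initial is None or (isinstance(initial, float) and math.isnan(initial)):
        return float("nan"), err_f, float("nan")
    err_i = abs(initial - outcome)
    return err_i, err_f, err_i - err_f


def bf_team_median_errors(initials, finals, outcome):
    i, f = _obs(initials), _obs(finals)
    med_err = abs(statistics.median(f) - outcome) if f else float("nan")
    if not i or not f:
        return med_err, float("nan")
    return med_err, abs(statistics.median(i) - outcome) - med_err


def bf_training_error(forecasts_by_round, outcomes_by_round, first_round,
                      last_round, n_players):
    total = 0.0
    for rnd in range(first_round, last_round + 1):
        for f in forecasts_by_round[rnd]:
            if f is not None and not (isinstance(f, float) and math.isnan(f)):
                total += abs(f - outcomes_by_round[rnd])
    return total / ((last_round - first_round + 1) * n_players)


def bf_standardize(values):
    m = statistics.fmean(values)
    sd = statistics.stdev(values)
    return [(v - m) / sd for v in values]


def bf_round_difficulty(z_by_round_category, assignment):
    """abs_z measure: standardized -|z| per category, size-weighted team value."""
    rounds = sorted(z_by_round_category)
    cats = sorted(assignment)
    per_cat = {}
    for c in cats:
        raw = [-abs(z_by_round_category[r][c]) for r in rounds]
        per_cat[c] = dict(zip(rounds, bf_standardize(raw)))
    total = sum(assignment.values())
    team = {r: sum(assignment[c] * per_cat[c][r] for c in cats) / total
            for r in rounds}
    return per_cat, team


def bf_collective_error(initials, outcome, focal_index):
    peers = [v for i, v in enumerate(initials)
             if i != focal_index and v is not None
             and not (isinstance(v, float) and math.isnan(v))]
    if not peers:
        return float("nan")
    return statistics.fmean(abs(v - outcome) for v in peers)


def bf_minority_weights(sizes, gamma):
    w = [(1.0 / n) ** gamma for n in sizes]
    s = sum(w)
    return [x / s for x in w]


def bf_minority_profile(centroids, sizes, gamma):
    w = bf_minority_weights(sizes, gamma)
    dim = len(centroids[0])
    return [sum(w[c] * centroids[c][d] for c in range(len(sizes)))
            for d in range(dim)]
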