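# hiddenprofile

A simulator and analysis library for the *hidden-profile* forecasting game
with a minority-supporting algorithmic player.

## The problem

In a hidden-profile task, the information needed to solve a problem is
unevenly distributed: some cues are shared by a majority of a group while
others are held only by small minorities.  Groups systematically under-use
minority-held information, so simple opinion averaging or voting is biased
toward whatever the majority happens to know.

This package simulates the canonical laboratory version of that task as a
probabilistic weather-forecasting game.  A team of 10 players predicts a
binary rain outcome over 160 rounds.  Three weather indicators (humidity,
temperature, wind) each carry equal and independent predictive value, but
each player sees only one of them: 5 players see one indicator (the
majority), 3 another (mid-size minority), and 2 the third (small minority).
During a 110-round training phase players forecast independently and receive
outcome feedback; during a 50-round interaction phase they additionally see
teammates' initial forecasts and may revise before committing.

The scientific object of interest is an **algorithmic team member** that
learns, without supervision, which players share an information source, and
then positions itself in opinion space to support under-represented views —
plus the metrics needed to measure what such a bot does to team polarization,
cross-group influence and accuracy, against a random-forecast control.

## The method

**Environment.** Per round `k` and indicator `c`, a uniform draw
`x ∈ [0,1]` is mapped through a category-specific transfer function
(humidity `1 + x`, temperature `1 − x`, wind `clip(50x² − 50x + 10, −2, 2)`,
each plus small Gaussian noise), z-scored over the whole game, and summed:

```
Z_k = z_hum_k + z_temp_k + z_wind_k,    P(rain_k) = 1 / (1 + exp(−5 Z_k))
```

Outcomes are Bernoulli draws; forecasts are scored with the two-category
Brier rule `2(f − o)²`.

**The bot.** A variational autoencoder is trained on the team's own
training-phase response matrix `X` (rounds 11–110 × 10 players): a tanh
encoder maps each round's 10 forecasts to a 3-dimensional Gaussian latent,
and a single affine-plus-sigmoid decoder reconstructs the 10 forecasts.
Because the decoder is one affine layer, each player is summarised by the 3
decoder weights feeding their output unit, and players whose forecasts
co-move acquire similar weight vectors.  The bot is then built in three
steps:

1. K-means (k = 3) on the 10 decoder weight vectors;
2. a synthetic weight vector as the centroid average with weights
   `w_c = (1/N_c)^γ` (normalised), `γ = 2`, so smaller opinion clusters
   dominate;
3. this vector replaces a randomly chosen player's output unit.  Each
   round, the humans' initial forecasts are encoded and the bot unit's
   decoded activation is the bot's forecast — an original, minority-leaning
   opinion, not a copy of any player.

Control teams get a bot drawing uniform random forecasts, deployed
identically.

**Synthetic humans.** Players are simulated with the minimal behaviour the
pipeline requires: within-condition correlation (shared indicator),
trial-and-error learning (noise decaying to a floor), attrition on
unrewarded initial forecasts, and a latitude-of-acceptance revision rule —
yield toward the median of displayed opinions that are not too distant,
unless a nearby ally entrenches you.  See `docs/methods.md` for the full
model and parameter table.

**Metrics.** Per team × round: indicator spread (`ZRange`), polarization
before and after peer exposure (`preSD`, `postSD`, `deltaSD`), median-based
cross-group influence, team median errors with and without the bot, round
difficulty; per player × round: prediction errors, improvement, leave-one-out
collective error; per team: late-training error.  All are validated against
independent brute-force implementations.

## Worked example

```python
import hiddenprofile as hp

log = hp.run_game(treatment="vae", seed=7, team_id="demo")
profile = log.profile
print("cluster sizes:", profile.sizes.tolist())
print("normalized minority weights:", [round(float(w), 4) for w in profile.normalized_weights])
print("bot slot (replaced player):", log.manifest["replaced_player"])

metrics = hp.team_round_metrics(log.frame)
print("mean deltaSD:", round(metrics["deltaSD"].mean(), 4))
print("mean median error (humans):", round(metrics["median_error"].mean(), 4))
print("training error:", round(hp.training_error(log.frame), 4))
```

prints

```
cluster sizes: [3, 5, 2]
normalized minority weights: [0.277, 0.0997, 0.6233]
bot slot (replaced player): p09
mean deltaSD: -0.0203
mean median error (humans): 0.3024
training error: 0.3137
```

The K-means step found the 3/5/2 information groups exactly; with `γ = 2`
the 2-person cluster receives 62.3% of the bot's profile weight and the
5-person majority only 10.0%.  `deltaSD` is the round-mean change in the
standard deviation of the team's forecasts after peer exposure (negative =
convergence), `median error` the distance of the team's median final
forecast from the realised outcome, and `training error` the players' mean
absolute error over training rounds 56–110.

A command-line interface wraps the same pipeline:

```bash
hiddenprofile simulate --teams-control 15 --teams-treatment 15 --seed 42 --out runs/
hiddenprofile metrics --log runs/teams/vae_01/forecasts.csv --out metrics.csv
hiddenprofile train-bot --log runs/teams/vae_01/forecasts.csv --seed 1 --out bot.json
hiddenprofile report --run runs/ --out report.md
hiddenprofile dump-defaults
```

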