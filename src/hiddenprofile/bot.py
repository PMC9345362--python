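"""Construction and inference of the minority-supporting algorithmic player.

Pipeline: cluster the trained decoder's per-player weight vectors with
K-means (k = 3), average the cluster centroids with weights
``w_c = (1/N_c)^gamma`` (small clusters dominate for ``gamma > 0``;
``gamma = 2`` by default), install the resulting synthetic output unit in
the decoder (replacing a random player's unit, or appended), and read the
bot's forecast off that unit when the model encodes the live round's human
forecasts.  A seeded uniform random bot serves as the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ConfigurationError, InsufficientDataError
from .vae import ResponseMatrix, VAEModel


def build_response_matrix(log: pd.DataFrame, burn_in: int = 10,
                          n_training: int = 110) -> ResponseMatrix:
    """Assemble the (rounds x players) training matrix from a forecast log.

    Keeps human initial forecasts on training rounds ``burn_in+1 .. n_training``
    and imputes missing entries with the player's observed mean (0.5 for a
    player who never responded).
    """
    rows = log[(log["phase"] == "training") & (~log["is_bot"].astype(bool))]
    rows = rows[(rows["round"] > burn_in) & (rows["round"] <= n_training)]
    if rows.empty:
        raise InsufficientDataError("log contains no usable training rounds")
    wide = rows.pivot(index="round", columns="player_id", values="initial_forecast")
    wide = wide.sort_index().sort_index(axis=1)
    if wide.shape[0] < 10:
        raise InsufficientDataError(
            f"only {wide.shape[0]} usable training rounds (need >= 10)")
    mask = wide.notna().to_numpy()
    values = wide.to_numpy(dtype=float)
    means = np.where(mask.any(axis=0),
                     np.nanmean(np.where(mask, values, np.nan), axis=0), 0.5)
    values = np.where(mask, values, means)
    return ResponseMatrix(values=values, mask=mask,
                          rounds=wide.index.to_numpy(),
                          player_ids=[str(c) for c in wide.columns])


def weight_correlation(model: VAEModel, include_bias: bool = False) -> pd.DataFrame:
    """Player-by-player Pearson correlation of decoder output-unit weights.

    Players whose forecasts co-moved during training acquire similar decoder
    weights, so the block structure of this matrix exposes the information
    groups.
    """
    W = model.output_weights(include_bias=include_bias)
    C = np.corrcoef(W)
    return pd.DataFrame(C, index=model.player_ids, columns=model.player_ids)


def projection_2d(model: VAEModel, extra_vectors: np.ndarray | None = None,
                  include_bias: bool = False) -> np.ndarray:
    """2-D PCA projection of the output-unit weight vectors.

    ``extra_vectors`` (e.g. the bot's synthetic vector) are projected with the
    same fitted rotation and returned as additional rows.
    """
    W = model.output_weights(include_bias=include_bias)
    pca = PCA(n_components=2).fit(W)
    coords = pca.transform(W)
    if extra_vectors is not None:
        coords = np.vstack([coords, pca.transform(np.atleast_2d(extra_vectors))])
    return coords


def cluster_output_weights(model: VAEModel, k: int = 3, seed: int = 0,
                           n_init: int = 25, include_bias: bool = False):
    """K-means over per-player decoder weight vectors.

    Returns ``(labels, centroids, sizes)``; deterministic under ``seed``.
    """
    W = model.output_weights(include_bias=include_bias)
    if k > W.shape[0]:
        raise ConfigurationError(f"k={k} exceeds number of players {W.shape[0]}")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) % (2**31)).fit(W)
    labels = km.labels_.astype(int)
    sizes = np.bincount(labels, minlength=k)
    if np.any(sizes == 0):
        raise ConfigurationError("K-means produced an empty cluster")
    return labels, km.cluster_centers_.copy(), sizes


def cluster_weights(sizes, gamma: float) -> np.ndarray:
    """Normalised minority weights ``(1/N_c)^gamma / sum``."""
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ConfigurationError("cluster sizes must be positive")
    w = (1.0 / sizes) ** gamma
    return w / w.sum()


def minority_weighted_profile(centroids, sizes, gamma: float = 2.0) -> np.ndarray:
    """Synthetic output-unit vector: centroid average weighted toward small clusters.

    ``gamma = 0`` recovers the unweighted centroid mean; large ``gamma``
    concentrates all weight on the smallest cluster.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    w = cluster_weights(sizes, gamma)
    if w.size != centroids.shape[0]:
        raise ConfigurationError("one size per centroid required")
    return w @ centroids


@dataclass
class BotProfile:
    """Everything needed to reconstruct (and audit) the algorithmic player."""

    labels: np.ndarray
    centroids: np.ndarray
    sizes: np.ndarray
    gamma: float
    weight_vector: np.ndarray      # latent-dim decoder weights of the bot unit
    bias: float
    slot: int | None = None        # output-unit index occupied after install
    mode: str = "replace"
    normalized_weights: np.ndarray = field(init=False)

    def __post_init__(self):
        self.normalized_weights = cluster_weights(self.sizes, self.gamma)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels.tolist(),
            "centroids": self.centroids.tolist(),
            "sizes": self.sizes.tolist(),
            "gamma": float(self.gamma),
            "normalized_weights": self.normalized_weights.tolist(),
            "weight_vector": self.weight_vector.tolist(),
            "bias": float(self.bias),
            "slot": None if self.slot is None else int(self.slot),
            "mode": self.mode,
        }


def build_bot_profile(model: VAEModel, k: int = 3, gamma: float = 2.0,
                      seed: int = 0, n_init: int = 25,
                      include_bias: bool = False) -> BotProfile:
    """Cluster a trained model's output weights and form the bot's unit.

    The bot's bias is the cluster-mean biases averaged with the same minority
    weights (biases are excluded from the clustering distance by default).
    """
    labels, centroids, sizes = cluster_output_weights(
        model, k=k, seed=seed, n_init=n_init, include_bias=include_bias)
    vec = minority_weighted_profile(centroids, sizes, gamma)
    biases = model.params["b_dec"]
    w = cluster_weights(sizes, gamma)
    if include_bias:
        bias = float(vec[-1])
        vec = vec[:-1]
    else:
        cluster_bias = np.array([biases[labels == c].mean() for c in range(len(sizes))])
        bias = float(w @ cluster_bias)
    return BotProfile(labels=labels, centroids=centroids, sizes=sizes,
                      gamma=gamma, weight_vector=np.asarray(vec, dtype=float),
                      bias=bias)


def install_bot(model: VAEModel, profile: BotProfile, mode: str = "replace",
                rng: np.random.Generator | None = None) -> tuple[VAEModel, int]:
    """Insert the bot's output unit into a copy of the model.

    ``replace`` overwrites a uniformly chosen player's unit (the default
    deployment); ``append`` adds an 11th unit, leaving every human unit
    intact.  Returns the modified model and the bot's slot index.
    """
    latent = model.params["W_dec"].shape[0]
    if profile.weight_vector.shape != (latent,):
        raise ConfigurationError(
            f"bot vector has dimension {profile.weight_vector.shape}, expected ({latent},)")
    params = {k: v.copy() for k, v in model.params.items()}
    if mode == "replace":
        if rng is None:
            raise ConfigurationError("replace mode needs an rng to choose the slot")
        slot = int(rng.integers(model.n_outputs))
        params["W_dec"][:, slot] = profile.weight_vector
        params["b_dec"][slot] = profile.bias
    elif mode == "append":
        slot = model.n_outputs
        params["W_dec"] = np.hstack([params["W_dec"], profile.weight_vector[:, None]])
        params["b_dec"] = np.append(params["b_dec"], profile.bias)
    else:
        raise ConfigurationError(f"unknown bot mode {mode!r}")
    new = VAEModel(params=params, hyper=model.hyper, player_ids=list(model.player_ids),
                   player_means=model.player_means.copy(), seed=model.seed,
                   loss_trace=list(model.loss_trace), bot_slot=slot)
    profile.slot = slot
    profile.mode = mode
    return new, slot


def bot_forecast(model: VAEModel, human_initials, latent_mode: str = "mean",
                 rng: np.random.Generator | None = None) -> float:
    """The bot's forecast for one round.

    ``human_initials`` are the round's human initial forecasts in the
    encoder's player order (NaN/None where missing; imputed with each
    player's training-phase mean).  The round is encoded, the latent taken
    at its posterior mean (or sampled), decoded, and the bot unit's
    activation returned, clamped to [0, 1].
    """
    if model.bot_slot is None:
        raise ConfigurationError("model has no installed bot unit; call install_bot first")
    x = np.array([np.nan if v is None else float(v) for v in human_initials], dtype=float)
    if x.shape[0] != model.params["W_enc"].shape[0]:
        raise ConfigurationError(
            f"expected {model.params['W_enc'].shape[0]} inputs, got {x.shape[0]}")
    x = np.where(np.isfinite(x), x, model.player_means)
    mu, logvar = model.encode(x)
    if latent_mode == "mean":
        z = mu
    elif latent_mode == "sample":
        if rng is None:
            raise ConfigurationError("sample mode needs an rng")
        z = mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)
    else:
        raise ConfigurationError(f"unknown latent_mode {latent_mode!r}")
    y = model.decode(z)[0, model.bot_slot]
    return float(min(1.0, max(0.0, y)))


def random_bot_forecast(rng: np.random.Generator) -> float:
    """Control bot: a uniform forecast on [0, 1]."""
    return float(rng.uniform(0.0, 1.0))
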