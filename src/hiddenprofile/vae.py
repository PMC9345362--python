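"""Variational autoencoder over team response matrices.

The encoder maps the 10 players' forecasts on one round to a 3-dimensional
Gaussian posterior; the decoder is a single affine map back to the 10 players
followed by a sigmoid.  Because the decoder is one affine layer, each player
is summarised by the 3 decoder weights (plus bias) feeding their output unit:
players whose forecasts co-move acquire similar weight vectors, which is the
representation the bot-construction step clusters.

Implemented directly in numpy (forward pass, analytic gradients,
reparameterization trick, Adam) so training is fully deterministic under a
seed and models serialise to plain JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .config import VAEParams
from .errors import ConfigurationError, TrainingFailureError

_PARAM_KEYS = ("W_enc", "b_enc", "W_mu", "b_mu", "W_logvar", "b_logvar", "W_dec", "b_dec")


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    e = np.exp(a[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class ResponseMatrix:
    """Training-phase initial forecasts, rounds x players, with missingness mask.

    ``values`` is fully imputed (player mean, 0.5 for never-responders);
    ``mask`` is True where the original forecast was observed.
    """

    values: np.ndarray
    mask: np.ndarray
    rounds: np.ndarray
    player_ids: list[str]
    player_means: np.ndarray = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ConfigurationError("values and mask shapes differ")
        means = np.empty(self.values.shape[1])
        for j in range(self.values.shape[1]):
            obs = self.values[self.mask[:, j], j]
            means[j] = obs.mean() if obs.size else 0.5
        self.player_means = means

    @property
    def n_players(self) -> int:
        return self.values.shape[1]


@dataclass
class VAEModel:
    """A trained (or freshly initialised) VAE with its provenance.

    ``params`` holds the eight weight/bias arrays; ``player_means`` are the
    training-phase per-player means used to impute missing encoder inputs at
    inference time; ``loss_trace`` is the per-epoch training objective.
    """

    params: dict[str, np.ndarray]
    hyper: VAEParams
    player_ids: list[str]
    player_means: np.ndarray
    seed: int | None = None
    loss_trace: list[float] = field(default_factory=list)
    bot_slot: int | None = None  # set by install_bot

    # -- network -----------------------------------------------------------

    @property
    def n_outputs(self) -> int:
        return self.params["W_dec"].shape[1]

    def encode(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and log-variance of the latent for each row of X."""
        p = self.params
        H = np.tanh(np.atleast_2d(X) @ p["W_enc"] + p["b_enc"])
        return H @ p["W_mu"] + p["b_mu"], H @ p["W_logvar"] + p["b_logvar"]

    def decode(self, Z: np.ndarray) -> np.ndarray:
        p = self.params
        return _sigmoid(np.atleast_2d(Z) @ p["W_dec"] + p["b_dec"])

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Deterministic reconstruction through the posterior mean."""
        mu, _ = self.encode(X)
        return self.decode(mu)

    def output_weights(self, include_bias: bool = False) -> np.ndarray:
        """Per-output-unit decoder parameter vectors, one row per player.

        These are the coordinates each player occupies along the latent
        layer; the clustering and the bot profile both live in this space.
        """
        W = self.params["W_dec"].T.copy()  # players x latent
        if include_bias:
            W = np.hstack([W, self.params["b_dec"][:, None]])
        return W

    # -- serialisation -----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "hyper": self.hyper.__dict__,
            "player_ids": self.player_ids,
            "player_means": self.player_means.tolist(),
            "seed": self.seed,
            "bot_slot": self.bot_slot,
            "loss_trace": [float(x) for x in self.loss_trace],
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "VAEModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                payload = json.load(fh)
        return cls(
            params={k: np.asarray(v, dtype=float) for k, v in payload["params"].items()},
            hyper=VAEParams(**payload["hyper"]),
            player_ids=list(payload["player_ids"]),
            player_means=np.asarray(payload["player_means"], dtype=float),
            seed=payload.get("seed"),
            loss_trace=list(payload.get("loss_trace", [])),
            bot_slot=payload.get("bot_slot"),
        )


def _init_params(n_players: int, hyper: VAEParams, rng: np.random.Generator) -> dict:
    def glorot(a, b):
        return rng.normal(scale=np.sqrt(2.0 / (a + b)), size=(a, b))

    h, d = hyper.hidden_width, hyper.latent_dim
    return {
        "W_enc": glorot(n_players, h), "b_enc": np.zeros(h),
        "W_mu": glorot(h, d), "b_mu": np.zeros(d),
        "W_logvar": glorot(h, d), "b_logvar": np.zeros(d),
        "W_dec": glorot(d, n_players), "b_dec": np.zeros(n_players),
    }


def elbo_loss(X: np.ndarray, Y: np.ndarray, mu: np.ndarray, logvar: np.ndarray,
              kl_weight: float) -> float:
    """Per-round average of squared reconstruction error (summed over players)
    plus ``kl_weight`` times KL(q(z|x) || N(0, I))."""
    recon = ((Y - X) ** 2).sum(axis=1).mean()
    kl = 0.5 * (np.exp(logvar) + mu**2 - 1.0 - logvar).sum(axis=1).mean()
    return float(recon + kl_weight * kl)


def train_vae(X, hyper: VAEParams | None = None, seed: int = 0) -> VAEModel:
    """Fit the VAE to a response matrix by full-batch Adam.

    ``X`` may be a :class:`ResponseMatrix` or a plain (rounds x players)
    array of forecasts in [0, 1].  Training is a pure function of
    (X, hyper, seed).
    """
    hyper = hyper or VAEParams()
    hyper.validate()
    if isinstance(X, ResponseMatrix):
        player_ids, data = X.player_ids, X.values
        player_means = X.player_means
    else:
        data = np.asarray(X, dtype=float)
        player_ids = [f"p{j + 1:02d}" for j in range(data.shape[1])]
        player_means = data.mean(axis=0)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ConfigurationError("response matrix must be 2-D with at least 2 rows")

    rng = np.random.default_rng(seed)
    n = data.shape[0]
    params = _init_params(data.shape[1], hyper, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    kw = hyper.kl_weight
    trace: list[float] = []

    for t in range(1, hyper.epochs + 1):
        H = np.tanh(data @ params["W_enc"] + params["b_enc"])
        mu = H @ params["W_mu"] + params["b_mu"]
        logvar = H @ params["W_logvar"] + params["b_logvar"]
        noise = rng.standard_normal(mu.shape)
        sd = np.exp(0.5 * logvar)
        Z = mu + sd * noise
        Y = _sigmoid(Z @ params["W_dec"] + params["b_dec"])

        loss = elbo_loss(data, Y, mu, logvar, kw)
        if not np.isfinite(loss):
            raise TrainingFailureError(
                f"non-finite loss at epoch {t}", loss_trace=trace)
        trace.append(loss)

        # backward pass (objective averaged over the batch)
        gA = (2.0 * (Y - data) / n) * Y * (1.0 - Y)       # pre-sigmoid output grad
        gW_dec = Z.T @ gA
        gb_dec = gA.sum(axis=0)
        gZ = gA @ params["W_dec"].T
        gmu = gZ + kw * mu / n
        glogvar = gZ * noise * 0.5 * sd + kw * 0.5 * (np.exp(logvar) - 1.0) / n
        gW_mu = H.T @ gmu
        gb_mu = gmu.sum(axis=0)
        gW_logvar = H.T @ glogvar
        gb_logvar = glogvar.sum(axis=0)
        gH = gmu @ params["W_mu"].T + glogvar @ params["W_logvar"].T
        gPre = gH * (1.0 - H**2)
        grads = {
            "W_enc": data.T @ gPre, "b_enc": gPre.sum(axis=0),
            "W_mu": gW_mu, "b_mu": gb_mu,
            "W_logvar": gW_logvar, "b_logvar": gb_logvar,
            "W_dec": gW_dec, "b_dec": gb_dec,
        }
        for k in _PARAM_KEYS:
            m[k] = beta1 * m[k] + (1.0 - beta1) * grads[k]
            v[k] = beta2 * v[k] + (1.0 - beta2) * grads[k] ** 2
            mhat = m[k] / (1.0 - beta1**t)
            vhat = v[k] / (1.0 - beta2**t)
            params[k] -= hyper.learning_rate * mhat / (np.sqrt(vhat) + eps_adam)

    return VAEModel(params=params, hyper=hyper, player_ids=player_ids,
                    player_means=np.asarray(player_means, dtype=float),
                    seed=seed, loss_trace=trace)
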