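"""Seeded feedforward autoencoder on pseudo-uniform data, in pure numpy.

The encoder maps a K-column pseudo-uniform row through hidden layers
(affine -> batch norm -> ReLU -> dropout) down to an unconstrained
d-dimensional latent code; the decoder mirrors the hidden widths in reverse
(affine -> batch norm -> ReLU, no dropout) and ends in a sigmoid so
reconstructions stay inside (0, 1). Dropout regularises the encoder only:
the decoder is the generative map from latent codes to pseudo-uniform rows,
and regularising it too shrinks the decoded values toward their column
means, which distorts the thresholded marginals and inter-item dependence
of the generated data. Training
minimises a composite objective

    L = L_recon + lambda * L_marginal,

where L_recon is the mean squared reconstruction error and L_marginal
penalises the squared deviation of each reconstructed column mean from 0.5,
anchoring the output to the uniform marginal domain. Optimisation is Adam
with mini-batches, ReduceLROnPlateau-style halving, and early stopping that
restores the best-validation weights. Every stochastic element (weight
initialisation, batch shuffling, dropout masks) is drawn from one seeded
generator, so a run is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .config import RunConfig

__all__ = ["Autoencoder", "TrainingTrace", "composite_loss", "train_autoencoder"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


# --------------------------------------------------------------------- layers


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialisation, suited to rectified units
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, training: bool):
        self._x = x if training else None
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def state(self):
        return {"W": self.W, "b": self.b}


class _BatchNorm:
    """Batch normalisation after the affine transform, before the rectifier."""

    def __init__(self, n: int):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)

    def forward(self, x, training: bool):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
            self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
            self._inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            self._xhat = (x - mu) * self._inv_std
            return self.gamma * self._xhat + self.beta
        return self.gamma * (x - self.running_mean) / np.sqrt(
            self.running_var + _BN_EPS) + self.beta

    def backward(self, grad):
        m = grad.shape[0]
        self.dgamma = (grad * self._xhat).sum(axis=0)
        self.dbeta = grad.sum(axis=0)
        g = grad * self.gamma
        return self._inv_std * (
            g - g.mean(axis=0) - self._xhat * (g * self._xhat).mean(axis=0)
        ) if m > 1 else g * self._inv_std

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def state(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "running_mean": self.running_mean, "running_var": self.running_var}


class _ReLU:
    def forward(self, x, training: bool):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask

    def params(self):
        return []

    def state(self):
        return {}


class _Dropout:
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training: bool):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def params(self):
        return []

    def state(self):
        return {}


class _Sigmoid:
    def forward(self, x, training: bool):
        self._y = expit(x)
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)

    def params(self):
        return []

    def state(self):
        return {}


# ---------------------------------------------------------------- autoencoder


class Autoencoder:
    """Encoder/decoder stack with an explicit latent boundary.

    ``encode``/``decode`` run in evaluation mode (stored batch-norm
    statistics, dropout off) and are deterministic given the weights.
    """

    def __init__(self, n_items: int, config: RunConfig, rng: np.random.Generator):
        self.n_items = n_items
        self.latent_dim = config.latent_dim
        enc_dims = list(config.encoder_dims)
        self.encoder: list = []
        prev = n_items
        for width in enc_dims:
            self.encoder.append(_Dense(prev, width, rng))
            self.encoder.append(_BatchNorm(width))
            self.encoder.append(_ReLU())
            self.encoder.append(_Dropout(config.dropout_rate, rng))
            prev = width
        self.encoder.append(_Dense(prev, config.latent_dim, rng))  # linear latent

        self.decoder: list = []
        prev = config.latent_dim
        for width in reversed(enc_dims):
            self.decoder.append(_Dense(prev, width, rng))
            self.decoder.append(_BatchNorm(width))
            self.decoder.append(_ReLU())
            prev = width
        self.decoder.append(_Dense(prev, n_items, rng))
        self.decoder.append(_Sigmoid())

    @property
    def layers(self):
        return self.encoder + self.decoder

    def _run(self, layers, x, training):
        for layer in layers:
            x = layer.forward(x, training)
        return x

    def forward(self, U, training: bool):
        return self._run(self.layers, np.asarray(U, dtype=float), training)

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def encode(self, U) -> np.ndarray:
        U = np.atleast_2d(np.asarray(U, dtype=float))
        if U.shape[1] != self.n_items:
            raise ValueError(f"expected {self.n_items} columns, got {U.shape[1]}")
        return self._run(self.encoder, U, training=False)

    def decode(self, Z) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.latent_dim:
            raise ValueError(f"expected {self.latent_dim} columns, got {Z.shape[1]}")
        return self._run(self.decoder, Z, training=False)

    # ----------------------------------------------------------- state I/O

    def get_state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.state().items():
                out[f"layer{i:02d}.{name}"] = arr.copy()
        return out

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.state():
                setattr(layer, name, state[f"layer{i:02d}.{name}"].copy())


# ------------------------------------------------------------------ training


def composite_loss(U, U_hat, lam: float) -> dict[str, float]:
    """Reconstruction MSE plus the marginal-preservation penalty.

    Returns a dict with ``recon``, ``marginal``, ``lambda`` and ``total``;
    total = recon + lambda * marginal.
    """
    U = np.asarray(U, dtype=float)
    U_hat = np.asarray(U_hat, dtype=float)
    if U.shape != U_hat.shape:
        raise ValueError("U and U_hat must have the same shape")
    recon = float(np.mean((U - U_hat) ** 2))
    marginal = float(np.mean((U_hat.mean(axis=0) - 0.5) ** 2))
    return {"recon": recon, "marginal": marginal, "lambda": lam,
            "total": recon + lam * marginal}


def _loss_gradient(U, U_hat, lam: float) -> np.ndarray:
    n, K = U.shape
    grad = 2.0 * (U_hat - U) / (n * K)
    grad += lam * 2.0 * (U_hat.mean(axis=0) - 0.5)[None, :] / (K * n)
    return grad


class _Adam:
    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, param_triples):
        self.t += 1
        for key, (name, p, g) in enumerate(param_triples):
            m = self.m.setdefault(key, np.zeros_like(p))
            v = self.v.setdefault(key, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainingTrace:
    """Per-epoch optimisation record."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_epoch: int = -1


_IMPROVE_TOL = 1e-6  # strict decrease needed to count as plateau-breaking


def train_autoencoder(U_train, U_val, config: RunConfig, seed: int):
    """Train the autoencoder; returns (model, TrainingTrace).

    Early stopping monitors the composite validation loss (evaluation mode)
    and restores the best-epoch weights. The learning rate halves after
    ``lr_patience`` epochs without improvement beyond 1e-6.
    """
    U_train = np.asarray(U_train, dtype=float)
    U_val = np.asarray(U_val, dtype=float)
    rng = np.random.default_rng(seed)
    model = Autoencoder(U_train.shape[1], config, rng)
    opt = _Adam(config.learning_rate)
    trace = TrainingTrace()
    lam = config.lambda_marginal

    best_val = np.inf
    best_state = model.get_state()
    epochs_since_best = 0
    lr_wait = 0

    n = U_train.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = U_train[idx]
            out = model.forward(batch, training=True)
            loss = composite_loss(batch, out, lam)
            if not np.isfinite(loss["total"]):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            batch_losses.append(loss["total"])
            model.backward(_loss_gradient(batch, out, lam))
            opt.step([t for layer in model.layers for t in layer.params()])

        val_out = model.forward(U_val, training=False)
        val_loss = composite_loss(U_val, val_out, lam)["total"]
        trace.train_loss.append(float(np.mean(batch_losses)))
        trace.val_loss.append(float(val_loss))
        trace.learning_rate.append(opt.lr)

        if val_loss < best_val - _IMPROVE_TOL:
            best_val = val_loss
            best_state = model.get_state()
            trace.best_epoch = epoch
            epochs_since_best = 0
            lr_wait = 0
        else:
            epochs_since_best += 1
            lr_wait += 1
            if lr_wait >= config.lr_patience:
                opt.lr *= config.lr_factor
                lr_wait = 0
            if epochs_since_best >= config.early_stop_patience:
                trace.stop_epoch = epoch
                break
    if trace.stop_epoch < 0:
        trace.stop_epoch = len(trace.val_loss) - 1
    model.set_state(best_state)
    return model, trace
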