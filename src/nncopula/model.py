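"""The neural copula generative model and its fitted results object.

:class:`NeuralCopula` couples three ingredients:

1. a randomized probability integral transform that lifts binary responses
   into copula (pseudo-uniform) space using the training-sample marginal
   probabilities;
2. an autoencoder that learns the inter-item dependence structure of the
   pseudo-uniform rows in a d-dimensional latent space;
3. a Gaussian-kernel density over the training latent codes from which new
   examinees are sampled.

Fitting returns a :class:`NeuralCopulaResults` whose ``generate`` method runs
the forward pipeline — sample latent codes from the KDE, decode to
pseudo-uniform space, threshold at 1 - p_hat — to produce synthetic binary
response matrices whose item marginals match the training data by
construction and whose dependence structure is inherited from the latent
model.

Example
-------
>>> model = NeuralCopula(Y_train, Y_val, config=RunConfig(max_epochs=100))
>>> res = model.fit(seed=42)
>>> synth = res.generate(m=3244, seed=42)
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig, spawn_seeds
from .copula import inverse_pit, marginal_probabilities, randomized_pit
from .kde import LatentKDE
from .network import Autoencoder, TrainingTrace, train_autoencoder

__all__ = ["NeuralCopula", "NeuralCopulaResults"]

_CHECKPOINT_VERSION = "1.0"


class NeuralCopula:
    """Neural-network copula model of a binary response matrix.

    Parameters
    ----------
    Y_train : (n, K) binary matrix or DataFrame — fits the marginals,
        the dependence network and the latent density.
    Y_val : held-out binary matrix for early stopping; its rows are
        transformed with the *training* marginal probabilities.
    config : RunConfig, optional.
    """

    def __init__(self, Y_train, Y_val, config: RunConfig | None = None):
        if isinstance(Y_train, pd.DataFrame):
            self.item_labels = [str(c) for c in Y_train.columns]
            Y_train = Y_train.to_numpy()
        else:
            Y_train = np.asarray(Y_train)
            self.item_labels = [f"item{k + 1:02d}" for k in range(Y_train.shape[1])]
        Y_val = Y_val.to_numpy() if isinstance(Y_val, pd.DataFrame) else np.asarray(Y_val)
        if Y_train.shape[1] != Y_val.shape[1]:
            raise ValueError("train and validation matrices must share items")
        self.Y_train = Y_train.astype(np.int8)
        self.Y_val = Y_val.astype(np.int8)
        self.config = config or RunConfig()
        self.p_hat = marginal_probabilities(self.Y_train)

    def fit(self, seed: int | None = None) -> "NeuralCopulaResults":
        """Transform, train and fit the latent density; returns results.

        ``seed`` defaults to the config's master seed. Child seeds are
        spawned for the PIT draw and the network so the whole fit is a
        deterministic function of (data, config, seed).
        """
        if seed is None:
            seed = self.config.master_seed
        pit_seed, val_pit_seed, net_seed = spawn_seeds(seed, 3)
        U_train = randomized_pit(self.Y_train, self.p_hat, pit_seed)
        U_val = randomized_pit(self.Y_val, self.p_hat, val_pit_seed)
        net, trace = train_autoencoder(U_train, U_val, self.config, net_seed)
        codes = net.encode(U_train)
        kde = LatentKDE.fit(codes, self.config.kde_bandwidth)
        return NeuralCopulaResults(
            network=net, kde=kde, p_hat=self.p_hat.copy(),
            item_labels=list(self.item_labels), config=self.config,
            trace=trace, fit_seed=int(seed),
        )


@dataclass
class NeuralCopulaResults:
    """Trained generator: network weights, marginals, latent density."""

    network: Autoencoder
    kde: LatentKDE
    p_hat: np.ndarray
    item_labels: list[str]
    config: RunConfig
    trace: TrainingTrace
    fit_seed: int

    def __post_init__(self):
        if len(self.p_hat) != self.network.n_items:
            raise ValueError("p_hat length must equal the decoder output width")

    # ----------------------------------------------------------- generation

    def generate(self, m: int, seed: int) -> pd.DataFrame:
        """Generate an m × K synthetic binary response matrix.

        Pipeline: KDE latent sample -> decoder (evaluation mode, so the
        output is batch-size independent) -> inverse PIT threshold at
        1 - p_hat.
        """
        if m < 1:
            raise ValueError("m must be >= 1")
        z = self.kde.sample(m, seed)
        U = self.network.decode(z)
        Y = inverse_pit(U, self.p_hat)
        return pd.DataFrame(Y, columns=self.item_labels)

    def generate_batch(self, m: int, M: int, master_seed: int) -> list[pd.DataFrame]:
        """M independent synthetic datasets using spawned child seeds."""
        if M < 1:
            raise ValueError("M must be >= 1")
        return [self.generate(m, s) for s in spawn_seeds(master_seed, M)]

    # -------------------------------------------------------------- summary

    def summary(self) -> str:
        t = self.trace
        lines = [
            "Neural copula generator",
            f"items: {len(self.item_labels)}   latent dim: "
            f"{self.config.latent_dim}   KDE bandwidth: "
            f"{self.kde.bandwidth} (Silverman ref {self.kde.h_silverman:.4f})",
            f"epochs run: {len(t.val_loss)}   best epoch: {t.best_epoch}   "
            f"best val loss: {min(t.val_loss):.6f}",
            f"final learning rate: {t.learning_rate[-1]:.2e}   "
            f"fit seed: {self.fit_seed}",
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------ persistence

    def save(self, path) -> None:
        """Write a single self-describing checkpoint (weights, batch-norm
        statistics, marginals, latent codes, config, seed)."""
        header = {
            "format_version": _CHECKPOINT_VERSION,
            "item_labels": self.item_labels,
            "config": self.config.to_dict(),
            "fit_seed": self.fit_seed,
            "kde_bandwidth": self.kde.bandwidth,
        }
        arrays = {f"net.{k}": v for k, v in self.network.get_state().items()}
        arrays["p_hat"] = self.p_hat
        arrays["kde_codes"] = self.kde.codes
        arrays["header_json"] = np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "NeuralCopulaResults":
        with np.load(path) as data:
            header = json.loads(bytes(data["header_json"]).decode())
            config = RunConfig.from_dict(header["config"])
            rng = np.random.default_rng(0)  # weights overwritten below
            net = Autoencoder(len(header["item_labels"]), config, rng)
            net.set_state({k[len("net."):]: data[k] for k in data.files
                           if k.startswith("net.")})
            kde = LatentKDE.fit(data["kde_codes"], header["kde_bandwidth"])
            return cls(network=net, kde=kde, p_hat=data["p_hat"].copy(),
                       item_labels=header["item_labels"], config=config,
                       trace=TrainingTrace(), fit_seed=header["fit_seed"])
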