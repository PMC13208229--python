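"""Run configuration and deterministic seed management.

A single :class:`RunConfig` carries every tunable of the pipeline: the
autoencoder architecture and optimiser schedule, the latent-space KDE
bandwidth, the train/validation/test partition fractions, and the Monte
Carlo replication count. Child seeds for replicated runs are spawned
deterministically from one master seed so that any figure in a report can
be regenerated bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = ["RunConfig", "SeedPolicy", "spawn_seeds"]

_FRACTION_TOL = 1e-9


@dataclass
class RunConfig:
    """Hyperparameters of one training/generation run.

    Parameters
    ----------
    encoder_dims : sequence of int
        Hidden-layer widths of the encoder, input side first. The decoder
        mirrors them in reverse.
    latent_dim : int
        Dimensionality ``d`` of the latent code.
    dropout_rate : float
        Dropout probability on hidden layers, in ``[0, 1)``.
    lambda_marginal : float
        Weight of the marginal-preservation loss term.
    learning_rate : float
        Initial Adam step size.
    batch_size : int
        Mini-batch size for stochastic optimisation.
    lr_patience : int
        Epochs without validation improvement before the learning rate is
        multiplied by ``lr_factor``.
    lr_factor : float
        Multiplicative learning-rate decay on plateau.
    early_stop_patience : int
        Epochs without validation improvement before training stops; the
        best-validation weights are restored.
    max_epochs : int
        Hard cap on training epochs.
    kde_bandwidth : float
        Isotropic Gaussian-kernel bandwidth ``h`` for latent sampling.
    train_fraction, val_fraction, test_fraction : float
        Stratified partition fractions; must sum to one.
    master_seed : int
        Master seed; every stochastic stage derives a child seed from it.
    n_mc_replications : int
        Number of synthetic replications ``M`` in the precision facet.
    """

    encoder_dims: Sequence[int] = (256, 128, 64)
    latent_dim: int = 20
    dropout_rate: float = 0.2
    lambda_marginal: float = 0.1
    learning_rate: float = 0.001
    batch_size: int = 64
    lr_patience: int = 10
    lr_factor: float = 0.5
    early_stop_patience: int = 20
    max_epochs: int = 500
    kde_bandwidth: float = 0.2
    train_fraction: float = 0.64
    val_fraction: float = 0.16
    test_fraction: float = 0.20
    master_seed: int = 42
    n_mc_replications: int = 500

    def __post_init__(self) -> None:
        self.encoder_dims = tuple(int(w) for w in self.encoder_dims)
        if not self.encoder_dims or any(w <= 0 for w in self.encoder_dims):
            raise ValueError("encoder_dims must be strictly positive integers")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.lambda_marginal < 0:
            raise ValueError("lambda_marginal must be nonnegative")
        for name in ("learning_rate", "kde_bandwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("batch_size", "lr_patience", "early_stop_patience",
                     "max_epochs", "n_mc_replications"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must lie in (0, 1)")
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(f"partition fractions sum to {total!r}, expected 1")

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.train_fraction, self.val_fraction, self.test_fraction)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["encoder_dims"] = list(self.encoder_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def spawn_seeds(master: int, count: int) -> list[int]:
    """Derive ``count`` child seeds from a master seed.

    Uses :class:`numpy.random.SeedSequence` spawning, a counter-based scheme
    that is deterministic across platforms: the same master always yields the
    same ordered child list, and children are collision-free with
    overwhelming probability. Returned seeds fit in a signed 32-bit integer.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    children = np.random.SeedSequence(master).spawn(count)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


@dataclass
class SeedPolicy:
    """A master seed and the child seeds already spawned from it."""

    master_seed: int
    children: list[int] = field(default_factory=list)

    def spawn(self, count: int) -> list[int]:
        start = len(self.children)
        seeds = spawn_seeds(self.master_seed, start + count)[start:]
        self.children.extend(seeds)
        return seeds
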