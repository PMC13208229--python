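"""Ground-truth 2PL response simulator.

Generates unidimensional two-parameter-logistic response matrices with known
item parameters and abilities, optionally contaminated with testlet-induced
local dependence, so that every downstream stage (copula transform, network
training, estimation, validation) can be exercised against a known truth.

Under the 2PL model an examinee with ability ``theta ~ N(0, 1)`` answers item
``k`` correctly with probability ``1 / (1 + exp(-a_k (theta - b_k)))``, where
``a_k > 0`` is the discrimination and ``b_k`` the difficulty. With a testlet
map, items in cluster ``c`` share an extra examinee-specific effect
``gamma * u_{ic}``, ``u ~ N(0,1)``, which induces within-cluster dependence
beyond the common trait; ``gamma = 0`` recovers strict local independence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .irt import two_pl_probability

__all__ = ["SimulationDesign", "simulate_2pl", "population_marginal",
           "default_item_params"]


def default_item_params(K: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw a realistic item bank: a ~ log-normal(0, 0.5^2) truncated to
    [0.5, 3.5], b ~ N(0, 1) truncated to [-2.5, 2.5]."""
    rng = np.random.default_rng(seed)
    a = np.empty(K)
    b = np.empty(K)
    for k in range(K):
        x = rng.lognormal(0.0, 0.5)
        while not 0.5 <= x <= 3.5:
            x = rng.lognormal(0.0, 0.5)
        a[k] = x
        y = rng.normal()
        while abs(y) > 2.5:
            y = rng.normal()
        b[k] = y
    return a, b


@dataclass
class SimulationDesign:
    """Specification of one simulated dataset.

    ``a`` and ``b`` may be given explicitly (length-K arrays); otherwise a
    default item bank is drawn from the design seed. ``testlets`` maps item
    index -> cluster id; ``gamma`` is the cluster-effect SD.
    """

    n: int
    K: int
    a: np.ndarray | None = None
    b: np.ndarray | None = None
    testlets: Mapping[int, int] | None = None
    gamma: float = 0.0
    seed: int = 0
    _resolved: bool = field(default=False, repr=False)

    def __post_init__(self):
        if self.n < 1 or self.K < 1:
            raise ValueError("n and K must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.a is None or self.b is None:
            a, b = default_item_params(self.K, self.seed)
            self.a = a if self.a is None else np.asarray(self.a, float)
            self.b = b if self.b is None else np.asarray(self.b, float)
        else:
            self.a = np.asarray(self.a, float)
            self.b = np.asarray(self.b, float)
        if len(self.a) != self.K or len(self.b) != self.K:
            raise ValueError("a and b must have length K")
        if (self.a <= 0).any():
            raise ValueError("all discriminations must be positive")


def simulate_2pl(design: SimulationDesign):
    """Simulate a binary response matrix under the (possibly testlet) 2PL.

    Returns
    -------
    Y : pandas.DataFrame of shape (n, K), int8
    params : pandas.DataFrame with columns ``a`` and ``b`` (the truth)
    theta : ndarray of the true abilities
    """
    rng = np.random.default_rng(design.seed)
    theta = rng.standard_normal(design.n)
    eff_theta = np.repeat(theta[:, None], design.K, axis=1)
    if design.testlets and design.gamma > 0:
        clusters = sorted(set(design.testlets.values()))
        u = rng.standard_normal((design.n, len(clusters)))
        col = {c: j for j, c in enumerate(clusters)}
        for k, c in design.testlets.items():
            eff_theta[:, k] += design.gamma * u[:, col[c]]
    P = two_pl_probability(eff_theta, design.a, design.b)
    Y = (rng.random((design.n, design.K)) < P).astype(np.int8)
    labels = [f"item{k + 1:02d}" for k in range(design.K)]
    params = pd.DataFrame({"a": design.a, "b": design.b}, index=labels)
    return pd.DataFrame(Y, columns=labels), params, theta


def population_marginal(a: float, b: float, n_points: int = 201) -> float:
    """P(Y=1) marginalised over theta ~ N(0,1) by Gauss–Hermite quadrature."""
    if a <= 0:
        raise ValueError("a must be positive")
    x, w = np.polynomial.hermite.hermgauss(n_points)
    theta = np.sqrt(2.0) * x
    weights = w / np.sqrt(np.pi)
    return float(np.sum(weights * two_pl_probability(theta, a, b)))
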