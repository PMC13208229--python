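"""Pure 2PL model functions: response probability, information, CSEM.

All functions broadcast over numpy arrays. The item characteristic curve is
``P(theta) = 1 / (1 + exp(-a (theta - b)))``; item information is
``I_k(theta) = a^2 P (1 - P)``, maximised at ``theta = b`` with value
``a^2 / 4``; the test information function is the sum over items and the
conditional standard error of measurement is its reciprocal square root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "two_pl_probability",
    "item_information",
    "ability_grid",
    "test_information_and_csem",
    "InformationProfile",
]


def two_pl_probability(theta, a, b):
    """2PL probability of a correct response; broadcasts over inputs."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("discrimination a must be positive")
    return expit(a * (np.asarray(theta, dtype=float) - np.asarray(b, dtype=float)))


def item_information(theta, a, b):
    """Fisher information of one 2PL item at ability theta: a^2 P (1-P)."""
    P = two_pl_probability(theta, a, b)
    return np.asarray(a, dtype=float) ** 2 * P * (1.0 - P)


def ability_grid(lo: float = -4.0, hi: float = 4.0, n_points: int = 100) -> np.ndarray:
    """Default evaluation grid: n_points equally spaced on [lo, hi], endpoints
    inclusive."""
    if n_points < 2 or hi <= lo:
        raise ValueError("need an increasing grid with at least 2 points")
    return np.linspace(lo, hi, n_points)


@dataclass
class InformationProfile:
    """Item/test information and CSEM evaluated on an ability grid."""

    theta: np.ndarray          # (Q,)
    item_info: np.ndarray      # (Q, K)
    tif: np.ndarray            # (Q,)
    csem: np.ndarray           # (Q,)
    item_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.item_info, columns=self.item_labels)
        df.insert(0, "theta", self.theta)
        df["TIF"] = self.tif
        df["CSEM"] = self.csem
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def test_information_and_csem(params, grid: np.ndarray | None = None) -> InformationProfile:
    """Evaluate per-item information, TIF and CSEM on an ability grid.

    Parameters
    ----------
    params : DataFrame with columns ``a`` and ``b`` (index = item labels),
        or any object with ``a``/``b`` array attributes.
    grid : ability grid; defaults to 100 points on [-4, 4].
    """
    a, b, labels = _unpack_params(params)
    if len(a) < 1:
        raise ValueError("need at least one item")
    if grid is None:
        grid = ability_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    info = item_information(grid[:, None], a[None, :], b[None, :])
    tif = info.sum(axis=1)
    if np.any(tif <= 0):
        raise ValueError("test information vanished on the grid")
    return InformationProfile(grid, info, tif, 1.0 / np.sqrt(tif), labels)


def _unpack_params(params):
    if isinstance(params, pd.DataFrame):
        return (params["a"].to_numpy(float), params["b"].to_numpy(float),
                [str(i) for i in params.index])
    a = np.asarray(params.a, dtype=float)
    b = np.asarray(params.b, dtype=float)
    return a, b, [f"item{k + 1:02d}" for k in range(len(a))]
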