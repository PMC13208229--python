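"""Gaussian kernel density model over latent codes.

The latent distribution is characterised non-parametrically as an equal-weight
mixture of isotropic Gaussians centred on the training codes with a single
scalar bandwidth h:

    f(z) = (1 / (n h^d)) sum_i K((z - z_i) / h),   K = standard Gaussian.

Sampling from f is exact: pick a training code uniformly and add h times a
standard-normal d-vector. A non-parametric density is used (rather than a
Gaussian fit) because deterministic autoencoder latents are typically
non-Gaussian with informative tails corresponding to extreme examinees; the
bandwidth trades tail coverage against over-smoothing of the dependence
structure. The Silverman rule-of-thumb value is computed for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LatentKDE", "silverman_bandwidth"]


def silverman_bandwidth(codes: np.ndarray) -> float:
    """Multivariate Silverman reference bandwidth.

    h = (4 / (d + 2))^(1/(d+4)) * n^(-1/(d+4)) * sigma_bar, with sigma_bar
    the mean per-dimension sample SD.
    """
    codes = np.atleast_2d(codes)
    n, d = codes.shape
    sigma_bar = float(np.mean(codes.std(axis=0, ddof=1)))
    return (4.0 / (d + 2)) ** (1.0 / (d + 4)) * n ** (-1.0 / (d + 4)) * sigma_bar


@dataclass
class LatentKDE:
    """Fitted kernel density over latent codes."""

    codes: np.ndarray       # (n, d)
    bandwidth: float
    h_silverman: float

    @classmethod
    def fit(cls, codes, bandwidth: float) -> "LatentKDE":
        codes = np.atleast_2d(np.asarray(codes, dtype=float))
        if codes.shape[0] < 2:
            raise ValueError("need at least 2 codes to fit a KDE")
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        return cls(codes=codes.copy(), bandwidth=float(bandwidth),
                   h_silverman=silverman_bandwidth(codes))

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def d(self) -> int:
        return self.codes.shape[1]

    def density(self, z) -> np.ndarray:
        """Evaluate f(z) by direct mixture summation (exact, O(n) per point)."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        h, d = self.bandwidth, self.d
        diff = (z[:, None, :] - self.codes[None, :, :]) / h   # (m, n, d)
        sq = np.sum(diff * diff, axis=2)
        kern = np.exp(-0.5 * sq) / (2.0 * np.pi) ** (d / 2.0)
        return kern.mean(axis=1) / h**d

    def sample(self, m: int, seed: int) -> np.ndarray:
        """Draw m latent codes exactly from the fitted mixture."""
        if m < 1:
            raise ValueError("m must be >= 1")
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, self.n, size=m)
        return self.codes[idx] + self.bandwidth * rng.standard_normal((m, self.d))
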