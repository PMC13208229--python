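"""Randomized probability integral transform for binary margins.

A binary response has no unique copula representation; the randomized PIT
resolves the discreteness by spreading each response uniformly over the
sub-interval of (0, 1) that its outcome occupies under the item's marginal
probability p_k:

    U ~ Uniform(1 - p_k, 1)   if Y = 1,
    U ~ Uniform(0, 1 - p_k)   if Y = 0.

Marginally U is exactly Uniform(0, 1) while rank dependence between items is
preserved, so the autoencoder can model the dependence structure in copula
space. The inverse transform thresholds at 1 - p_k (strict inequality),
making the round trip exact and guaranteeing E[Y_syn] = p_k for uniform U.
"""

from __future__ import annotations

import numpy as np

__all__ = ["randomized_pit", "inverse_pit", "marginal_probabilities"]

_EPS = np.finfo(float).eps


def marginal_probabilities(Y) -> np.ndarray:
    """Column means of a binary matrix; errors on degenerate items."""
    p = np.asarray(Y, dtype=float).mean(axis=0)
    if np.any((p <= 0) | (p >= 1)):
        bad = np.flatnonzero((p <= 0) | (p >= 1))
        raise ValueError(f"degenerate items (all 0 or all 1) at columns {bad.tolist()}")
    return p


def randomized_pit(Y, p, seed: int) -> np.ndarray:
    """Map binary responses to pseudo-uniform variates.

    Draws are taken from the open sub-intervals (endpoints excluded by a
    machine-epsilon shift) so that the strict threshold of
    :func:`inverse_pit` inverts every cell exactly.
    """
    Y = np.asarray(Y)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("marginal probabilities must lie strictly in (0, 1)")
    if Y.shape[1] != p.shape[0]:
        raise ValueError("column count of Y must match length of p")
    rng = np.random.default_rng(seed)
    V = rng.random(Y.shape)  # in [0, 1)
    V = np.clip(V, _EPS, 1.0 - _EPS)
    thresh = 1.0 - p[None, :]
    # Y=1 -> (1-p, 1); Y=0 -> (0, 1-p)
    U = np.where(np.asarray(Y, dtype=bool),
                 thresh + V * p[None, :],
                 V * thresh)
    return U


def inverse_pit(U, p) -> np.ndarray:
    """Threshold pseudo-uniform variates back to binary: Y = 1{U > 1 - p}."""
    U = np.asarray(U, dtype=float)
    p = np.asarray(p, dtype=float)
    if U.shape[-1] != p.shape[0]:
        raise ValueError("column count of U must match length of p")
    return (U > 1.0 - p).astype(np.int8)
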