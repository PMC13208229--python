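"""Shared fixtures: a simulated benchmark study and one trained generator.

The benchmark study simulates a 20-item assessment from the bundled
published item parameters (n = 5069 examinees, theta ~ N(0,1)), partitions
it 64/16/20 by score decile, and fits the 2PL reference model on the
training partition. Training the neural copula once per session keeps the
end-to-end tests affordable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from nncopula import (NeuralCopula, RunConfig, SimulationDesign, TwoPL,
                      simulate_2pl, stratified_partition)
from nncopula.datasets import benchmark_item_params

warnings.filterwarnings("ignore", message="n=.* is small for MML")


@pytest.fixture(scope="session")
def benchmark_sim():
    """Simulated study: (Y_train, Y_val, Y_test, truth params, theta)."""
    bench = benchmark_item_params()
    design = SimulationDesign(n=5069, K=20, a=bench["a_real"].to_numpy(),
                              b=bench["b_real"].to_numpy(), seed=7)
    Y, truth, theta = simulate_2pl(design)
    Y_train, Y_val, Y_test = stratified_partition(Y, (0.64, 0.16, 0.20), seed=1)
    return Y_train, Y_val, Y_test, truth, theta


@pytest.fixture(scope="session")
def reference_fit(benchmark_sim):
    """2PL MML-EM fit of the training partition (the benchmark 'real' fit)."""
    Y_train = benchmark_sim[0]
    return TwoPL(Y_train).fit()


@pytest.fixture(scope="session")
def trained_generator(benchmark_sim):
    """Neural copula trained once on the benchmark study partitions."""
    Y_train, Y_val = benchmark_sim[0], benchmark_sim[1]
    return NeuralCopula(Y_train, Y_val, RunConfig()).fit(seed=42)


@pytest.fixture()
def tiny_config():
    """Small architecture for fast training-behaviour tests."""
    return RunConfig(encoder_dims=(32, 16), latent_dim=4, max_epochs=25,
                     early_stop_patience=8, lr_patience=4, batch_size=32)


@pytest.fixture(scope="session")
def small_sim():
    """A small, quickly estimable 2PL dataset (n=600, K=10)."""
    design = SimulationDesign(n=600, K=10, seed=11)
    return simulate_2pl(design)


def rng_binary(n, k, seed, p=0.5):
    rng = np.random.default_rng(seed)
    return (rng.random((n, k)) < p).astype(np.int8)
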