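"""Shared fixtures: one synthetic economy, one calibrated model and one
solved policy run reused across the suite."""

import time

import pytest

from fiscalfood import (ModelDimensions, ScenarioConfig, build_model,
                        decompose_pathways, find_tax_rate,
                        generate_synthetic_economy)

SEED = 1


@pytest.fixture(scope="session")
def dims():
    return ModelDimensions()


@pytest.fixture(scope="session")
def noisy_bundle(dims):
    """(truth, unbalanced SAM, elasticity priors) at 5% noise."""
    return generate_synthetic_economy(dims, seed=SEED, noise_level=0.05)


@pytest.fixture(scope="session")
def truth(dims):
    """Noise-free ground truth (priors coincide with the truth)."""
    return generate_synthetic_economy(dims, seed=SEED, noise_level=0.0)[0]


@pytest.fixture(scope="session")
def model(truth):
    """Calibrated model with the solved 20-period counterfactual baseline."""
    return build_model(truth, seed=SEED)


@pytest.fixture(scope="session")
def policy(model):
    """Tax rate hitting the 50% intake-reduction target, plus its run and
    the wall-clock time of the search."""
    t0 = time.perf_counter()
    tau, result = find_tax_rate(model, ScenarioConfig())
    elapsed = time.perf_counter() - t0
    return tau, result, elapsed


@pytest.fixture(scope="session")
def decomposition(model, policy):
    tau, result, _ = policy
    return decompose_pathways(model, ScenarioConfig(), tax_rate=tau,
                              total_result=result)
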