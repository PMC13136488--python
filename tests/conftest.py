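"""Shared fixtures.

The expensive study-scale fixture (thousands of simulated circuits and
a multi-seed CVAE fit) is session-scoped and lazy: only tests that ask
for it pay for it, and they share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from circuitgen import (
    CVAE,
    RateSet,
    SamplingConfig,
    SignalConfig,
    SolverConfig,
    TrainConfig,
    build_dataset,
    sample_energy_circuits,
    train_multi_seed,
)
from circuitgen.pipeline import simulate_circuit_table


@pytest.fixture(scope="session")
def rates() -> RateSet:
    return RateSet()


@pytest.fixture(scope="session")
def small_metrics() -> pd.DataFrame:
    """Signal-protocol metrics for a small batch of random circuits."""
    circuits = sample_energy_circuits(SamplingConfig(n_circuits=40, seed=11))
    return simulate_circuit_table(circuits)


@pytest.fixture(scope="session")
def study():
    """Study-scale pipeline artefacts shared by the acceptance tests.

    5,000 parameter-sampled circuits simulated under the two-phase step
    protocol, filtered/normalised with scalar adaptation labels
    (80/20 split), and a CVAE trained for each of 5 seeds.
    """
    circuits = sample_energy_circuits(SamplingConfig(n_circuits=5000, seed=101))
    metrics = simulate_circuit_table(circuits)
    dataset = build_dataset(metrics, objective="adaptation", seed=101, test_fraction=0.2)
    train_cfg = TrainConfig(seed=0)
    best, all_results = train_multi_seed(dataset, seeds=[0, 1, 2, 3, 4], train=train_cfg)
    return {
        "metrics": metrics,
        "dataset": dataset,
        "best": best,
        "all_results": all_results,
    }
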