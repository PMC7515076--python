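import numpy as np
import pytest

from hippogamma.circuit import build_circuit
from hippogamma.engine import run_batch, run_simulation
from hippogamma.protocols import Condition, build_condition_inputs, standard_conditions


@pytest.fixture(scope="session")
def circuit():
    return build_circuit()


@pytest.fixture(scope="session")
def control_recording(circuit):
    """One full-length seeded control run."""
    cond = standard_conditions(duration=10_000.0, n_runs=1, base_seed=7)["control"]
    recs, _ = run_batch(cond, circuit)
    return recs[0]


@pytest.fixture(scope="session")
def short_control_batch(circuit):
    """Two short control runs for cheap structural tests."""
    cond = standard_conditions(duration=3_000.0, n_runs=2, base_seed=3)["control"]
    recs, manifest = run_batch(cond, circuit)
    return recs, manifest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
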