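import numpy as np
import pytest

import couptake as cu
from couptake.protocols import adaptation_ramp_protocol, static_induction_protocol


@pytest.fixture(scope="session")
def tandem_params() -> cu.UptakeModelParams:
    """Static-experiment fit for the tandem-scFv strain (the dynamics testbed)."""
    return cu.parameter_set("tandem_scfv")


@pytest.fixture(scope="session")
def combination_params() -> cu.UptakeModelParams:
    return cu.parameter_set("combination")


@pytest.fixture(scope="session")
def default_truth() -> cu.SimTruth:
    return cu.SimTruth()


@pytest.fixture(scope="session")
def static_run(default_truth) -> cu.SimulationOutput:
    """Noise-free 6 h induced fed-batch at the 0.25 g/g/h adaptation setpoint."""
    return cu.simulate(
        static_induction_protocol(0.25, duration=6.0, sampling_min=10.0), default_truth
    )


@pytest.fixture(scope="session")
def ramp_run(default_truth) -> cu.SimulationOutput:
    """Noise-free adaptation + ramp-up cultivation."""
    return cu.simulate(adaptation_ramp_protocol(ramp_h=2.9), default_truth)


@pytest.fixture(scope="session")
def clean_combined_points(default_truth) -> list:
    """Noise-free rate points of the combined (ramp-up + two static) design."""
    suite = cu.generate_benchmark_suite(default_truth, seed=0, noise=False)
    return suite["combined"]["points"]
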