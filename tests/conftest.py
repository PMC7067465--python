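import numpy as np
import pytest

from tctalpha import (Connectivity, ModelParameters, SimulationConfig,
                      Trajectory, default_connectivity, default_parameters)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return default_parameters()


@pytest.fixture(scope="session")
def conn() -> Connectivity:
    return default_connectivity()


@pytest.fixture()
def short_cfg() -> SimulationConfig:
    """Deterministic 2 s run, cheap enough for unit tests."""
    return SimulationConfig(duration=2.0, transient=0.5, noise_on=False,
                            n_realizations=1)


def make_trajectory(v: np.ndarray, dt: float, transient: float = 0.0) -> Trajectory:
    """Wrap a raw series as a Trajectory (for analysis-only tests)."""
    cfg = SimulationConfig(dt=dt, duration=len(v) * dt, transient=transient,
                           noise_on=False, n_realizations=1)
    return Trajectory(t=np.arange(len(v)) * dt, states=None, v_tcr=v,
                      dt=dt, seed=0, config=cfg)
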