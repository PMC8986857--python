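import numpy as np
import pandas as pd
import pytest

from peaq import (ConstantCa, NoiseModel, ProtocolSpec, build_schedule,
                  default_gcamp6s_q, simulate_trace)
from peaq.workflows import calibrate_titration, simulate_titration


@pytest.fixture(scope="session")
def params():
    return default_gcamp6s_q()


@pytest.fixture(scope="session")
def protocol():
    return ProtocolSpec(n_cycles=3)


@pytest.fixture(scope="session")
def schedule(protocol):
    return build_schedule(protocol)


@pytest.fixture(scope="session")
def titration(params, protocol):
    """Noiseless simulated 11-point titration (contrast + fluorescence)."""
    return simulate_titration(params, protocol, seed=0)


@pytest.fixture(scope="session")
def curves(titration, protocol):
    return calibrate_titration(titration, fingerprint=protocol.fingerprint())


@pytest.fixture()
def noiseless_trace(params, schedule):
    """Single saturated cell, no noise, no background."""
    return simulate_trace(params, schedule, ConstantCa(39000.0),
                          noise=NoiseModel.none(), background_level=0.0)


def make_traceset(values, times=None, cycle_ids=None, background=None,
                  corrected=False):
    """Hand-build a one-cell TraceSet from raw fluorescence values."""
    from peaq.simulate import TraceSet

    values = np.asarray(values, dtype=float)
    n = len(values)
    if times is None:
        times = np.arange(n, dtype=float)
    if cycle_ids is None:
        cycle_ids = [None] * n
    if background is None:
        background = np.zeros(n)
    frames = pd.DataFrame({
        "cell_id": "cell_000",
        "frame": np.arange(n),
        "time_s": times,
        "cycle_id": pd.array([c if c is not None else pd.NA
                              for c in cycle_ids], dtype="Int64"),
        "fluorescence": values,
    })
    return TraceSet(frames=frames, background=np.asarray(background, float),
                    expression_scales={"cell_000": 1.0}, seed=0,
                    background_corrected=corrected)
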