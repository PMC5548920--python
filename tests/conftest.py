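import numpy as np
import pytest

import relfit as rf


@pytest.fixture(scope="session")
def decay_model():
    """dx/dt = -k x, x(0) = 1: closed form x(t) = exp(-k t)."""
    return rf.OdeModel.from_expressions(["x"], ["k"], {"x": "-k*x"}, {"x": 1.0})


@pytest.fixture(scope="session")
def chain_model():
    """Mass-action conversion A -> B: conserves the total."""
    return rf.OdeModel.from_expressions(
        ["A", "B"], ["k"], {"A": "-k*A", "B": "k*A"}, {"A": 2.0, "B": 0.5}
    )


@pytest.fixture(scope="session")
def styx_problem():
    """Noiseless single-observable cascade (1 observable, 10 free params)."""
    problem, truth = rf.make_preset("styx-like", seed=1, noise=(0.0, 0.0))
    return problem, truth


@pytest.fixture(scope="session")
def egfhrg_problem():
    """Noiseless 8-observable cascade (8 observables, 10 free params)."""
    problem, truth = rf.make_preset("egfhrg-small", seed=1, noise=(0.0, 0.0))
    return problem, truth


@pytest.fixture
def simple_dataset():
    """Two observables x two replicates with easy-to-check group values."""
    points = []
    for obs, rep, vals in [
        ("obs1", "r1", [2.0, 4.0, 6.0]),
        ("obs1", "r2", [10.0, 20.0, 30.0]),
        ("obs2", "r1", [1.0, 3.0, 5.0]),
    ]:
        for t, v in zip([0.0, 1.0, 2.0], vals):
            points.append(rf.DataPoint("ctrl", obs, t, rep, v))
    return rf.Dataset(tuple(points), rf.NormalizationSpec("average"))
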