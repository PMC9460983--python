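"""Shared fixtures.

The two MCMC calibrations (parameter recovery on the `recovery` scenario and
the FM/RM2 pair on the `waterlogged` scenario) are expensive, so they are
session-scoped and shared by every test that inspects them.
"""

from __future__ import annotations

import numpy as np
import pytest

from peatflux import inference
from peatflux.forward import Dataset
from peatflux.params import ParameterSpace
from peatflux.synth import make_fixture, _truth_vector


@pytest.fixture(scope="session")
def tiny_fixture():
    return make_fixture("tiny", seed=3)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_fixture):
    fx = tiny_fixture
    return Dataset.from_frames(fx["drivers"], eobs=fx["eobs"], trees=fx["trees"])


@pytest.fixture(scope="session")
def recovery_fit():
    """Full-model calibration on the 6-tree, 4-season recovery scenario with
    a known interior truth."""
    fx = make_fixture("recovery", seed=7)
    ds = Dataset.from_frames(fx["drivers"], eobs=fx["eobs"], trees=fx["trees"])
    result = inference.fit(ds, variant="FM", n_walkers=64, n_steps=3000, seed=11)
    truth = _truth_vector(result.space, fx["spec"])
    return {"fixture": fx, "dataset": ds, "result": result, "truth": truth}


@pytest.fixture(scope="session")
def waterlogged_fits():
    """FM and RM2 calibrated on the waterlogging-heavy scenario."""
    fx = make_fixture("waterlogged", seed=5)
    ds = Dataset.from_frames(fx["drivers"], eobs=fx["eobs"], trees=fx["trees"])
    fm = inference.fit(ds, variant="FM", n_walkers=48, n_steps=1200, seed=21)
    rm2 = inference.fit(ds, variant="RM2", n_walkers=48, n_steps=1200, seed=22)
    return {"fixture": fx, "dataset": ds, "FM": fm, "RM2": rm2}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fm_space():
    return ParameterSpace("FM", n_trees=6)
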