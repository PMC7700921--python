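"""Shared fixtures: a desk-scale phantom and normalized plans.

The small fixture grid (48x48x60 at 5 mm) keeps plan optimization and dose
computation fast while preserving every geometric relation of the default
configuration (margins and shifts stay super-voxel).
"""

import numpy as np
import pytest

from impteval.dose import DoseEngine
from impteval.phantom import PhantomConfig, build_phantom, make_motion_model
from impteval.planning import generate_plan, make_beam_config

SMALL_CONFIG = PhantomConfig(grid_shape=(48, 48, 60), spacing_mm=5.0)


@pytest.fixture(scope="session")
def phantom():
    return build_phantom(SMALL_CONFIG, seed=1)


@pytest.fixture(scope="session")
def motion():
    return make_motion_model(0.8)


@pytest.fixture(scope="session")
def engine(phantom):
    return DoseEngine(phantom)


@pytest.fixture(scope="session")
def plan_si(phantom, motion, engine):
    return generate_plan(
        phantom, make_beam_config("S-I"), motion=motion, engine=engine, seed=1
    )


@pytest.fixture(scope="session")
def plan_rl(phantom, motion, engine):
    return generate_plan(
        phantom, make_beam_config("R-L"), motion=motion, engine=engine, seed=1
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
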