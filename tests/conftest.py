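import numpy as np
import pytest

import vesselfoci as vf


@pytest.fixture(scope="session")
def small_geometry():
    """A compact ROI geometry used across tests (fast to render)."""
    return vf.SectionGeometry(shape=(384, 384), n_nuclei=25)


@pytest.fixture(scope="session")
def rendered_section(small_geometry):
    """One rendered phantom ROI with a moderate foci rate."""
    arm = vf.ArmConfig("demo", lambda_ext=4.0, lambda_emitter=6.0, tau_um=50.0)
    return vf.generate_section(arm, small_geometry, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
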