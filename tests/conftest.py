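import numpy as np
import pytest

import vesitraj as vt


@pytest.fixture(scope="session")
def gel_vesicle():
    """Planted-shell gel vesicle: 3.0/4.5 nm, 210/790 monomers, no jitter."""
    spec = vt.VesicleSpec(
        r_inner=3.0, r_outer=4.5, n_inner=210, n_outer=790, tail_state="gel", jitter=0.0, seed=101
    )
    return vt.make_vesicle(spec)


@pytest.fixture(scope="session")
def jittered_vesicle():
    spec = vt.VesicleSpec(
        r_inner=3.0, r_outer=4.5, n_inner=210, n_outer=790, tail_state="gel", jitter=0.05, seed=102
    )
    return vt.make_vesicle(spec)


@pytest.fixture(scope="session")
def small_vesicle():
    """Light fixture for dynamics: 300 monomers."""
    spec = vt.VesicleSpec(
        r_inner=2.0, r_outer=3.5, n_inner=60, n_outer=240, tail_state="gel", seed=103
    )
    return vt.make_vesicle(spec)


@pytest.fixture(scope="session")
def da25_vesicle():
    """Reference-composition preset: 1000 monomers, 21% inner."""
    return vt.make_vesicle(vt.preset_spec("DA-25", seed=104))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
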