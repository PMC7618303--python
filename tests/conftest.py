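import numpy as np
import pytest

import dantespace as ds


@pytest.fixture(scope="session")
def space():
    return ds.SpaceParams()


@pytest.fixture(scope="session")
def dante():
    return ds.DanteParams()


@pytest.fixture(scope="session")
def vw_flip_angles(space):
    """Refocusing train designed once for the vessel wall (shared: the
    design is deterministic and moderately expensive)."""
    return ds.design_space_flip_angles(space, ds.VW)


@pytest.fixture(scope="session")
def static_vw_runs(space, dante, vw_flip_angles):
    """Converged (2-repetition) static vessel-wall protocol with and
    without the preparation module; reused by several comparisons."""
    protocol = ds.ProtocolParams()
    no_dante = ds.DanteParams(n_pulses=0)
    with_prep = ds.run_protocol(
        ds.VW, ds.MotionModel.static(), dante, space, protocol,
        seed=1, flip_angles=vw_flip_angles,
    )
    without_prep = ds.run_protocol(
        ds.VW, ds.MotionModel.static(), no_dante, space, protocol,
        seed=1, flip_angles=vw_flip_angles,
    )
    return with_prep, without_prep
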