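import numpy as np
import pytest

import laaview as lv


@pytest.fixture(scope="session")
def windsock():
    """Canonical windsock: 25 x 20 mm elliptical orifice, 30 mm long."""
    params = lv.AnatomyParams(lv.MorphologyLabel.WINDSOCK,
                              orifice_long_axis_mm=25.0,
                              orifice_short_axis_mm=20.0,
                              length_mm=30.0)
    return lv.generate_case(params, rng_seed=1)


@pytest.fixture(scope="session")
def windsock_zone(windsock):
    return lv.locate_landing_zone(windsock)


@pytest.fixture(scope="session")
def windsock_coarse(windsock):
    return lv.generate_case(windsock.truth, windsock.rng_seed, edge_length_mm=2.5)


@pytest.fixture(scope="session")
def windsock_plan(windsock, windsock_zone, windsock_coarse):
    return lv.plan_views(windsock, windsock_zone, scoring_mesh=windsock_coarse.mesh)


@pytest.fixture(scope="session")
def cauliflower():
    params = lv.AnatomyParams(lv.MorphologyLabel.CAULIFLOWER,
                              orifice_long_axis_mm=24.0,
                              orifice_short_axis_mm=21.0,
                              length_mm=22.0)
    return lv.generate_case(params, rng_seed=4)


@pytest.fixture(scope="session")
def default_run():
    """The default 28-case study at the documented demonstration seed."""
    return lv.run_experiment(lv.RunConfig(seed=1))


@pytest.fixture(scope="session")
def noisefree_run():
    """Same cohort with every noise source disabled."""
    return lv.run_experiment(lv.RunConfig(seed=1, noise=lv.NoiseModel.noiseless()))


def rigid_rotation(axis, angle_deg):
    import trimesh
    return trimesh.transformations.rotation_matrix(
        np.deg2rad(angle_deg), axis)[:3, :3]
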