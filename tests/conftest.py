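import copy

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def rough_mesh():
    """Small periodic patch with frozen random heights (read-only)."""
    from avidmc import membrane as mb

    m = mb.triangular_lattice_patch(100.0, 10, 10, kappa=20.0, sigma=0.0)
    m.vertices[:, 2] = 2.0 * np.random.default_rng(7).standard_normal(
        m.n_vertices)
    return m


@pytest.fixture(scope="session")
def desk_trajectory():
    """One short deformable-particle trajectory shared by invariant and
    bookkeeping tests (the system is evolved in place)."""
    from avidmc import mc_engine as eng
    from avidmc.system_builder import desk_fixture

    system = desk_fixture("mini_LSt_strong_lowNr")
    sched = copy.deepcopy(system.schedule)
    sched.equilibration_steps = 5_000
    sched.production_steps = 15_000
    sched.sample_interval = 100
    sched.record_interval = 1_000
    sched.resync_interval = 10 ** 9   # exercise incremental bookkeeping
    traj = eng.run_mc(system, sched, seed=5, inplace=True)
    return system, traj
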