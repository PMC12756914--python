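"""Metropolis orchestration: acceptance rule, determinism, replicas,
reference ensembles, bookkeeping and structural invariants."""

import copy

import numpy as np
import pytest

from avidmc import mc_engine as eng
from avidmc import membrane as mb
from avidmc.system_builder import desk_fixture


class TestMetropolisRule:
    def test_downhill_and_flat_always_accepted(self, rng):
        assert eng.metropolis_accept(0.0, rng)
        assert eng.metropolis_accept(-5.0, rng)

    def test_uphill_rate_matches_exponential(self):
        rng = np.random.default_rng(8)
        n = 100_000
        acc = sum(eng.metropolis_accept(1.0, rng) for _ in range(n))
        p = np.exp(-1.0)
        sigma = np.sqrt(p * (1 - p) * n)
        assert abs(acc - n * p) < 3 * sigma

    def test_nan_energy_raises(self, rng):
        with pytest.raises(ValueError):
            eng.metropolis_accept(float("nan"), rng)


class TestScheduleValidation:
    def test_frequencies_normalized(self):
        s = eng.McSchedule(move_mix={"vertex": 2.0, "bond": 2.0})
        assert sum(s.move_mix.values()) == pytest.approx(1.0)

    def test_unknown_move_rejected(self):
        with pytest.raises(ValueError):
            eng.McSchedule(move_mix={"teleport": 1.0})

    def test_sampling_grid_consistency(self):
        with pytest.raises(ValueError):
            eng.McSchedule(production_steps=10, sample_interval=100)

    def test_default_replica_count_is_four(self):
        assert eng.McSchedule().n_replicas == 4


class TestRunDeterminism:
    def test_same_seed_bitwise_identical(self):
        system = desk_fixture("two_state_toy")
        a = eng.run_mc(system, system.schedule, seed=5)
        b = eng.run_mc(system, system.schedule, seed=5)
        assert np.array_equal(a.m_series, b.m_series)
        assert np.array_equal(a.energy_series["total"], b.energy_series["total"])

    def test_zero_production_yields_empty_valid_trajectory(self):
        system = desk_fixture("two_state_toy")
        sched = copy.deepcopy(system.schedule)
        sched.production_steps = 0
        traj = eng.run_mc(system, sched, seed=1)
        assert traj.m_series.size == 0
        assert traj.mean_m == 0.0


class TestTwoStateSampling:
    def test_bound_fraction_matches_boltzmann(self):
        """Exact two-state occupancy within 3 sigma Monte Carlo error."""
        system = desk_fixture("two_state_toy")
        sched = copy.deepcopy(system.schedule)
        sched.production_steps = 120_000
        traj = eng.run_mc(system, sched, seed=21)
        p_exp = system.expectation["p_bound"]
        p_obs = float((traj.m_series > 0).mean())
        n_eff = traj.m_series.size / 8.0  # conservative correlation discount
        assert abs(p_obs - p_exp) < 3 * np.sqrt(p_exp * (1 - p_exp) / n_eff)


class TestReplicas:
    def test_duplicate_seeds_rejected(self):
        system = desk_fixture("two_state_toy")
        with pytest.raises(ValueError, match="distinct"):
            eng.run_replicas(system, system.schedule, [3, 3, 4, 5])

    def test_replica_summaries(self):
        system = desk_fixture("two_state_toy")
        sched = copy.deepcopy(system.schedule)
        sched.production_steps = 20_000
        ens = eng.run_replicas(system, sched, [1, 2, 3, 4])
        assert ens.n_replicas == 4
        mean, sd = ens.mean_and_sd()
        assert 0 < mean < 1.001
        assert sd >= 0

    def test_error_shrinks_with_more_sampling(self):
        """Replica scatter of the bound fraction decreases with run length
        roughly as 1/sqrt(steps)."""
        system = desk_fixture("two_state_toy")
        sds = []
        for steps in (6_000, 60_000):
            sched = copy.deepcopy(system.schedule)
            sched.production_steps = steps
            ens = eng.run_replicas(system, sched, [11, 12, 13, 14])
            frac = [(t.m_series > 0).mean() for t in ens.trajectories]
            sds.append(np.std(frac, ddof=1))
        assert sds[1] < sds[0]


class TestUnboundReference:
    def test_reference_never_binds_and_is_reproducible(self):
        system = desk_fixture("mini_RG_strong")
        sched = copy.deepcopy(system.schedule)
        sched.equilibration_steps = 2_000
        sched.production_steps = 10_000
        sched.sample_interval = 100
        a = eng.run_unbound_reference(system, sched, seed=9)
        b = eng.run_unbound_reference(system, sched, seed=9)
        assert np.all(a.m_series == 0)
        assert np.array_equal(a.energy_series["total"],
                              b.energy_series["total"])

    def test_membrane_statistics_match_particle_free_run(self):
        """With the particle out of range, membrane bending energies are
        statistically indistinguishable from a membrane-only run (Welch test
        on block-averaged, decorrelated samples)."""
        from avidmc import binding as bd, nanoparticle as npm
        from avidmc.system_builder import System, build_membrane_fixture
        from avidmc.thermo_analysis import welch_test

        def tiny_system(with_np):
            mesh = build_membrane_fixture(60.0, 36, 0.10, seed=2, kappa=20.0)
            nano = (npm.build_rigid_np(n_ligands=8, radius=10.0, seed=1,
                                       center=(30.0, 30.0, 300.0))
                    if with_np else None)
            rec = bd.ReceptorField(anchors_xy=np.random.default_rng(3)
                                   .uniform(0, 60.0, size=(4, 2)))
            return System(mesh=mesh, nano=nano, receptors=rec,
                          bond_model=bd.BINDERS["strong"],
                          schedule=eng.DESK_SCHEDULE, equil_scaffold=False)

        sched = eng.McSchedule(move_mix={"vertex": 0.8, "hop": 0.2},
                               equilibration_steps=20_000,
                               production_steps=60_000,
                               sample_interval=300, record_interval=0)
        ref = eng.run_unbound_reference(tiny_system(True), sched, seed=3)
        sched_np = copy.deepcopy(sched)
        bare = eng.run_mc(tiny_system(False), sched_np, seed=4)
        blocks = lambda e: e.reshape(10, -1).mean(axis=1)
        _, _, p = welch_test(blocks(ref.energy_series["bending"]),
                             blocks(bare.energy_series["bending"]))
        assert p > 1e-3


class TestBookkeepingAndInvariants:
    def test_incremental_energy_matches_recomputation(self, desk_trajectory):
        """Per-move energy updates agree with a from-scratch evaluation at
        the end of a run with resynchronization disabled."""
        system, traj = desk_trajectory
        fresh = eng.total_energy(system)
        assert traj.energy_series["total"][-1] == pytest.approx(
            fresh["total"], abs=1e-6)

    def test_multivalency_bounded_by_capacity(self, desk_trajectory):
        system, traj = desk_trajectory
        assert traj.m_series.max() <= min(traj.n_ligands, traj.n_receptors)
        assert traj.m_series.min() >= 0

    def test_topology_and_counts_conserved(self, desk_trajectory):
        system, traj = desk_trajectory
        assert mb.mesh_topology_check(system.mesh).ok
        assert system.nano.n_ligands == traj.n_ligands
        assert system.receptors.n_receptors == traj.n_receptors
        assert system.check_invariants()

    def test_acceptance_rates_recorded_per_move_type(self, desk_trajectory):
        _, traj = desk_trajectory
        assert set(traj.acceptance) == set(eng.MOVE_TYPES)
        assert traj.attempted["vertex"] > 0
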