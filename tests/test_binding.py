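"""Bond energetics, candidate enumeration and receptor moves."""

import math

import numpy as np
import pytest

from avidmc import binding as bd
from avidmc.constants import stiffness_kbt
from avidmc.system_builder import desk_fixture


class TestBellPotential:
    @pytest.mark.parametrize("binder,depth", [
        ("strong", -19.1), ("intermediate", -11.45), ("weak", -1.76)])
    def test_well_depth_at_rest_length(self, binder, depth):
        bm = bd.BINDERS[binder]
        assert bd.bell_bond_energy(bm.rest_length, bm) == depth

    def test_intermediate_binder_one_kbt_stretch(self):
        """Stretch chosen so the harmonic term contributes exactly 1 k_BT."""
        bm = bd.BINDERS["intermediate"]
        delta = math.sqrt(2.0 / stiffness_kbt(0.38))
        e = bd.bell_bond_energy(bm.rest_length + delta, bm)
        assert e == pytest.approx(-10.45, rel=1e-9)

    def test_minimum_is_at_rest_length(self):
        bm = bd.BINDERS["strong"]
        d = np.linspace(bm.rest_length - 0.2, bm.capture_cutoff, 101)
        e = bd.bell_bond_energy(d, bm)
        assert np.argmin(e) == np.argmin(np.abs(d - bm.rest_length))

    def test_no_bond_beyond_capture_cutoff(self):
        bm = bd.BINDERS["strong"]
        assert np.isinf(bd.bell_bond_energy(bm.capture_cutoff + 0.01, bm))

    def test_binder_models_validated(self):
        with pytest.raises(ValueError):
            bd.BondModel("bad", dG0=1.0, k_b_si=1.0)
        with pytest.raises(ValueError):
            bd.BondModel("bad", dG0=-1.0, k_b_si=0.0)


class TestFlexuralEnergy:
    def test_unbent_bound_rod_is_free(self):
        assert bd.receptor_flexural_energy(0.0, 5.0, bound=True) == 0.0

    def test_unbound_rod_pays_nothing(self):
        assert bd.receptor_flexural_energy(0.7, 5.0, bound=False) == 0.0

    def test_harmonic_scaling(self):
        e1 = bd.receptor_flexural_energy(0.2, 5.0)
        e2 = bd.receptor_flexural_energy(0.4, 5.0)
        assert e2 == pytest.approx(4.0 * e1)

    def test_flexural_constant_units(self):
        rec = bd.ReceptorField(np.zeros((1, 2)))
        # 7000 pN nm^2 over a 19 nm rod, in k_BT/rad^2
        assert rec.flexural_k == pytest.approx(7000.0 / 19.0 * 0.24306, rel=1e-3)


class TestEffectiveStiffness:
    def test_equal_springs_halve(self):
        assert bd.effective_stiffness(1.0, 1.0) == pytest.approx(0.5)
        assert bd.effective_stiffness(0.38, 0.38) == pytest.approx(0.19)

    def test_rigid_substrate_limit(self):
        assert bd.effective_stiffness(0.38, 1e9) == pytest.approx(0.38, rel=1e-6)

    def test_series_bound(self):
        assert bd.effective_stiffness(0.7, 0.2) <= 0.2

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bd.effective_stiffness(0.0, 1.0)


class TestCandidateEnumeration:
    def _scene(self, n_l, n_r, rng, spread=30.0):
        tips = rng.uniform(0, spread, size=(n_l, 3))
        tips[:, 2] = rng.uniform(15.0, 22.0, n_l)
        anchors = np.column_stack([rng.uniform(0, spread, size=(n_r, 2)),
                                   np.zeros(n_r)])
        normals = np.tile([0.0, 0.0, 1.0], (n_r, 1))
        return tips, anchors, normals

    def test_distant_particle_has_no_candidates(self, rng):
        tips, anchors, normals = self._scene(5, 5, rng)
        tips[:, 2] += 200.0
        li, rj, e = bd.enumerate_bond_candidates(
            tips, np.ones(5, bool), anchors, normals, np.ones(5, bool),
            bd.BINDERS["strong"], 5.0, box=None)
        assert li.size == 0

    def test_single_contact_pair(self):
        bm = bd.BINDERS["strong"]
        tips = np.array([[10.0, 10.0, bm.rest_length]])
        anchors = np.array([[10.0, 10.0, 0.0]])
        normals = np.array([[0.0, 0.0, 1.0]])
        li, rj, e = bd.enumerate_bond_candidates(
            tips, np.ones(1, bool), anchors, normals, np.ones(1, bool),
            bm, 5.0, box=None)
        assert li.tolist() == [0] and rj.tolist() == [0]
        assert e[0] == pytest.approx(bm.dG0
                                     + bd.rod_orientation_penalty(
                                         bm.rest_length, bm, 19.0))

    def test_matches_exhaustive_scan(self, rng):
        """Vectorized enumeration equals a brute-force O(N_l N_r) loop."""
        bm = bd.BondModel("loose", dG0=-5.0, k_b_si=0.005)
        tips, anchors, normals = self._scene(12, 15, rng)
        lig_free = rng.random(12) > 0.3
        rec_free = rng.random(15) > 0.3
        li, rj, _ = bd.enumerate_bond_candidates(
            tips, lig_free, anchors, normals, rec_free, bm, 4.0, box=60.0)
        got = set(zip(li.tolist(), rj.tolist()))
        expected = set()
        for i in range(12):
            for j in range(15):
                if not (lig_free[i] and rec_free[j]):
                    continue
                d = tips[i] - anchors[j]
                d[:2] -= 60.0 * np.round(d[:2] / 60.0)
                if abs(np.linalg.norm(d) - bm.rest_length) <= bm.capture_halfwidth:
                    expected.add((i, j))
        assert got == expected

    def test_bound_partners_excluded(self, rng):
        bm = bd.BondModel("loose", dG0=-5.0, k_b_si=0.005)
        tips, anchors, normals = self._scene(6, 6, rng)
        free = np.ones(6, bool)
        free[2] = False
        li, _, _ = bd.enumerate_bond_candidates(
            tips, free, anchors, normals, np.ones(6, bool), bm, 4.0, box=None)
        assert 2 not in li


class TestReceptorHops:
    def test_unbound_hop_is_free(self, rng):
        system = desk_fixture("mini_RG_strong")
        free = int(np.where(system.receptors.bound_partner < 0)[0][0])
        prop = bd.receptor_hop_move(system, free, 5.0, rng)
        assert prop.delta_energy == 0.0

    def test_bound_hop_pays_bond_energy_difference(self, rng):
        system = desk_fixture("mini_RG_strong")
        r = int(np.where(system.receptors.bound_partner >= 0)[0][0])
        e_old = system.bond_energy_of(r)
        prop = bd.receptor_hop_move(system, r, 2.0, rng)
        e_new = system.bond_energy_at(r, prop.new_xy)
        assert prop.delta_energy == pytest.approx(e_new - e_old, abs=1e-9)

    def test_free_diffusion_explores_patch_uniformly(self):
        """chi^2 test of anchor occupancy after long unbound diffusion."""
        import copy
        from scipy import stats
        from avidmc import mc_engine as eng

        system = desk_fixture("mini_RG_intermediate")
        system.receptors.bound_partner[:] = -1
        system.ligand_bound[:] = -1
        system.bonds_enabled = False
        sched = copy.deepcopy(system.schedule)
        sched.move_mix = {"hop": 1.0}
        sched.equilibration_steps = 2_000
        sched.production_steps = 60_000
        sched.sample_interval = 300
        sched.record_interval = 300
        traj = eng.run_mc(system, sched, seed=3)
        xy = traj.receptor_xy_frames.reshape(-1, 2)
        L = system.mesh.box
        counts, *_ = np.histogram2d(xy[:, 0], xy[:, 1],
                                    bins=4, range=[[0, L], [0, L]])
        _, p = stats.chisquare(counts.ravel())
        assert p > 1e-3
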